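"""Compute per-sample discriminating scores for pathway pairs.

Builds a tiny synthetic cohort with one planted pathway pair, computes
the DS feature matrix, and shows how the planted pair's scores separate
cases from controls while an unrelated pair's do not.
"""

from pathcrosstalk import (
    SimulationConfig,
    build_feature_matrix,
    ds_score,
    log_transform,
    simulate_cohort,
)

# DS of two small gene-expression vectors: |mean difference| relative to
# the summed spread
print(f"ds_score([1,3], [5,7]) = {ds_score([1, 3], [5, 7]):.5f}  (= sqrt(2))")

config = SimulationConfig(
    n_genes=200,
    n_pathways=4,
    genes_per_pathway=15,
    n_samples_case=50,
    n_samples_control=50,
    planted_pairs=((0, 1),),
    effect_size=2.0,
    background_de_fraction=0.0,
    planted_regulators={},
    seed=0,
)
gene_expr, _, pathways, labels, truth = simulate_cohort(config)
log2 = log_transform(gene_expr)
features = build_feature_matrix(log2, pathways.restrict(set(log2.feature_ids), 2))

print(f"\n{len(features.pairs)} pathway pairs x {len(features.sample_ids)} samples")
for key in ("PW00|PW01", "PW02|PW03"):
    case_mean = features.ds.loc[labels.case_ids, key].mean()
    ctrl_mean = features.ds.loc[labels.control_ids, key].mean()
    tag = "planted" if key == "PW00|PW01" else "null"
    print(f"{key} ({tag:7s}): mean DS case={case_mean:.3f}  control={ctrl_mean:.3f}")
print(
    "\nThe planted pair's DS is higher in cases (its two pathways move"
    " apart there); the null pair's DS is class-independent."
)
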