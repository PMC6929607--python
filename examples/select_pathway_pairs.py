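"""Monte-Carlo cross-validated pathway-pair selection, end to end.

Simulates a discovery-scale cohort (30 pathways, 3 planted cross-talk
pairs), runs the repeated train/test protocol with per-pair random-forest
ranking, and reports the selected top-10 panel with its train/test AUC.
Takes ~2 min on one CPU (most of it in the miRNA mutual-information
stage of the full pipeline).
"""

from pathcrosstalk import (
    PipelineConfig,
    SimulationConfig,
    run_pipeline_data,
    simulate_cohort,
)

config = SimulationConfig(seed=0)  # 1500 genes, 30 pathways, 60+60 samples
gene_expr, mirna_expr, pathways, labels, truth = simulate_cohort(config)

pipeline = PipelineConfig(
    n_repeats=10, rf_n_estimators=10, screen_top=25, seed=0
)
result = run_pipeline_data(gene_expr, mirna_expr, pathways, labels, pipeline)

planted = {"|".join(sorted(p)) for p in truth.planted_pairs}
print("top-10 panel (pair, repeats-in-top-10):")
freq = dict(zip(result.aggregate["pair"], result.aggregate["frequency"]))
for key in result.panel:
    mark = "  <- planted" if key in planted else ""
    print(f"  {key}  {freq[key]:2d}/10{mark}")
print(f"\nrecovered {len(planted & set(result.panel))}/3 planted pairs")
print(
    f"panel AUC: train {result.auc_train_mean:.3f} / test {result.auc_test_mean:.3f}"
)
print(
    "\nAUCs near 1 on held-out data mean the selected pathway-pair DS"
    " features separate cases from controls; under a null cohort they"
    " would hover around 0.5."
)
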