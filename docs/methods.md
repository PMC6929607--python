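# Methods

## The model and its assumptions

The package treats "pathway cross-talk" operationally: two pathways
cross-talk, with respect to a two-class cohort, when the relationship
between their average expression levels differs between classes. The
per-sample statistic used is the discriminating score

    DS(x, y; s) = |M_x(s) − M_y(s)| / (SD_x(s) + SD_y(s)),

where M and SD are the mean and (n−1)-denominator standard deviation of
the sample's log2 expression over each pathway's member genes, restricted
to measured genes. DS is computed per sample so that it can serve as a
classification feature; it is symmetric in the two pathways, invariant
under rescaling all expression values, and non-negative. A small epsilon
(10⁻¹²) guards the denominator, so constant pathways produce a large
finite score rather than an error; genes shared by both pathways
contribute to both means. Because of the absolute value, DS responds to a
class shift in M_x − M_y only to the extent that the shift changes the
*magnitude* of the gap — a property the synthetic generator must respect
(below).

Pair selection assumes nothing about the DS distribution: each pair is
ranked by the stratified k-fold (default k = 10) cross-validated AUC of a
random forest fit on its single DS feature, on class-balanced training
data, and the procedure is repeated over Monte-Carlo 60/40 train/test
partitions. Differential expression and enrichment are recomputed inside
every repeat on the training split only, so the feature space itself is
re-selected per repeat; the miRNA stage runs once on the whole dataset.
Aggregation counts, per pair, how many repeats placed it in the top
`top_m` (= 10) positions; the final panel is the `top_m` most frequent
pairs (ties by mean AUC, then name), and its joint random-forest model is
evaluated on each repeat's held-out split.

Differential expression uses a two-sided Wilcoxon rank-sum test on log2
values (exact null for tie-free classes of ≤ 25 samples, normal
approximation with tie correction otherwise; Welch's t available). This
is a deliberate, documented divergence from count-model differential
expression: the pipeline only needs a robust ranking of class-shifted
features, not dispersion estimates. Both the gene and miRNA stages
threshold the Benjamini–Hochberg-adjusted p by default (raw-p optional),
with |log2FC| > 1.

Enrichment is the one-sided Fisher exact (upper hypergeometric tail)
test, conditioned on the measured-gene universe after variance filtering
(not the full pathway collection), with a raw p < 0.01 call by default;
BH adjustment across pathways is available but off, matching the usual
over-representation practice of thresholding pathway p-values directly.

Mutual information uses the Kraskov–Stögbauer–Grassberger estimator
(variant 1, Chebyshev metric, k = 3 neighbours, nats), computed by exact
pairwise-distance counting (O(n²) per pair, vectorised over genes; the
batch path works in float32 to halve memory traffic). The estimator
assumes continuous data; neighbour counts are clipped at zero where ties
would otherwise make them negative. A gene is called a potential target
of a miRNA when its MI exceeds the per-gene (1 − α) quantile (α = 0.01,
"higher" interpolation, so the exceedance probability is ≤ 1/(P+1) for P
permutations) of a null built from P = 100 random permutations of the
miRNA's sample vector. Permutation calibration was chosen because no
principled fixed MI threshold exists for finite samples; it is
seed-reproducible and matches the nominal α under the null (verified in
the tests).

"Degree centrality" follows the method's usage, not graph theory: for a
retained miRNA it is the number of its declared targets inside the union
of the panel pathways in which its target set is over-represented,
reported together with that union's size and the number of coupled
pathways. The network filter (pathway nodes need ≥ 2 interactions) is
applied once, not iteratively, then isolated nodes are dropped.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `logfc_threshold`, `de_alpha` | 1, 0.01 | volcano rule on log2 scale, adjusted p |
| `enrich_alpha` | 0.01 | raw Fisher p cut; ≥ 1 disables the gate |
| `train_fraction`, `n_repeats` | 0.6, 50 | Monte-Carlo 60/40 splits; per-class train size is `round(0.6·n)` |
| `inner_folds` | 10 | stratified CV folds for per-pair AUC |
| `top_m` | 10 | panel size and per-repeat top positions counted |
| `rf_n_estimators` | 100 | forest size; 10 used in the scaled validation runs |
| `screen_top` | 50 | pairs given full RF CV per repeat (see below) |
| `mi_k_neighbors`, `mi_permutations`, `mi_alpha` | 3, 100, 0.01 | KSG + permutation null |
| `min_interactions` | 2 | network node filter |
| `variance_quantile` | 0 | drop only constant genes; no variance cutoff is imposed by default |

**Screening.** A full random-forest cross-validation for each of several
hundred pairs in every repeat costs ~1 ms per tree per fit and dominates
the runtime. Since an RF on a *single* feature estimates the same
population quantity as the feature's rank (Mann–Whitney) AUC, ranking
first computes the folded rank-AUC for all pairs (vectorised, exact) and
runs the forest CV only for the best `screen_top` candidates; the
remaining pairs keep the rank statistic. The screen is several times
wider than `top_m`, so top positions are always forest-ranked. Forest
defaults are likewise a scale decision: 100 trees by default, 10 trees in
the package's own validation runs, where the feature is one-dimensional
and fold AUCs are averaged over 10 folds and 10 repeats.

## The synthetic generator

`SimulationConfig` defaults define the validation scenario used
throughout: 1500 genes, 30 disjoint 15-gene pathways (the remaining 1050
genes are pathway-free background), 60 case + 60 control samples, three
planted pathway pairs at `effect_size = 2` within-class standard
deviations of pair contrast, 20 miRNAs with two planted regulators and
three decoys. Expression is log-normal: per-gene baselines N(7, 1.5²) on
the log2 scale, within-class Gaussian noise (sd 0.5), written as raw
values 2^x − 1 so the standard log2(x+1) load path recovers the
generating scale. Three structural choices matter and are deliberate:

* **Antisymmetric, baseline-oriented pair planting.** For a planted pair,
  cases shift one pathway up and the other down by `effect_size/2 ·
  noise_sd` each, the up-shift going to the pathway with the higher
  realized baseline mean, and pathway blocks share a common average
  baseline. Together these guarantee the planted shift *widens*
  |M_x − M_y| instead of folding through the absolute value, and they
  bound the contrast of any pair containing only one planted pathway at
  half the planted contrast. Shifting only one pathway — the more obvious
  design — makes roughly half of all (planted, other) pairs carry the
  full planted contrast, and exact pair recovery becomes impossible in
  principle. A consequence of antisymmetric planting with several pairs
  is that up/down combinations *across* planted pairs are exactly as
  discriminative as the pairs themselves; with 3 planted pairs this
  yields 9 strong pairs, which still fit a top-10 panel.
* **Balanced background differential genes.** Every pathway receives a
  fraction (0.5) of member genes shifted ±1.6 log2 units in cases, half
  up and half down. Individually these genes pass the DE rule, so every
  pathway — not only the planted ones — is enriched and the pair stage
  faces the full candidate space; because the shifts cancel within a
  pathway, pathway means (the DS numerator) stay at baseline. The shifts
  do inflate the case-side per-sample SD, which nudges null-pair DS
  distributions away from exact class symmetry — visible as folded AUCs
  of ~0.6–0.7 for null pairs, well below the planted ~0.95.
* **Within-class regulator coupling.** A regulator miRNA is shifted by
  `mirna_logfc` (1.5) in cases; its targets replace √ρ of their noise
  with the *within-class standardized* miRNA fluctuation, negated
  (repression), with ρ = `regulation_strength` the explained variance
  fraction. Coupling to the raw (class-shifted) miRNA value instead
  would hand every differentially expressed miRNA a genuine
  class-mediated mutual information with every class-shifted gene, making
  regulator identity unidentifiable — decoy miRNAs would tie with true
  regulators. Within-class coupling keeps miRNA-target dependence
  attributable to regulation. The cost is that targets do not inherit
  the miRNA's class shift; the per-pathway shared activity factor
  (sd 0.25 per pathway and sample, emulating co-expression) and the
  planted shifts still make target pathways differential.

Presets: `null_config` zeroes *every* planted structure (pair shifts,
background DE, miRNA shifts, couplings) for calibration runs;
`regulator_recovery_config` (250 genes, 10 pathways, 100+100 samples, no
pair/background shifts) isolates the regulator-ranking task;
`small_pipeline_config` exercises all stages quickly.

What the generator does **not** model: sequencing-count noise (negative
binomial), batch effects, overlapping pathways, realistic cohort sizes,
or sequence-based miRNA targeting. Passing tests therefore demonstrate
that the implementation recovers the structures it defines under
idealized log-normal noise — not that the method would perform equally
on real tumour cohorts.

## Numerical choices

Sample standard deviations use the n−1 denominator throughout. BH
adjustment delegates to statsmodels and is verified against a brute-force
step-up oracle to 10⁻¹²; Fisher p-values use the scipy hypergeometric
survival function and are verified against exact integer enumeration on
all tables with N ≤ 25 to 10⁻¹⁰. AUCs are computed by the Mann–Whitney
rank identity with average ranks for ties; a constant feature is defined
to have AUC 0.5. Train/test splitting rounds the per-class training size
to the nearest integer (52/34 for 86 balanced samples at 0.6) and clamps
so neither side is empty. Expression TSVs are written with 17 significant
digits and parsed with numpy's correctly rounded string conversion, so
write→read round trips are bit-exact. All randomness derives from a
master seed through SHA-256 hashing of (seed, stage, repeat) context, so
stages are independently reproducible and a rerun is byte-identical.

## Validation problem sizes

The package's own acceptance runs use scaled-down settings chosen for a
single CPU: 10 Monte-Carlo repeats, 10-tree ranking forests behind a
25-candidate prescreen (panel evaluation uses the same forest size), 100
MI permutations, 10 master seeds for the recovery checks and 20 for the
null calibrations. At these sizes the planted-pair check runs in ~5 min
and the regulator check in ~4 min.

## Known limitations

* The DS reading is per-sample; cohort-level cross-talk statistics are
  out of scope.
* Wilcoxon-based DE is rank-based and will not match count-model tools
  gene-for-gene on real count data.
* The enrichment gate requires ≥ 2 enriched pathways per repeat; repeats
  below that are skipped with a warning (a fully null cohort should be
  run with `enrich_alpha = 1`).
* KSG MI degrades on heavily tied (e.g. zero-inflated) data.
* With several planted pairs the cross-combinations of their pathways are
  inherently as discriminative as the pairs themselves (see above); the
  panel, not the single best pair, is the unit of recovery.
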