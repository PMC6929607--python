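# pathcrosstalk

Discovery of class-discriminative **pathway cross-talk** and of the
**miRNA regulators** that control it, from a two-class (case/control)
transcriptomics cohort — e.g. a tumour subtype versus normal tissue.

Given a gene expression matrix, a matched miRNA expression matrix,
case/control labels and a pathway collection (GMT), the package runs a
four-step workflow:

1. **Differential expression** of genes (Wilcoxon rank-sum or Welch's t on
   log2 values; Benjamini–Hochberg correction; significance rule
   |log2FC| > 1 and adjusted p < 0.01).
2. **Pathway enrichment** of the differential genes (one-sided Fisher's
   exact test against the measured-gene universe, p < 0.01).
3. **Pathway cross-talk scoring and pair selection.** For every pair of
   enriched pathways (x, y) and every sample, the *discriminating score*

   DS = |M<sub>x</sub> − M<sub>y</sub>| / (SD<sub>x</sub> + SD<sub>y</sub>)

   contrasts the mean expression of the two pathways' member genes in that
   sample, normalised by their spread. Under Monte-Carlo cross-validation
   (class-balanced 60/40 train/test splits, repeated; steps 1–3 recomputed
   on each training set), each pair's DS feature is ranked by the
   stratified 10-fold cross-validated AUC of a random forest, the top 10
   pairs per repeat are recorded, and the pairs most frequently in the top
   10 form the final panel, evaluated jointly on the held-out test splits.
4. **miRNA regulator ranking.** On the whole dataset, differentially
   expressed miRNAs are mapped to putative target genes by
   Kraskov k-nearest-neighbour **mutual information** with a permutation
   null; each miRNA's targets are tested for enrichment in the panel
   pathways (Fisher, p < 0.01); retained miRNAs are ranked by **degree
   centrality** — the number of genes they regulate within their coupled
   pathways — and the pathway/miRNA network is assembled (pathway nodes
   with fewer than 2 interactions dropped).

A first-class synthetic-cohort generator
(`pathcrosstalk.synthetic_data`) plants known cross-talk pairs and
regulator miRNAs so that every stage can be validated against ground
truth without external data.

## Worked example

```python
from pathcrosstalk import (
    PipelineConfig, SimulationConfig, run_pipeline_data, simulate_cohort,
)

config = SimulationConfig(seed=0)   # 1500 genes, 30 pathways, 60+60 samples,
                                    # 3 planted pairs, 2 planted regulators
gene, mirna, pathways, labels, truth = simulate_cohort(config)
result = run_pipeline_data(
    gene, mirna, pathways, labels,
    PipelineConfig(n_repeats=10, rf_n_estimators=10, screen_top=25, seed=0),
)
print(result.panel)
print(result.auc_train_mean, result.auc_test_mean)
```

prints the selected top-10 pathway-pair panel and its AUCs (about two
minutes on one CPU):

```
['PW02|PW05', 'PW02|PW03', 'PW00|PW05', 'PW00|PW03', 'PW04|PW05',
 'PW01|PW04', 'PW03|PW04', 'PW05|PW09', 'PW00|PW01', 'PW04|PW15']
0.982... 0.993...
```

— all three planted pairs (`PW00|PW01`, `PW02|PW03`, `PW04|PW05`) are in
the panel (the up/down cross-combinations of planted pathways, such as
`PW02|PW05`, are equally discriminative by construction and accompany
them), and the joint random-forest model on the panel's DS features
reaches held-out AUC ≈ 0.99; under a cohort with no planted structure the
same protocol stays near AUC 0.5. The scripts in `examples/` walk through
each capability (DS scoring, pair selection, regulator ranking) with
printed output.

## Command line

```bash
pathcrosstalk simulate --outdir cohort --seed 0
pathcrosstalk run-all --expression cohort/expression.tsv \
    --mirna cohort/mirna.tsv --labels cohort/labels.tsv \
    --gmt cohort/pathways.gmt --outdir run --seed 0
```

`run-all` writes per-repeat rankings, pair frequencies, the panel, an AUC
report, miRNA targets and centrality tables, the network (GraphML +
edge TSV), a `manifest.json` (config, seed, library versions, row
counts) and a `run.log` recording every derived seed; a rerun with the
same seed is byte-identical. Each stage (`de`, `enrich`, `crosstalk`, `select-pairs`,
`mirna-net`) is also callable standalone on the previous stage's TSV
outputs.

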