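"""Synthetic two-class expression cohorts with planted ground truth.

The generator emulates the structure of a case/control RNA-seq cohort
(e.g. a tumour subtype versus normal tissue) at desk scale:

* genes organised into disjoint pathway blocks plus a pool of background
  genes outside any pathway;
* per-gene baselines on the log2 scale with Gaussian within-class noise
  (i.e. log-normal expression), written out as non-negative "raw" values
  ``2**x - 1`` so that the standard ``log2(x + 1)`` transform recovers the
  generating scale;
* *planted pathway pairs*: for a planted pair, case samples shift one
  pathway up and the other down by ``effect_size/2 * noise_sd`` each
  (the up-shift goes to the pathway with the higher realized baseline,
  so the gap |Mx − My| widens rather than folds through zero), giving
  the pair a class contrast of ``effect_size * noise_sd`` while any pair
  involving only one of the two pathways carries at most half of it —
  planted pairs are the strongest cross-talk signal by construction;
* *background differentially expressed genes*: in every pathway a fraction
  of member genes receives a balanced up/down case shift. Individually
  these genes are strongly differentially expressed, which makes every
  pathway (not only the planted ones) enriched and lets the pair-selection
  stage face a realistically large candidate space; because the up and
  down shifts cancel, pathway means — the quantity the discriminating
  score contrasts — stay at baseline;
* *regulator miRNAs*: planted regulators are shifted by ``mirna_logfc`` in
  cases, and their target genes are generated with monotone *negative*
  dependence on the miRNA's within-class fluctuations (repressor
  semantics), ``regulation_strength`` being the fraction of target-gene
  variance explained by the miRNA. Decoy miRNAs are class-shifted but
  regulate nothing, so regulator ranking cannot succeed on differential
  expression alone.

Everything is a deterministic function of ``SimulationConfig`` (including
its seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CASE,
    CONTROL,
    ExpressionMatrix,
    GeneSetCollection,
    Labels,
    write_expression,
    write_gmt,
    write_labels,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "write_fixtures",
    "null_config",
    "regulator_recovery_config",
    "small_pipeline_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults describe the scaled-down discovery scenario used throughout
    the package's own validation: 30 disjoint 15-gene pathways inside a
    1500-gene universe, 60 case and 60 control samples, three planted
    pathway pairs at two within-class standard deviations of pair-level
    contrast, and two planted regulator miRNAs among 20.
    """

    n_genes: int = 1500
    n_pathways: int = 30
    genes_per_pathway: int = 15
    n_samples_case: int = 60
    n_samples_control: int = 60
    planted_pairs: tuple[tuple[int, int], ...] = ((0, 1), (2, 3), (4, 5))
    effect_size: float = 2.0
    n_mirnas: int = 20
    #: miRNA index -> tuple of target gene indices; None selects the
    #: default of two regulators, each repressing a disjoint gene block
    #: in the down-shifted pathway of every planted pair.
    planted_regulators: dict[int, tuple[int, ...]] | None = None
    regulation_strength: float = 0.9
    mirna_logfc: float = 1.5
    noise_sd: float = 0.5
    seed: int = 0
    # Balanced up/down differentially expressed genes per pathway (fraction
    # of members; shift magnitude on the log2 scale in cases).
    background_de_fraction: float = 0.5
    background_de_logfc: float = 1.6
    n_decoy_mirnas: int = 3
    #: fraction of a pathway's genes each default regulator represses
    regulator_target_fraction: float = 0.2
    #: sd of a per-(pathway, sample) shared activity factor added to every
    #: member gene — emulates within-pathway co-expression, which keeps
    #: pathway means noisy at realistic levels instead of averaging away
    pathway_noise_sd: float = 0.2
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    mirna_baseline_mean: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_pathways",
            "genes_per_pathway",
            "n_samples_case",
            "n_samples_control",
            "n_mirnas",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.regulation_strength <= 1:
            raise ValueError("regulation_strength must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError(
                "disjoint pathway blocks need n_pathways * genes_per_pathway "
                f"<= n_genes ({self.n_pathways} * {self.genes_per_pathway} > "
                f"{self.n_genes})"
            )
        for x, y in self.planted_pairs:
            if x == y:
                raise ValueError(f"planted pair ({x}, {y}) is degenerate")
            if not (0 <= x < self.n_pathways and 0 <= y < self.n_pathways):
                raise ValueError(f"planted pair ({x}, {y}) out of range")
        if self.planted_regulators is not None:
            for m, targets in self.planted_regulators.items():
                if not 0 <= m < self.n_mirnas:
                    raise ValueError(f"regulator miRNA index {m} out of range")
                for t in targets:
                    if not 0 <= t < self.n_genes:
                        raise ValueError(f"target gene index {t} out of range")
        if self.n_decoy_mirnas < 0:
            raise ValueError("n_decoy_mirnas must be >= 0")

    # -- naming ----------------------------------------------------------

    def gene_ids(self) -> list[str]:
        w = max(4, len(str(self.n_genes - 1)))
        return [f"g{i:0{w}d}" for i in range(self.n_genes)]

    def sample_ids(self) -> list[str]:
        case = [f"case_{i:03d}" for i in range(self.n_samples_case)]
        ctrl = [f"ctrl_{i:03d}" for i in range(self.n_samples_control)]
        return case + ctrl

    def pathway_names(self) -> list[str]:
        w = max(2, len(str(self.n_pathways - 1)))
        return [f"PW{i:0{w}d}" for i in range(self.n_pathways)]

    def mirna_ids(self) -> list[str]:
        w = max(2, len(str(self.n_mirnas - 1)))
        return [f"mir{i:0{w}d}" for i in range(self.n_mirnas)]

    def pathway_blocks(self) -> list[np.ndarray]:
        g = self.genes_per_pathway
        return [np.arange(p * g, (p + 1) * g) for p in range(self.n_pathways)]

    def default_regulators(
        self, oriented_pairs: tuple[tuple[int, int], ...]
    ) -> dict[int, tuple[int, ...]]:
        """Regulator layout for (up, down)-oriented planted pairs.

        Explicit ``planted_regulators`` win; otherwise two miRNAs each
        repress a disjoint block of ``regulator_target_fraction *
        genes_per_pathway`` genes in the down-shifted pathway of every
        planted pair, so each regulator couples to all planted pairs'
        pathways and its targets sit inside the expected cross-talk
        panel."""
        if self.planted_regulators is not None:
            return {m: tuple(t) for m, t in self.planted_regulators.items()}
        if not oriented_pairs:
            return {}
        regulators: dict[int, tuple[int, ...]] = {}
        blocks = self.pathway_blocks()
        n_t = max(2, round(self.regulator_target_fraction * self.genes_per_pathway))
        for m in range(min(2, self.n_mirnas)):
            lo, hi = m * n_t, (m + 1) * n_t
            targets = [int(t) for _, y in oriented_pairs for t in blocks[y][lo:hi]]
            if targets:
                regulators[m] = tuple(targets)
        return regulators


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, in output-ID space."""

    planted_pairs: frozenset[tuple[str, str]]
    regulator_mirnas: frozenset[str]
    regulator_targets: dict[str, frozenset[str]]
    background_de_genes: frozenset[str]
    decoy_mirnas: frozenset[str]

    def to_json_dict(self) -> dict:
        return {
            "planted_pairs": sorted(list(p) for p in self.planted_pairs),
            "regulator_mirnas": sorted(self.regulator_mirnas),
            "regulator_targets": {
                m: sorted(t) for m, t in sorted(self.regulator_targets.items())
            },
            "background_de_genes": sorted(self.background_de_genes),
            "decoy_mirnas": sorted(self.decoy_mirnas),
        }


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GeneSetCollection, Labels, GroundTruth]:
    """Generate one cohort: (genes, miRNAs, pathways, labels, ground truth).

    Matrices are returned on the raw (non-negative) scale; apply
    :func:`pathcrosstalk.differential_expression.log_transform` before
    analysis.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples_case + cfg.n_samples_control
    case_cols = np.arange(cfg.n_samples_case)

    gene_ids = cfg.gene_ids()
    sample_ids = cfg.sample_ids()
    pathway_names = cfg.pathway_names()
    mirna_ids = cfg.mirna_ids()
    blocks = cfg.pathway_blocks()

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    # pathway blocks share a common average baseline: genes within a
    # pathway keep their spread, but no pathway pair starts with a large
    # built-in mean gap, so |Mx - My| contrasts reflect class structure
    for block in blocks:
        baseline[block] += cfg.baseline_mean - baseline[block].mean()

    # orient each planted shift along the realized baseline gap: the
    # higher-baseline pathway goes up, the lower one down, so the case
    # shift always widens |Mx − My| instead of folding through zero
    block_means = [float(baseline[b].mean()) for b in blocks]
    oriented_pairs = tuple(
        (x, y) if block_means[x] >= block_means[y] else (y, x)
        for x, y in cfg.planted_pairs
    )

    # class-dependent mean shifts on the log2 scale, accumulated per gene
    shift = np.zeros((cfg.n_genes, n))

    half = 0.5 * cfg.effect_size * cfg.noise_sd
    for x, y in oriented_pairs:
        shift[np.ix_(blocks[x], case_cols)] += half
        shift[np.ix_(blocks[y], case_cols)] -= half

    background_idx: list[int] = []
    if cfg.background_de_fraction > 0 and cfg.background_de_logfc > 0:
        n_bg = 2 * round(cfg.background_de_fraction * cfg.genes_per_pathway / 2)
        for block in blocks:
            if n_bg == 0:
                break
            chosen = rng.choice(block, size=min(n_bg, len(block)), replace=False)
            k = len(chosen) // 2
            shift[np.ix_(chosen[:k], case_cols)] += cfg.background_de_logfc
            shift[np.ix_(chosen[k : 2 * k], case_cols)] -= cfg.background_de_logfc
            background_idx.extend(int(i) for i in chosen[: 2 * k])

    noise = rng.standard_normal((cfg.n_genes, n))

    # shared per-pathway activity (within-pathway co-expression)
    pathway_factor = np.zeros((cfg.n_genes, n))
    if cfg.pathway_noise_sd > 0:
        u = rng.normal(0.0, cfg.pathway_noise_sd, size=(cfg.n_pathways, n))
        for p, block in enumerate(blocks):
            pathway_factor[block] = u[p]

    # miRNAs
    mirna_baseline = rng.normal(cfg.mirna_baseline_mean, cfg.baseline_sd, cfg.n_mirnas)
    mirna_log = mirna_baseline[:, None] + cfg.noise_sd * rng.standard_normal(
        (cfg.n_mirnas, n)
    )
    regulators = cfg.default_regulators(oriented_pairs)
    decoys = [
        m
        for m in range(cfg.n_mirnas)
        if m not in regulators
    ][: cfg.n_decoy_mirnas]
    if cfg.mirna_logfc != 0:
        for m in sorted(set(regulators) | set(decoys)):
            mirna_log[m, case_cols] += cfg.mirna_logfc

    gene_log = baseline[:, None] + shift + pathway_factor + cfg.noise_sd * noise

    # regulator -> target coupling: replace part of the target's noise
    # with the miRNA's *within-class* fluctuation (negative sign =
    # repression). Coupling to within-class fluctuations rather than the
    # raw value keeps the miRNA's planted class shift out of its targets,
    # so miRNA-target dependence is attributable to regulation rather
    # than to both variables tracking the case/control split.
    rho = cfg.regulation_strength
    case_mask = np.zeros(n, dtype=bool)
    case_mask[case_cols] = True
    for m in sorted(regulators):
        x = mirna_log[m]
        centered = x - np.where(case_mask, x[case_mask].mean(), x[~case_mask].mean())
        sd = centered.std()
        if sd == 0:
            continue
        z = centered / sd
        for t in regulators[m]:
            gene_log[t] = (
                baseline[t]
                + shift[t]
                + pathway_factor[t]
                + cfg.noise_sd * (-math.sqrt(rho) * z + math.sqrt(1 - rho) * noise[t])
            )

    gene_raw = np.clip(np.exp2(gene_log) - 1.0, 0.0, None)
    mirna_raw = np.clip(np.exp2(mirna_log) - 1.0, 0.0, None)

    gene_em = ExpressionMatrix(
        pd.DataFrame(gene_raw, index=gene_ids, columns=sample_ids), scale_tag="raw"
    )
    mirna_em = ExpressionMatrix(
        pd.DataFrame(mirna_raw, index=mirna_ids, columns=sample_ids), scale_tag="raw"
    )
    gene_sets = GeneSetCollection(
        {
            pathway_names[p]: frozenset(gene_ids[i] for i in blocks[p])
            for p in range(cfg.n_pathways)
        },
        universe=frozenset(gene_ids),
    )
    labels = Labels(
        {
            s: (CASE if i < cfg.n_samples_case else CONTROL)
            for i, s in enumerate(sample_ids)
        }
    )
    truth = GroundTruth(
        planted_pairs=frozenset(
            tuple(sorted((pathway_names[x], pathway_names[y])))
            for x, y in cfg.planted_pairs
        ),
        regulator_mirnas=frozenset(mirna_ids[m] for m in regulators),
        regulator_targets={
            mirna_ids[m]: frozenset(gene_ids[t] for t in targets)
            for m, targets in regulators.items()
        },
        background_de_genes=frozenset(gene_ids[i] for i in background_idx),
        decoy_mirnas=frozenset(mirna_ids[m] for m in decoys),
    )
    return gene_em, mirna_em, gene_sets, labels, truth


def write_fixtures(
    gene_em: ExpressionMatrix,
    mirna_em: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    labels: Labels,
    truth: GroundTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write a cohort as plain-text files; returns the path of each artifact.

    Files round-trip losslessly through the readers in
    :mod:`pathcrosstalk.io`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "mirna": directory / "mirna.tsv",
        "labels": directory / "labels.tsv",
        "gmt": directory / "pathways.gmt",
        "ground_truth": directory / "ground_truth.json",
    }
    write_expression(gene_em, paths["expression"])
    write_expression(mirna_em, paths["mirna"])
    write_labels(labels, paths["labels"])
    write_gmt(gene_sets, paths["gmt"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A cohort with *no* class structure of any kind.

    All planted signals — pair shifts, background differential genes,
    miRNA class shifts, and regulator couplings — are zeroed, so every
    downstream discovery statistic should behave at its null level.
    """
    base = dict(
        n_genes=300,
        n_pathways=7,
        genes_per_pathway=10,
        n_samples_case=40,
        n_samples_control=40,
        planted_pairs=(),
        effect_size=0.0,
        n_mirnas=6,
        planted_regulators={},
        regulation_strength=0.0,
        mirna_logfc=0.0,
        background_de_fraction=0.0,
        n_decoy_mirnas=0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def regulator_recovery_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Scenario for miRNA regulator ranking: 2 regulators among 20 miRNAs,
    strong repression (90% of target variance), 100 samples per class."""
    base = dict(
        n_genes=250,
        n_pathways=10,
        genes_per_pathway=12,
        n_samples_case=100,
        n_samples_control=100,
        planted_pairs=((0, 1), (2, 3)),
        effect_size=0.0,
        background_de_fraction=0.0,
        n_mirnas=20,
        planted_regulators=None,
        regulator_target_fraction=0.35,
        regulation_strength=0.9,
        mirna_logfc=1.5,
        n_decoy_mirnas=3,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def small_pipeline_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A small end-to-end fixture covering every pipeline stage quickly."""
    base = dict(
        n_genes=300,
        n_pathways=8,
        genes_per_pathway=10,
        n_samples_case=40,
        n_samples_control=40,
        planted_pairs=((0, 1), (2, 3)),
        effect_size=2.0,
        background_de_fraction=0.6,
        n_mirnas=10,
        planted_regulators=None,
        regulator_target_fraction=0.3,
        regulation_strength=0.9,
        mirna_logfc=1.5,
        n_decoy_mirnas=0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)
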