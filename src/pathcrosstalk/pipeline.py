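"""End-to-end orchestration of the 4-step discovery workflow.

Per Monte-Carlo repeat (on a class-balanced, stratified 60/40 split):

1. differential expression of genes on the training samples;
2. Fisher enrichment of the differential genes in the pathway collection;
3. discriminating-score features for every pair of enriched pathways and
   random-forest ranking of the pairs on the training samples.

Repeats are then aggregated into top-position frequencies and the final
pathway-pair panel, whose joint model is evaluated on every repeat's
train/test split. Step 4 — differential miRNAs, mutual-information
target inference, panel enrichment and degree-centrality ranking — runs
once on the whole dataset, and the regulator network is assembled.

Every random draw derives from the master seed via
:func:`pathcrosstalk.seeds.derive_seed`, so a rerun with the same config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crosstalk import PAIR_SEP, CrosstalkFeatureMatrix, build_feature_matrix
from .differential_expression import differential_test, log_transform
from .enrichment import fisher_enrich
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    Labels,
    read_expression,
    read_gmt,
    read_labels,
    variance_filter,
    write_network,
)
from .mirna_network import (
    MiRNATargetMap,
    RegulatorNetwork,
    build_network,
    infer_targets,
    mirna_pathway_enrichment,
)
from .pair_selection import (
    MonteCarloPlan,
    aggregate_top,
    balance_classes,
    evaluate_panel,
    monte_carlo_split,
    rank_pairs,
)
from .seeds import derive_seed

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_pipeline_data"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the workflow (paths plus thresholds plus seeding)."""

    expression_path: str = ""
    mirna_path: str = ""
    labels_path: str = ""
    gmt_path: str = ""
    outdir: str = ""
    # preprocessing
    variance_quantile: float = 0.0
    pseudocount: float = 1.0
    # gene differential expression
    de_test: str = "wilcoxon"
    logfc_threshold: float = 1.0
    de_alpha: float = 0.01
    de_use_adjusted: bool = True
    # pathway enrichment (>= 1 disables the gate: all pathways retained)
    enrich_alpha: float = 0.01
    # Monte-Carlo pair selection
    n_repeats: int = 50
    train_fraction: float = 0.6
    inner_folds: int = 10
    top_m: int = 10
    rf_n_estimators: int = 100
    screen_top: int | None = 50
    # miRNA stage
    mirna_logfc_threshold: float = 1.0
    mirna_de_alpha: float = 0.01
    mi_k_neighbors: int = 3
    mi_permutations: int = 100
    mi_alpha: float = 0.01
    mirna_enrich_alpha: float = 0.01
    min_interactions: int = 2
    seed: int = 0

    def plan(self) -> MonteCarloPlan:
        return MonteCarloPlan(
            n_repeats=self.n_repeats,
            train_fraction=self.train_fraction,
            inner_folds=self.inner_folds,
            top_m=self.top_m,
            rf_n_estimators=self.rf_n_estimators,
            screen_top=self.screen_top,
            seed=self.seed,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of config keys")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class RepeatResult:
    repeat_index: int
    train_ids: list[str]
    test_ids: list[str]
    n_de_genes: int
    enriched_pathways: list[str]
    ranking: pd.DataFrame | None  # None when < 2 pathways were enriched


@dataclass
class PipelineResult:
    repeats: list[RepeatResult]
    aggregate: pd.DataFrame
    panel: list[str]
    panel_features: CrosstalkFeatureMatrix
    auc_report: pd.DataFrame  # repeat, auc_train, auc_test
    de_mirnas: pd.DataFrame
    target_map: MiRNATargetMap | None
    mirna_enrichment: dict[str, pd.DataFrame]
    network: RegulatorNetwork | None

    @property
    def auc_train_mean(self) -> float:
        return float(self.auc_report["auc_train"].mean())

    @property
    def auc_test_mean(self) -> float:
        return float(self.auc_report["auc_test"].mean())


def _panel_pathway_names(panel: list[str]) -> list[str]:
    names: list[str] = []
    for key in panel:
        for name in key.split(PAIR_SEP):
            if name not in names:
                names.append(name)
    return sorted(names)


def run_pipeline_data(
    gene_raw: ExpressionMatrix,
    mirna_raw: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    labels: Labels,
    config: PipelineConfig,
) -> PipelineResult:
    """Run the whole workflow on in-memory inputs."""
    labels.validate_against(gene_raw.sample_ids)
    seed = config.seed
    plan = config.plan()

    gene_log = log_transform(
        variance_filter(gene_raw, config.variance_quantile), config.pseudocount
    )
    mirna_log = log_transform(variance_filter(mirna_raw, 0.0), config.pseudocount)
    universe = frozenset(gene_log.feature_ids)
    measured_sets = gene_sets.restrict(universe, min_size=2)

    # --- steps 1-3, repeated on Monte-Carlo training sets ---------------
    repeats: list[RepeatResult] = []
    rankings: list[pd.DataFrame] = []
    for r in range(plan.n_repeats):
        balanced = balance_classes(labels, derive_seed(seed, "balance", r))
        bal_labels = labels.subset(balanced)
        train_ids, test_ids = monte_carlo_split(balanced, bal_labels, plan, r)

        de = differential_test(
            gene_log.subset_samples(train_ids),
            labels.subset(train_ids),
            test=config.de_test,
            logfc_threshold=config.logfc_threshold,
            alpha=config.de_alpha,
            use_adjusted=config.de_use_adjusted,
        )
        de_genes = set(de.loc[de["significant"], "feature_id"])

        if config.enrich_alpha >= 1:
            enriched = list(measured_sets.sets)
        elif de_genes:
            enr = fisher_enrich(
                de_genes, measured_sets, universe, alpha=config.enrich_alpha
            )
            enriched = enr.loc[enr["enriched"], "pathway"].tolist()
        else:
            enriched = []

        result = RepeatResult(r, train_ids, test_ids, len(de_genes), sorted(enriched), None)
        if len(enriched) >= 2:
            features = build_feature_matrix(
                gene_log.subset_samples(train_ids), measured_sets.subset(enriched)
            )
            result.ranking = rank_pairs(
                features, labels.subset(train_ids), plan, seed=derive_seed(seed, "rank", r)
            )
            rankings.append(result.ranking)
        else:
            logger.warning(
                "repeat %d: %d enriched pathways, skipping pair ranking", r, len(enriched)
            )
        repeats.append(result)

    if not rankings:
        raise RuntimeError(
            "pair selection failed: no repeat produced >= 2 enriched pathways"
        )
    aggregate, panel = aggregate_top(rankings, plan)

    # --- panel evaluation on every repeat's split -----------------------
    panel_features = build_feature_matrix(
        gene_log, measured_sets.subset(_panel_pathway_names(panel))
    ).subset_pairs(panel)
    auc_rows = []
    for rep in repeats:
        auc_train, auc_test = evaluate_panel(
            panel_features,
            panel,
            rep.train_ids,
            rep.test_ids,
            labels.subset(rep.train_ids + rep.test_ids),
            plan,
            seed=derive_seed(seed, "evaluate", rep.repeat_index),
        )
        auc_rows.append((rep.repeat_index, auc_train, auc_test))
    auc_report = pd.DataFrame(auc_rows, columns=["repeat", "auc_train", "auc_test"])

    # --- step 4: miRNA regulators, on the whole dataset -----------------
    de_mirnas = differential_test(
        mirna_log,
        labels,
        test=config.de_test,
        logfc_threshold=config.mirna_logfc_threshold,
        alpha=config.mirna_de_alpha,
        use_adjusted=True,
    )
    sig_mirnas = de_mirnas.loc[de_mirnas["significant"], "feature_id"].tolist()
    target_map = None
    mirna_enr: dict[str, pd.DataFrame] = {}
    network = None
    if sig_mirnas:
        target_map = infer_targets(
            mirna_log.subset_features(sig_mirnas),
            gene_log,
            k_neighbors=config.mi_k_neighbors,
            n_permutations=config.mi_permutations,
            alpha=config.mi_alpha,
            seed=derive_seed(seed, "mi"),
        )
        panel_sets = measured_sets.subset(_panel_pathway_names(panel))
        mirna_enr = mirna_pathway_enrichment(
            target_map, panel_sets, universe, alpha=config.mirna_enrich_alpha
        )
        network = build_network(
            panel_features.pairs,
            target_map,
            mirna_enr,
            pair_stats=aggregate,
            min_interactions=config.min_interactions,
        )
    else:
        logger.warning("no differentially expressed miRNAs; skipping network stage")

    return PipelineResult(
        repeats=repeats,
        aggregate=aggregate,
        panel=panel,
        panel_features=panel_features,
        auc_report=auc_report,
        de_mirnas=de_mirnas,
        target_map=target_map,
        mirna_enrichment=mirna_enr,
        network=network,
    )


def _write_outputs(result: PipelineResult, config: PipelineConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    per_repeat = pd.concat(
        [
            rep.ranking.assign(repeat=rep.repeat_index)[
                ["repeat", "pair", "auc", "rf_ranked"]
            ]
            for rep in result.repeats
            if rep.ranking is not None
        ],
        ignore_index=True,
    )
    per_repeat.to_csv(outdir / "per_repeat_rankings.tsv", sep="\t", index=False)
    counts["per_repeat_rankings"] = len(per_repeat)

    result.aggregate.to_csv(outdir / "pair_frequencies.tsv", sep="\t", index=False)
    counts["pair_frequencies"] = len(result.aggregate)

    with open(outdir / "panel.json", "w") as fh:
        json.dump(
            {
                "panel": result.panel,
                "auc_train_mean": result.auc_train_mean,
                "auc_test_mean": result.auc_test_mean,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    result.auc_report.to_csv(outdir / "auc_report.tsv", sep="\t", index=False)
    counts["auc_report"] = len(result.auc_report)

    result.de_mirnas.to_csv(outdir / "de_mirnas.tsv", sep="\t", index=False)
    counts["de_mirnas"] = int(result.de_mirnas["significant"].sum())

    if result.target_map is not None:
        targets = result.target_map.to_frame()
        targets.to_csv(outdir / "mirna_targets.tsv", sep="\t", index=False)
        counts["mirna_targets"] = len(targets)
    if result.network is not None:
        result.network.centrality.to_csv(
            outdir / "mirna_centrality.tsv", sep="\t", index=False
        )
        counts["mirna_centrality"] = len(result.network.centrality)
        write_network(result.network.graph, outdir / "network.graphml", "graphml")
        write_network(result.network.graph, outdir / "network_edges.tsv", "edge-tsv")
        counts["network_nodes"] = result.network.graph.number_of_nodes()
        counts["network_edges"] = result.network.graph.number_of_edges()
    return counts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load inputs from ``config`` paths, run the workflow, write the run
    directory (stage outputs + ``manifest.json``)."""
    for attr in ("expression_path", "mirna_path", "labels_path", "gmt_path", "outdir"):
        if not getattr(config, attr):
            raise ValueError(f"config.{attr} is required")
    for attr in ("expression_path", "mirna_path", "labels_path", "gmt_path"):
        if not Path(getattr(config, attr)).exists():
            raise FileNotFoundError(f"{attr}: {getattr(config, attr)}")

    gene_raw = read_expression(config.expression_path)
    mirna_raw = read_expression(config.mirna_path)
    labels = read_labels(config.labels_path)
    gene_sets = read_gmt(config.gmt_path)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # run log (DEBUG level, so every seed derivation is recorded); the
    # timestamp-free format keeps reruns byte-identical
    root = logging.getLogger("pathcrosstalk")
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    handler.setLevel(logging.DEBUG)
    old_level = root.level
    root.addHandler(handler)
    root.setLevel(logging.DEBUG)
    try:
        result = run_pipeline_data(gene_raw, mirna_raw, gene_sets, labels, config)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
    counts = _write_outputs(result, config, outdir)
    import scipy
    import sklearn

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "pathcrosstalk": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "row_counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
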