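"""miRNA regulator discovery: kNN mutual information, target-set pathway
enrichment, degree-centrality ranking, and regulator-network assembly.

Dependence between each differentially expressed miRNA and every gene is
quantified with the Kraskov-Stoegbauer-Grassberger (KSG) k-nearest-
neighbour mutual-information estimator (variant 1, Chebyshev metric,
nats). A gene is called "potentially regulated" when its MI exceeds the
(1 − alpha) quantile of a permutation null obtained by shuffling the
miRNA's sample vector. Each miRNA's putative target set is then tested
for over-representation in the selected pathway panel (Fisher's exact
test), and retained miRNAs are ranked by *degree centrality* — here, as
in the underlying method, the number of genes the miRNA regulates within
its coupled (enriched) panel pathways, not graph-theoretic node degree.

The estimator assumes continuous data; heavily tied inputs degrade the
neighbour counts (counts are clipped at zero rather than allowed to go
negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import digamma

from .crosstalk import PathwayPair
from .enrichment import fisher_enrich
from .io import ExpressionMatrix, GeneSetCollection
from .seeds import derive_seed

logger = logging.getLogger(__name__)

__all__ = [
    "MiRNATargetMap",
    "RegulatorNetwork",
    "mutual_information",
    "infer_targets",
    "mirna_pathway_enrichment",
    "degree_centrality",
    "build_network",
]

_CHUNK_ELEMENTS = 8_000_000  # ~64 MB of float64 pairwise distances per chunk


# ---------------------------------------------------------------------------
# KSG estimator
# ---------------------------------------------------------------------------


def _abs_diff(v: np.ndarray) -> np.ndarray:
    return np.abs(v[:, None] - v[None, :])


def _mi_batch(dx: np.ndarray, dys: np.ndarray, k: int, psi_table: np.ndarray) -> np.ndarray:
    """KSG-1 MI between one x (pairwise distances ``dx``, n×n) and a batch
    of y vectors (``dys``, g×n×n). Returns g estimates in nats, >= 0."""
    n = dx.shape[0]
    dz = np.maximum(dys, dx[None, :, :])
    # kth smallest including the zero self-distance = kth-neighbour distance
    eps = np.partition(dz, k, axis=2)[:, :, k]
    nx_ = (dx[None, :, :] < eps[:, :, None]).sum(axis=2) - 1
    ny_ = (dys < eps[:, :, None]).sum(axis=2) - 1
    np.clip(nx_, 0, None, out=nx_)
    np.clip(ny_, 0, None, out=ny_)
    mi = (
        digamma(k)
        + digamma(n)
        - (psi_table[nx_ + 1] + psi_table[ny_ + 1]).mean(axis=1)
    )
    return np.clip(mi, 0.0, None)


def mutual_information(x, y, k_neighbors: int = 3) -> float:
    """KSG k-nearest-neighbour mutual information estimate in nats.

    Non-negative by construction (small negative estimates are clipped).
    Constant vectors have zero MI with anything.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 10:
        raise ValueError("mutual_information needs at least 10 observations")
    if not 1 <= k_neighbors < n:
        raise ValueError("k_neighbors must satisfy 1 <= k < n")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    psi_table = digamma(np.arange(1, n + 1))
    psi_table = np.concatenate([[0.0], psi_table])  # 1-based index
    mi = _mi_batch(_abs_diff(x), _abs_diff(y)[None], k_neighbors, psi_table)
    return float(mi[0])


# ---------------------------------------------------------------------------
# Target inference
# ---------------------------------------------------------------------------


@dataclass
class MiRNATargetMap:
    """Declared miRNA -> target-gene calls with the supporting MI value."""

    targets: dict[str, dict[str, float]]
    k_neighbors: int
    n_permutations: int
    alpha: float

    def target_set(self, mirna: str) -> frozenset[str]:
        return frozenset(self.targets.get(mirna, ()))

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.targets)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m, g, mi)
            for m, genes in self.targets.items()
            for g, mi in sorted(genes.items())
        ]
        return pd.DataFrame(rows, columns=["mirna", "gene", "mi"])


def infer_targets(
    mirna_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    k_neighbors: int = 3,
    n_permutations: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
) -> MiRNATargetMap:
    """Permutation-calibrated MI target calls for each miRNA.

    For every (miRNA, gene) pair the KSG MI is compared with the
    ``(1 − alpha)`` quantile of the MI values obtained after shuffling the
    miRNA's sample vector ``n_permutations`` times; genes above their null
    quantile are declared potential targets. Deterministic given ``seed``.

    ``mirna_matrix`` should be restricted to the differentially expressed
    miRNAs beforehand; both matrices must share the same samples.
    """
    if mirna_matrix.n_features == 0:
        raise ValueError("no miRNAs to test (empty matrix)")
    if set(mirna_matrix.sample_ids) != set(gene_matrix.sample_ids):
        raise ValueError("miRNA and gene matrices must share their samples")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    samples = gene_matrix.sample_ids
    # float32 halves the memory traffic of the pairwise-distance batches;
    # expression values occupy a narrow range, so neighbour counts are
    # unaffected in practice
    mirna_values = mirna_matrix.subset_samples(samples).values.astype(np.float32)
    gene_values = gene_matrix.values.astype(np.float32)
    n = len(samples)
    if n < 10:
        raise ValueError("need at least 10 shared samples")
    n_genes = gene_values.shape[0]
    gene_ids = gene_matrix.feature_ids

    psi_table = np.concatenate([[0.0], digamma(np.arange(1, n + 1))])
    gene_constant = np.ptp(gene_values, axis=1) == 0
    chunk = max(1, _CHUNK_ELEMENTS // (n * n))
    rng = np.random.default_rng(derive_seed(seed, "mi-permutations"))

    out: dict[str, dict[str, float]] = {}
    for mi_idx, mirna in enumerate(mirna_matrix.feature_ids):
        x = mirna_values[mi_idx]
        if np.ptp(x) == 0:
            out[mirna] = {}
            continue
        perms = [rng.permutation(n) for _ in range(n_permutations)]
        dx = _abs_diff(x)
        observed = np.zeros(n_genes)
        null = np.zeros((n_permutations, n_genes))
        for start in range(0, n_genes, chunk):
            idx = np.arange(start, min(start + chunk, n_genes))
            idx = idx[~gene_constant[idx]]
            if idx.size == 0:
                continue
            dys = np.abs(
                gene_values[idx][:, :, None] - gene_values[idx][:, None, :]
            )
            observed[idx] = _mi_batch(dx, dys, k_neighbors, psi_table)
            for p, perm in enumerate(perms):
                dx_perm = dx[np.ix_(perm, perm)]
                null[p, idx] = _mi_batch(dx_perm, dys, k_neighbors, psi_table)
        threshold = np.quantile(null, 1 - alpha, axis=0, method="higher")
        declared = (observed > threshold) & ~gene_constant
        out[mirna] = {
            gene_ids[g]: float(observed[g]) for g in np.flatnonzero(declared)
        }
        logger.info("%s: %d putative targets", mirna, len(out[mirna]))
    return MiRNATargetMap(out, k_neighbors, n_permutations, alpha)


# ---------------------------------------------------------------------------
# Panel enrichment + centrality
# ---------------------------------------------------------------------------


def mirna_pathway_enrichment(
    target_map: MiRNATargetMap,
    panel_pathways: GeneSetCollection,
    universe,
    alpha: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """Fisher over-representation of each miRNA's targets in the panel
    pathways. miRNAs whose targets never reach the universe are skipped;
    a miRNA is *retained* when it is enriched in at least one pathway."""
    universe = frozenset(universe)
    results: dict[str, pd.DataFrame] = {}
    for mirna in target_map.mirna_ids:
        query = target_map.target_set(mirna) & universe
        if not query:
            continue
        results[mirna] = fisher_enrich(query, panel_pathways, universe, alpha=alpha)
    return results


def retained_mirnas(enrichment_results: dict[str, pd.DataFrame]) -> list[str]:
    return [
        m for m, df in enrichment_results.items() if bool(df["enriched"].any())
    ]


def degree_centrality(
    mirna: str,
    target_map: MiRNATargetMap,
    coupled_pathways: GeneSetCollection,
) -> tuple[int, int, int]:
    """``(n_regulated, n_total_genes, n_coupled_pathways)`` for one miRNA.

    ``coupled_pathways`` are the panel pathways in which the miRNA's
    targets are enriched, with gene sets already restricted to measured
    genes; ``n_regulated`` counts the miRNA's targets inside their union.
    """
    union: set[str] = set()
    for members in coupled_pathways.sets.values():
        union |= members
    n_regulated = len(target_map.target_set(mirna) & union)
    return n_regulated, len(union), len(coupled_pathways.sets)


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


@dataclass
class RegulatorNetwork:
    """Bipartite-ish network of panel pathways and regulator miRNAs.

    ``graph`` holds pathway nodes (``node_type="pathway"``), miRNA nodes
    (``node_type="mirna"``), pathway-pathway ``crosstalk`` edges and
    miRNA-pathway ``regulation`` edges. ``centrality`` ranks retained
    miRNAs by the number of genes they regulate within their coupled
    pathways. ``status`` is ``"empty"`` when the interaction filter
    removed everything.
    """

    graph: nx.Graph
    centrality: pd.DataFrame
    status: str = "ok"

    @property
    def pathway_nodes(self) -> list[str]:
        return [
            n for n, d in self.graph.nodes(data=True) if d.get("node_type") == "pathway"
        ]

    @property
    def mirna_nodes(self) -> list[str]:
        return [
            n for n, d in self.graph.nodes(data=True) if d.get("node_type") == "mirna"
        ]

    def top_regulators(self, n: int = 3) -> list[str]:
        return self.centrality["mirna"].head(n).tolist()


def build_network(
    panel_pairs: list[PathwayPair],
    target_map: MiRNATargetMap,
    enrichment_results: dict[str, pd.DataFrame],
    pair_stats: pd.DataFrame | None = None,
    min_interactions: int = 2,
) -> RegulatorNetwork:
    """Assemble the cross-talk network and rank regulators.

    Nodes are the panel pathways plus every retained miRNA; edges are the
    panel pairs (``crosstalk``) and the miRNA -> enriched-pathway links
    (``regulation``, annotated with the enrichment p and overlap size).
    Pathway nodes with fewer than ``min_interactions`` total edges are
    removed once, then isolated nodes are dropped. Degree centrality is
    computed over each miRNA's coupled pathways that survive the filter.
    """
    if not panel_pairs:
        raise ValueError("panel is empty")
    pathway_genes: dict[str, frozenset[str]] = {}
    for pair in panel_pairs:
        pathway_genes.setdefault(pair.name_x, pair.genes_x)
        pathway_genes.setdefault(pair.name_y, pair.genes_y)

    graph = nx.Graph()
    for name in sorted(pathway_genes):
        graph.add_node(name, node_type="pathway", n_genes=len(pathway_genes[name]))
    stats_by_pair = {}
    if pair_stats is not None:
        stats_by_pair = {
            row.pair: row for row in pair_stats.itertuples(index=False)
        }
    for pair in panel_pairs:
        attrs = {"edge_type": "crosstalk"}
        row = stats_by_pair.get(pair.key)
        if row is not None:
            attrs["frequency"] = int(row.frequency)
            attrs["mean_auc"] = float(row.mean_auc)
        graph.add_edge(pair.name_x, pair.name_y, **attrs)

    kept = retained_mirnas(enrichment_results)
    mirna_pathways: dict[str, list[str]] = {}
    for mirna in kept:
        df = enrichment_results[mirna]
        enriched = df.loc[df["enriched"]]
        graph.add_node(mirna, node_type="mirna")
        names = []
        for row in enriched.itertuples(index=False):
            if row.pathway in graph:
                graph.add_edge(
                    mirna,
                    row.pathway,
                    edge_type="regulation",
                    p=float(row.p),
                    n_target_genes=int(row.k_overlap),
                )
                names.append(row.pathway)
        mirna_pathways[mirna] = names

    # single-pass interaction filter on pathway nodes, then drop isolates
    weak = [
        n
        for n, d in graph.nodes(data=True)
        if d.get("node_type") == "pathway" and graph.degree(n) < min_interactions
    ]
    graph.remove_nodes_from(weak)
    graph.remove_nodes_from(list(nx.isolates(graph)))

    rows = []
    for mirna in kept:
        if mirna not in graph:
            continue
        coupled_names = [p for p in mirna_pathways[mirna] if p in graph]
        if coupled_names:
            coupled = GeneSetCollection({p: pathway_genes[p] for p in coupled_names})
            n_reg, n_tot, n_cpl = degree_centrality(mirna, target_map, coupled)
        else:
            n_reg, n_tot, n_cpl = 0, 0, 0
        df = enrichment_results[mirna]
        min_p = float(df.loc[df["enriched"], "p"].min()) if df["enriched"].any() else float("nan")
        rows.append((mirna, n_reg, n_tot, n_cpl, min_p))
        graph.nodes[mirna]["n_regulated"] = n_reg
        graph.nodes[mirna]["n_total_genes"] = n_tot
        graph.nodes[mirna]["n_coupled_pathways"] = n_cpl
    centrality = pd.DataFrame(
        rows,
        columns=["mirna", "n_regulated", "n_total_genes", "n_coupled_pathways", "min_p"],
    ).sort_values(
        ["n_regulated", "min_p", "mirna"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)

    status = "ok" if graph.number_of_nodes() else "empty"
    return RegulatorNetwork(graph, centrality, status)
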