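"""Per-sample discriminating score (DS) features for pathway pairs.

For a pair of pathways (x, y) and one sample, let M and SD be the mean
and (n−1) standard deviation of the sample's log2 expression over each
pathway's member genes. The discriminating score

    DS = |Mx − My| / (SDx + SDy)

contrasts the two pathways' average activity in that sample, normalised
by their internal spread. Computed for every unordered pair of enriched
pathways and every sample, the DS values form a samples × pairs feature
matrix on which pathway-pair cross-talk is ranked by its power to
discriminate cases from controls.

A small epsilon guards the denominator so constant pathways yield a
large but finite score instead of a division error.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

__all__ = ["PathwayPair", "CrosstalkFeatureMatrix", "ds_score", "build_feature_matrix", "PAIR_SEP"]

#: separator used in "pathwayX|pathwayY" column names
PAIR_SEP = "|"

_DEFAULT_EPS = 1e-12


@dataclass(frozen=True)
class PathwayPair:
    """An unordered pathway pair in canonical (lexicographic) order."""

    name_x: str
    name_y: str
    genes_x: frozenset[str]
    genes_y: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name_x < self.name_y:
            raise ValueError(
                f"pair names must be in canonical order: {self.name_x!r} < {self.name_y!r}"
            )
        if len(self.genes_x) < 2 or len(self.genes_y) < 2:
            raise ValueError("each pathway of a pair needs >= 2 measured genes")

    @property
    def key(self) -> str:
        return f"{self.name_x}{PAIR_SEP}{self.name_y}"

    @property
    def gene_union(self) -> frozenset[str]:
        return self.genes_x | self.genes_y


@dataclass
class CrosstalkFeatureMatrix:
    """Samples × pathway-pairs matrix of DS values."""

    pairs: list[PathwayPair]
    ds: pd.DataFrame  # rows: samples, columns: pair keys

    def __post_init__(self) -> None:
        keys = [p.key for p in self.pairs]
        if keys != list(self.ds.columns):
            raise ValueError("pair order and DS columns disagree")
        values = self.ds.to_numpy()
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValueError("DS values must be finite and >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ds.index)

    def subset_samples(self, sample_ids) -> "CrosstalkFeatureMatrix":
        return CrosstalkFeatureMatrix(self.pairs, self.ds.loc[list(sample_ids)])

    def subset_pairs(self, keys) -> "CrosstalkFeatureMatrix":
        keys = list(keys)
        by_key = {p.key: p for p in self.pairs}
        return CrosstalkFeatureMatrix([by_key[k] for k in keys], self.ds[keys])


def ds_score(values_x, values_y, epsilon: float = _DEFAULT_EPS) -> float:
    """Discriminating score between two value vectors (one sample's
    member-gene expression for each pathway).

    ``|mean(x) − mean(y)| / (sd(x) + sd(y) + epsilon)`` with sample
    (n−1) standard deviations.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("ds_score needs at least 2 values on each side")
    return float(
        abs(x.mean() - y.mean()) / (x.std(ddof=1) + y.std(ddof=1) + epsilon)
    )


def build_feature_matrix(
    matrix: ExpressionMatrix,
    pathways: GeneSetCollection,
    epsilon: float = _DEFAULT_EPS,
) -> CrosstalkFeatureMatrix:
    """DS features for every unordered pair of pathways, per sample.

    ``pathways`` is typically the enriched subset of the full collection.
    Each pathway is intersected with the measured genes; pathways with
    fewer than 2 measured genes are dropped, and pairs whose measured
    gene sets coincide are excluded.
    """
    if matrix.scale_tag != "log2":
        raise ValueError("build_feature_matrix expects log2-scale values")
    measured = frozenset(matrix.feature_ids)
    usable = {
        name: members & measured
        for name, members in pathways.sets.items()
        if len(members & measured) >= 2
    }
    if len(usable) < 2:
        raise ValueError("need at least 2 pathways with >= 2 measured genes")

    names = sorted(usable)
    row_of = {g: i for i, g in enumerate(matrix.feature_ids)}
    values = matrix.values
    n_samples = matrix.n_samples
    M = np.empty((len(names), n_samples))
    SD = np.empty((len(names), n_samples))
    for i, name in enumerate(names):
        rows = [row_of[g] for g in sorted(usable[name])]
        sub = values[rows]
        M[i] = sub.mean(axis=0)
        SD[i] = sub.std(axis=0, ddof=1)

    pairs: list[PathwayPair] = []
    columns: dict[str, np.ndarray] = {}
    for i, j in combinations(range(len(names)), 2):
        if usable[names[i]] == usable[names[j]]:
            continue
        pair = PathwayPair(names[i], names[j], usable[names[i]], usable[names[j]])
        pairs.append(pair)
        columns[pair.key] = np.abs(M[i] - M[j]) / (SD[i] + SD[j] + epsilon)
    if not pairs:
        raise ValueError("no valid pathway pairs (all measured gene sets identical)")
    ds = pd.DataFrame(columns, index=matrix.sample_ids)
    return CrosstalkFeatureMatrix(pairs, ds)
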