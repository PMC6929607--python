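"""Readers/writers for expression matrices, labels, GMT gene sets and networks.

All tabular formats are plain TSV. Readers validate and reject malformed
input (duplicate IDs, non-numeric cells, missing values) rather than
silently coercing; writers round-trip numeric content exactly (floats are
serialized with 17 significant digits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed input file (carries file and, where known, line context)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A features × samples numeric matrix.

    Parameters
    ----------
    data
        DataFrame with unique feature IDs as index and unique sample IDs as
        columns. No missing values are allowed.
    scale_tag
        ``"raw"`` for non-negative expression values (e.g. normalized
        counts), ``"log2"`` after log transformation.
    """

    data: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("raw", "log2"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ParseError(f"duplicate feature IDs: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample IDs: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParseError("expression values must be numeric")
        if np.isnan(values).any():
            g, s = np.argwhere(np.isnan(values))[0]
            raise ParseError(
                f"missing value at feature {idx[g]!r}, sample {cols[s]!r}"
            )
        if self.scale_tag == "raw" and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ParseError(
                f"negative raw value at feature {idx[g]!r}, sample {cols[s]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown sample IDs: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data[sample_ids], scale_tag=self.scale_tag)

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        feature_ids = list(feature_ids)
        missing = set(feature_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown feature IDs: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            self.data.loc[feature_ids], scale_tag=self.scale_tag
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with an optional explicit gene universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def effective_universe(self) -> frozenset[str]:
        if self.universe is not None:
            return self.universe
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def restrict(self, genes: Iterable[str], min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with ``genes``; drop sets below ``min_size``."""
        genes = frozenset(genes)
        kept = {
            name: members & genes
            for name, members in self.sets.items()
            if len(members & genes) >= min_size
        }
        return GeneSetCollection(kept, universe=genes)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self.sets[n] for n in names}, universe=self.universe
        )


@dataclass
class Labels:
    """Two-class (case/control) sample annotation."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in (CASE, CONTROL)}
        if bad:
            raise ValueError(
                f"labels must be {CASE!r} or {CONTROL!r}; found {sorted(bad)}"
            )
        if not self.case_ids or not self.control_ids:
            raise ValueError("both classes must be non-empty")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mapping)

    @property
    def case_ids(self) -> list[str]:
        return [s for s, c in self.mapping.items() if c == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, c in self.mapping.items() if c == CONTROL]

    def y(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Binary vector (case=1) in the order of ``sample_ids``."""
        return np.array(
            [1 if self.mapping[s] == CASE else 0 for s in sample_ids], dtype=int
        )

    def validate_against(self, sample_ids: Iterable[str]) -> None:
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.mapping)
        if missing:
            raise ValueError(
                f"samples without labels: {sorted(missing)[:5]}"
            )
        extra = set(self.mapping) - set(sample_ids)
        if extra:
            raise ValueError(
                f"labelled samples absent from matrix: {sorted(extra)[:5]}"
            )

    def subset(self, sample_ids: Iterable[str]) -> "Labels":
        return Labels({s: self.mapping[s] for s in sample_ids})


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, scale_tag: str = "raw") -> ExpressionMatrix:
    """Read a features × samples TSV (first column feature ID, header row
    sample IDs)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature IDs {dup[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        # +2: one for the header row, one for 1-based numbering
        raise ParseError(
            f"{path}, line {g + 2}: non-numeric value {df.iat[g, s]!r} "
            f"for feature {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if numeric.isna().to_numpy().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}, line {g + 2}: missing value for feature "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    # pd.to_numeric is used only to locate bad cells; numpy's string cast
    # is correctly rounded, keeping write -> read round trips exact
    values = df.to_numpy(dtype=str).astype(np.float64)
    exact = pd.DataFrame(values, index=df.index, columns=df.columns)
    return ExpressionMatrix(exact, scale_tag=scale_tag)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Labels TSV
# ---------------------------------------------------------------------------


def read_labels(path: str | Path) -> Labels:
    """Read a two-column TSV: sample ID, class (``case`` / ``control``).

    A header line ``sample_id\\tclass`` is accepted and skipped.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}, line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            sample, cls = parts
            if lineno == 1 and cls not in (CASE, CONTROL):
                continue  # header
            if sample in mapping:
                raise ParseError(f"{path}, line {lineno}: duplicate sample {sample!r}")
            if cls not in (CASE, CONTROL):
                raise ParseError(
                    f"{path}, line {lineno}: class must be {CASE!r} or "
                    f"{CONTROL!r}, got {cls!r}"
                )
            mapping[sample] = cls
    if not mapping:
        raise ParseError(f"{path}: no labels found")
    return Labels(mapping)


def write_labels(labels: Labels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for sample, cls in labels.mapping.items():
            fh.write(f"{sample}\t{cls}\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, member genes; tab-separated)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}, line {lineno}: GMT lines need >= 3 fields "
                    f"(name, description, members), got {len(parts)}"
                )
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}, line {lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise ParseError(f"{path}, line {lineno}: set {name!r} has no members")
            sets[name] = members
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def write_gmt(
    collection: GeneSetCollection, path: str | Path, description: str = "na"
) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Variance filter
# ---------------------------------------------------------------------------


def variance_filter(matrix: ExpressionMatrix, q: float = 0.0) -> ExpressionMatrix:
    """Drop low-variance features.

    Removes features whose across-sample variance falls below the ``q``-th
    quantile of all feature variances; zero-variance (constant) features are
    always removed. ``q=0`` therefore drops only constant features.
    """
    if not 0 <= q < 1:
        raise ValueError(f"q must be in [0, 1), got {q}")
    variances = matrix.data.var(axis=1, ddof=1)
    cutoff = float(np.quantile(variances.to_numpy(), q)) if q > 0 else 0.0
    keep = (variances > 0) & (variances >= cutoff)
    return ExpressionMatrix(matrix.data.loc[keep], scale_tag=matrix.scale_tag)


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "sif", "edge-tsv")


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Serialize a pathway/miRNA network.

    Node attribute ``node_type`` (``pathway`` / ``mirna``) and edge attribute
    ``edge_type`` (``crosstalk`` / ``regulation``) plus any numeric edge
    attributes (p-values, gene counts) are preserved in GraphML and edge-TSV;
    SIF keeps only the edge type as the relation.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, attrs in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{attrs.get('edge_type', 'edge')}\t{v}\n")
    elif fmt == "edge-tsv":
        attr_names = sorted(
            {k for _, _, a in graph.edges(data=True) for k in a} - {"edge_type"}
        )
        with open(path, "w") as fh:
            fh.write("\t".join(["source", "target", "edge_type", *attr_names]) + "\n")
            for u, v, attrs in sorted(graph.edges(data=True)):
                row = [str(u), str(v), str(attrs.get("edge_type", ""))]
                row += [str(attrs.get(k, "")) for k in attr_names]
                fh.write("\t".join(row) + "\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}; use one of {NETWORK_FORMATS}")
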