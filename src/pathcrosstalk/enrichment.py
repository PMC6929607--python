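"""Fisher's exact over-representation analysis of a query gene set.

Given a query (differentially expressed genes, or a miRNA's putative
targets), each pathway is tested for over-representation with the
one-sided Fisher exact test, i.e. the upper hypergeometric tail
``P(X >= k)`` of the 2×2 table

====================  ============  ==============
..                    in pathway    not in pathway
====================  ============  ==============
in query              k             n − k
not in query          K − k         N − K − n + k
====================  ============  ==============

with N the measured-gene universe, K the pathway size within the
universe, and n the query size within the universe. By default the raw
p-value is thresholded (no multiple-testing correction across pathways);
a BH-adjusted option is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential_expression import bh_adjust
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "fisher_enrich"]


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    k_overlap: int
    K_pathway: int
    n_query: int
    N_universe: int
    p: float
    enriched: bool


def fisher_enrich(
    query,
    sets: GeneSetCollection,
    universe,
    alpha: float = 0.01,
    adjust: bool = False,
) -> pd.DataFrame:
    """One-sided over-representation of ``query`` in each gene set.

    Query members outside the universe are dropped (their count is
    logged); pathway memberships are likewise intersected with the
    universe. Results are sorted by p-value (ties by pathway name).

    Returns a DataFrame with columns
    ``pathway, k_overlap, K_pathway, n_query, N_universe, p, enriched``.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = frozenset(query)
    if not query:
        raise ValueError("query gene set is empty")
    dropped = len(query - universe)
    if dropped:
        logger.warning("%d query genes outside the universe were dropped", dropped)
    query &= universe
    if not query:
        raise ValueError("no query genes remain inside the universe")

    N = len(universe)
    n = len(query)
    rows = []
    for name, members in sets.sets.items():
        members = members & universe
        K = len(members)
        k = len(query & members)
        # upper tail P(X >= k) of Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["pathway", "k_overlap", "K_pathway", "n_query", "N_universe", "p"]
    )
    p_used = bh_adjust(df["p"].to_numpy()) if adjust else df["p"].to_numpy()
    df["enriched"] = p_used < alpha
    df = df.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
    return df
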