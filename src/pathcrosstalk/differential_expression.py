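"""Two-class differential expression on log2 expression values.

The test statistic is distribution-light by design: a two-sided Wilcoxon
rank-sum (Mann-Whitney) test per feature, exact for small tie-free classes
and normal-approximated with tie correction otherwise, or Welch's t as an
alternative. Log2 fold change is the difference of class means on the
log2 scale, and p-values are adjusted with the Benjamini-Hochberg step-up
procedure. A feature is flagged significant when |log2FC| exceeds the
fold-change threshold and the (adjusted, by default) p-value is below
alpha — the conventional volcano-plot rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CASE, ExpressionMatrix, Labels

__all__ = ["log_transform", "differential_test", "bh_adjust"]

#: largest per-class size for which the exact Wilcoxon null is used
_EXACT_MAX_N = 25

TESTS = ("wilcoxon", "welch")


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return ``log2(value + pseudocount)`` with ``scale_tag="log2"``.

    Refuses to transform twice (``scale_tag`` must be ``"raw"``).
    """
    if matrix.scale_tag != "raw":
        raise ValueError(f"matrix is already on the {matrix.scale_tag} scale")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (matrix.values < 0).any():
        raise ValueError("raw expression values must be non-negative")
    return ExpressionMatrix(
        np.log2(matrix.data + pseudocount), scale_tag="log2"
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Values are monotone-enforced and clipped to 1; a single p-value is
    returned unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _wilcoxon_pvalues(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Mann-Whitney p per row of (features × samples)."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    constant = np.ptp(np.hstack([case, ctrl]), axis=1) == 0
    p = np.ones(case.shape[0])
    active = ~constant
    if active.any():
        if max(n1, n2) <= _EXACT_MAX_N:
            # small classes: exact null where the data are tie-free
            for i in np.flatnonzero(active):
                x, y = case[i], ctrl[i]
                pooled = np.concatenate([x, y])
                method = "exact" if np.unique(pooled).size == pooled.size else "asymptotic"
                p[i] = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        else:
            res = stats.mannwhitneyu(
                case[active], ctrl[active], alternative="two-sided",
                method="asymptotic", axis=1,
            )
            p[active] = np.nan_to_num(res.pvalue, nan=1.0)
    return np.clip(p, 0.0, 1.0)


def differential_test(
    matrix: ExpressionMatrix,
    labels: Labels,
    test: str = "wilcoxon",
    logfc_threshold: float = 1.0,
    alpha: float = 0.01,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Per-feature two-class differential expression.

    Parameters
    ----------
    matrix
        Log2-scale expression (features × samples).
    labels
        Case/control assignment covering exactly the matrix samples.
    test
        ``"wilcoxon"`` (rank-sum; default) or ``"welch"`` (unequal-variance t).
    logfc_threshold, alpha
        Significance rule: ``|log2fc| > logfc_threshold`` and
        ``p < alpha``, where ``p`` is the BH-adjusted p-value unless
        ``use_adjusted=False``.

    Returns
    -------
    DataFrame with columns ``feature_id, log2fc, p_raw, p_adj, significant``
    in the matrix's feature order.
    """
    if matrix.scale_tag != "log2":
        raise ValueError("differential_test expects log2-scale values")
    if test not in TESTS:
        raise ValueError(f"test must be one of {TESTS}")
    labels.validate_against(matrix.sample_ids)
    case_ids, ctrl_ids = labels.case_ids, labels.control_ids
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("each class needs at least 2 samples")

    case = matrix.data[case_ids].to_numpy()
    ctrl = matrix.data[ctrl_ids].to_numpy()
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)

    if test == "wilcoxon":
        p_raw = _wilcoxon_pvalues(case, ctrl)
    else:
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        p_raw = np.nan_to_num(res.pvalue, nan=1.0)  # constant features -> 1

    p_adj = bh_adjust(p_raw)
    p_used = p_adj if use_adjusted else p_raw
    significant = (np.abs(log2fc) > logfc_threshold) & (p_used < alpha)
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": significant,
        }
    )
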