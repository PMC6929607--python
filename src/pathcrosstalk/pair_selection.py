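"""Monte-Carlo cross-validated pathway-pair ranking and panel selection.

The selection protocol repeats, ``n_repeats`` times on freshly drawn
class-balanced 60/40 train/test partitions: rank every pathway pair by
the stratified k-fold (k=10 by default) cross-validated AUC of a random
forest fit on that pair's single discriminating-score feature, and record
the top ``top_m`` pairs. Pairs are then aggregated by how often they
reached the top positions, and the ``top_m`` most frequent pairs form the
final panel, whose joint random-forest model is evaluated on the training
split (cross-validated) and the held-out test split.

Because a full random-forest cross-validation for every one of possibly
hundreds of pairs in every repeat is the dominant cost, ranking first
computes each pair's rank-statistic (Mann-Whitney) AUC — the population
quantity the forest estimates for a single monotone-ish feature — and
runs the full forest cross-validation only for the best ``screen_top``
candidates; the remaining pairs keep their rank-statistic AUC. The
screen is wide relative to ``top_m``, so the reported top positions are
always forest-ranked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .crosstalk import CrosstalkFeatureMatrix
from .io import Labels
from .seeds import derive_seed

__all__ = [
    "MonteCarloPlan",
    "balance_classes",
    "monte_carlo_split",
    "rank_pairs",
    "aggregate_top",
    "evaluate_panel",
    "rank_auc",
]


@dataclass(frozen=True)
class MonteCarloPlan:
    """Parameters of the Monte-Carlo cross-validation protocol."""

    n_repeats: int = 50
    train_fraction: float = 0.6
    inner_folds: int = 10
    top_m: int = 10
    rf_n_estimators: int = 100
    #: run full RF cross-validation for this many top candidates per repeat
    #: (None = all pairs)
    screen_top: int | None = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.top_m < 1:
            raise ValueError("top_m must be >= 1")
        if self.rf_n_estimators < 1:
            raise ValueError("rf_n_estimators must be >= 1")
        if self.screen_top is not None and self.screen_top < self.top_m:
            raise ValueError("screen_top must be >= top_m")


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC of ``scores`` for labels ``y`` via the Mann-Whitney identity
    (average ranks handle ties)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def balance_classes(labels: Labels, seed: int) -> list[str]:
    """All minority-class samples plus an equally sized uniform random
    subset of the majority class; order follows the labels."""
    case_ids, ctrl_ids = labels.case_ids, labels.control_ids
    rng = np.random.default_rng(seed)
    if len(case_ids) == len(ctrl_ids):
        chosen = set(case_ids) | set(ctrl_ids)
    else:
        minority, majority = sorted([case_ids, ctrl_ids], key=len)
        keep = rng.choice(len(majority), size=len(minority), replace=False)
        chosen = set(minority) | {majority[i] for i in keep}
    return [s for s in labels.sample_ids if s in chosen]


def monte_carlo_split(
    sample_ids: Sequence[str],
    labels: Labels,
    plan: MonteCarloPlan,
    repeat_index: int,
) -> tuple[list[str], list[str]]:
    """One stratified train/test partition, a deterministic function of
    ``(plan.seed, repeat_index)``.

    The per-class training size is ``round(train_fraction * n_class)``
    (clamped so both sides of the split are non-empty).
    """
    rng = np.random.default_rng(derive_seed(plan.seed, "split", repeat_index))
    train: list[str] = []
    test: list[str] = []
    for cls_ids in (labels.case_ids, labels.control_ids):
        ids = [s for s in sample_ids if s in set(cls_ids)]
        if len(ids) < 2:
            raise ValueError("each class needs >= 2 samples to stratify")
        n_train = int(np.clip(round(plan.train_fraction * len(ids)), 1, len(ids) - 1))
        order = rng.permutation(len(ids))
        train.extend(ids[i] for i in order[:n_train])
        test.extend(ids[i] for i in order[n_train:])
    return sorted(train), sorted(test)


def _rf_cv_auc(
    x: np.ndarray, y: np.ndarray, plan: MonteCarloPlan, rf_seed: int, cv_seed: int
) -> float:
    """Mean across stratified folds of the out-of-fold RF AUC for a single
    feature. Constant features score 0.5 by definition."""
    if np.ptp(x) == 0:
        return 0.5
    skf = StratifiedKFold(
        n_splits=plan.inner_folds, shuffle=True, random_state=cv_seed
    )
    X = x.reshape(-1, 1)
    fold_aucs = []
    for train_idx, test_idx in skf.split(X, y):
        rf = RandomForestClassifier(
            n_estimators=plan.rf_n_estimators, random_state=rf_seed, n_jobs=1
        )
        rf.fit(X[train_idx], y[train_idx])
        proba = rf.predict_proba(X[test_idx])[:, 1]
        fold_aucs.append(rank_auc(proba, y[test_idx]))
    return float(np.mean(fold_aucs))


def rank_pairs(
    features: CrosstalkFeatureMatrix,
    labels: Labels,
    plan: MonteCarloPlan,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rank every pathway pair by single-feature classification AUC.

    Returns a DataFrame ``pair, auc, rf_ranked`` sorted by AUC descending
    (ties broken by canonical pair name); ``rf_ranked`` marks pairs whose
    AUC came from the full random-forest cross-validation rather than the
    rank-statistic screen.
    """
    seed = plan.seed if seed is None else seed
    y = labels.subset(features.sample_ids).y(features.sample_ids)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if min(n1, n0) < plan.inner_folds:
        raise ValueError(
            f"need >= inner_folds={plan.inner_folds} samples per class, "
            f"got {n1} cases / {n0} controls"
        )
    X = features.ds.to_numpy()
    keys = list(features.ds.columns)

    # screen: folded rank AUC (direction-free) per pair, fully vectorized
    ranks = rankdata(X, axis=0)
    u = ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2
    raw_auc = u / (n1 * n0)
    folded = np.maximum(raw_auc, 1 - raw_auc)
    folded[np.ptp(X, axis=0) == 0] = 0.5

    order = sorted(range(len(keys)), key=lambda i: (-folded[i], keys[i]))
    n_cand = len(keys) if plan.screen_top is None else min(plan.screen_top, len(keys))
    candidates = set(order[:n_cand])

    cv_seed = derive_seed(seed, "cv")
    auc = folded.copy()
    rf_ranked = np.zeros(len(keys), dtype=bool)
    for i in candidates:
        auc[i] = _rf_cv_auc(X[:, i], y, plan, derive_seed(seed, "rf", keys[i]), cv_seed)
        rf_ranked[i] = True

    df = pd.DataFrame({"pair": keys, "auc": auc, "rf_ranked": rf_ranked})
    return (
        df.sort_values(["auc", "pair"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def aggregate_top(
    rankings: Sequence[pd.DataFrame], plan: MonteCarloPlan
) -> tuple[pd.DataFrame, list[str]]:
    """Aggregate per-repeat rankings into top-position frequencies.

    Returns ``(aggregate, panel)`` where ``aggregate`` has columns
    ``pair, frequency, mean_auc`` (frequency = number of repeats in which
    the pair reached the top ``top_m`` positions; mean AUC over the
    repeats where the pair was ranked at all) and ``panel`` is the
    ``top_m`` pairs by frequency (ties by mean AUC, then name).
    """
    if not rankings:
        raise ValueError("at least one repeat ranking required")
    freq: dict[str, int] = {}
    aucs: dict[str, list[float]] = {}
    for ranking in rankings:
        for rank, row in enumerate(ranking.itertuples(index=False)):
            aucs.setdefault(row.pair, []).append(row.auc)
            if rank < plan.top_m:
                freq[row.pair] = freq.get(row.pair, 0) + 1
    rows = [
        (pair, freq.get(pair, 0), float(np.mean(vals)))
        for pair, vals in aucs.items()
    ]
    agg = pd.DataFrame(rows, columns=["pair", "frequency", "mean_auc"])
    agg = agg.sort_values(
        ["frequency", "mean_auc", "pair"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    panel = agg.loc[agg["frequency"] > 0, "pair"].head(plan.top_m).tolist()
    return agg, panel


def evaluate_panel(
    features: CrosstalkFeatureMatrix,
    panel: Sequence[str],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    labels: Labels,
    plan: MonteCarloPlan,
    seed: int | None = None,
) -> tuple[float, float]:
    """Joint random-forest model on the panel's DS features.

    Returns ``(auc_train, auc_test)``: the stratified ``inner_folds``-fold
    cross-validated AUC on the training samples, and the AUC of the
    train-fit model on the held-out test samples.
    """
    if not panel:
        raise ValueError("panel is empty")
    seed = plan.seed if seed is None else seed
    panel = list(panel)
    train_ids, test_ids = list(train_ids), list(test_ids)
    Xtr = features.ds.loc[train_ids, panel].to_numpy()
    Xte = features.ds.loc[test_ids, panel].to_numpy()
    ytr = labels.subset(train_ids).y(train_ids)
    yte = labels.subset(test_ids).y(test_ids)

    rf_seed = derive_seed(seed, "panel-rf")
    skf = StratifiedKFold(
        n_splits=plan.inner_folds, shuffle=True, random_state=derive_seed(seed, "panel-cv")
    )
    fold_aucs = []
    for tr, te in skf.split(Xtr, ytr):
        rf = RandomForestClassifier(
            n_estimators=plan.rf_n_estimators, random_state=rf_seed, n_jobs=1
        )
        rf.fit(Xtr[tr], ytr[tr])
        fold_aucs.append(rank_auc(rf.predict_proba(Xtr[te])[:, 1], ytr[te]))
    auc_train = float(np.mean(fold_aucs))

    rf = RandomForestClassifier(
        n_estimators=plan.rf_n_estimators, random_state=rf_seed, n_jobs=1
    )
    rf.fit(Xtr, ytr)
    auc_test = rank_auc(rf.predict_proba(Xte)[:, 1], yte)
    return auc_train, auc_test
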