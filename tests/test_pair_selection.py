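from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from oracles import pairwise_auc
from pathcrosstalk.crosstalk import CrosstalkFeatureMatrix, PathwayPair
from pathcrosstalk.io import Labels
from pathcrosstalk.pair_selection import (
    MonteCarloPlan,
    aggregate_top,
    balance_classes,
    evaluate_panel,
    monte_carlo_split,
    rank_auc,
    rank_pairs,
)


def _labels(n_case, n_ctrl):
    mapping = {f"c{i}": "case" for i in range(n_case)}
    mapping.update({f"n{i}": "control" for i in range(n_ctrl)})
    return Labels(mapping)


def _features(columns: dict, sample_ids) -> CrosstalkFeatureMatrix:
    pairs = []
    for key in columns:
        x, y = key.split("|")
        pairs.append(
            PathwayPair(x, y, frozenset({f"{x}.1", f"{x}.2"}), frozenset({f"{y}.1", f"{y}.2"}))
        )
    ds = pd.DataFrame(columns, index=list(sample_ids)).abs()
    return CrosstalkFeatureMatrix(pairs, ds)


class TestRankAuc:
    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(0)
        for n1, n0 in [(2, 2), (3, 5), (4, 4), (5, 3)]:
            for _ in range(20):
                y = np.array([1] * n1 + [0] * n0)
                scores = rng.integers(0, 4, size=n1 + n0).astype(float)  # with ties
                assert rank_auc(scores, y) == pytest.approx(pairwise_auc(scores, y))

    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0])
        assert rank_auc(np.array([4.0, 3.0, 2.0, 1.0]), y) == 1.0


class TestBalanceClasses:
    def test_imbalanced_cohort_downsampled(self):
        labels = _labels(43, 113)
        chosen = balance_classes(labels, seed=5)
        sub = labels.subset(chosen)
        assert len(chosen) == 86
        assert len(sub.case_ids) == 43 and len(sub.control_ids) == 43

    def test_balanced_identity(self):
        labels = _labels(10, 10)
        assert balance_classes(labels, seed=1) == labels.sample_ids

    def test_deterministic(self):
        labels = _labels(20, 50)
        assert balance_classes(labels, 7) == balance_classes(labels, 7)
        assert balance_classes(labels, 7) != balance_classes(labels, 8)


class TestMonteCarloSplit:
    def test_sizes_and_stratification(self):
        labels = _labels(43, 43)
        plan = MonteCarloPlan(seed=0)
        train, test = monte_carlo_split(labels.sample_ids, labels, plan, 0)
        assert len(train) == 52 and len(test) == 34
        sub = labels.subset(train)
        assert len(sub.case_ids) == 26 and len(sub.control_ids) == 26
        assert set(train) | set(test) == set(labels.sample_ids)
        assert not set(train) & set(test)

    def test_repeat_index_changes_split(self):
        labels = _labels(20, 20)
        plan = MonteCarloPlan(seed=3)
        s0 = monte_carlo_split(labels.sample_ids, labels, plan, 0)
        s1 = monte_carlo_split(labels.sample_ids, labels, plan, 1)
        assert s0 != s1
        assert s0 == monte_carlo_split(labels.sample_ids, labels, plan, 0)


class TestRankPairs:
    def _plan(self, **kw):
        defaults = dict(n_repeats=1, inner_folds=5, rf_n_estimators=10, seed=0)
        defaults.update(kw)
        return MonteCarloPlan(**defaults)

    def test_perfect_feature_ranks_first_with_auc_one(self):
        rng = np.random.default_rng(0)
        labels = _labels(15, 15)
        ids = labels.sample_ids
        y = labels.y(ids)
        features = _features(
            {
                "A|B": np.where(y == 1, 5.0, 1.0) + rng.normal(0, 0.1, 30),
                "C|D": rng.normal(2, 1, 30),
            },
            ids,
        )
        ranking = rank_pairs(features, labels, self._plan())
        assert ranking.iloc[0]["pair"] == "A|B"
        assert ranking.iloc[0]["auc"] == pytest.approx(1.0)

    def test_constant_feature_scores_half(self):
        labels = _labels(10, 10)
        features = _features(
            {"A|B": np.full(20, 2.0), "C|D": np.random.default_rng(1).normal(2, 1, 20)},
            labels.sample_ids,
        )
        ranking = rank_pairs(features, labels, self._plan())
        assert ranking.set_index("pair").loc["A|B", "auc"] == 0.5

    def test_random_feature_near_half(self):
        rng = np.random.default_rng(7)
        labels = _labels(40, 40)
        features = _features({"A|B": rng.normal(3, 1, 80)}, labels.sample_ids)
        ranking = rank_pairs(features, labels, self._plan(inner_folds=10))
        assert 0.35 <= ranking.iloc[0]["auc"] <= 0.65

    def test_screen_limits_rf_work(self):
        rng = np.random.default_rng(2)
        labels = _labels(12, 12)
        columns = {f"P{i:02d}|Q{i:02d}": rng.normal(2, 1, 24) for i in range(12)}
        ranking = rank_pairs(
            features=_features(columns, labels.sample_ids),
            labels=labels,
            plan=self._plan(inner_folds=4, screen_top=5, top_m=3),
        )
        assert ranking["rf_ranked"].sum() == 5

    def test_too_few_samples_per_class(self):
        labels = _labels(4, 4)
        features = _features({"A|B": np.arange(8.0)}, labels.sample_ids)
        with pytest.raises(ValueError, match="inner_folds"):
            rank_pairs(features, labels, self._plan(inner_folds=10))


class TestAggregateTop:
    def _ranking(self, rows):
        return pd.DataFrame(rows, columns=["pair", "auc", "rf_ranked"])

    def test_single_repeat_panel(self):
        rows = [(f"P|{chr(65+i)}", 1 - 0.05 * i, True) for i in range(12)]
        plan = MonteCarloPlan(top_m=10, seed=0)
        agg, panel = aggregate_top([self._ranking(rows)], plan)
        assert panel == [r[0] for r in rows[:10]]

    def test_frequencies_counted(self):
        r1 = self._ranking([("A|B", 0.9, True), ("C|D", 0.8, True), ("E|F", 0.7, True)])
        r2 = self._ranking([("C|D", 0.95, True), ("A|B", 0.95, True), ("E|F", 0.6, True)])
        plan = MonteCarloPlan(top_m=2, seed=0)
        agg, panel = aggregate_top([r1, r2], plan)
        freq = dict(zip(agg["pair"], agg["frequency"]))
        assert freq == {"A|B": 2, "C|D": 2, "E|F": 0}
        assert set(panel) == {"A|B", "C|D"}

    def test_tie_break_by_mean_auc(self):
        r1 = self._ranking([("A|B", 0.9, True), ("C|D", 0.7, True)])
        plan = MonteCarloPlan(top_m=1, seed=0)
        agg, panel = aggregate_top([r1], plan)
        assert panel == ["A|B"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_top([], MonteCarloPlan(seed=0))


class TestEvaluatePanel:
    def test_perfect_single_feature(self):
        rng = np.random.default_rng(0)
        labels = _labels(20, 20)
        ids = labels.sample_ids
        y = labels.y(ids)
        features = _features(
            {"A|B": np.where(y == 1, 5.0, 1.0) + rng.normal(0, 0.05, 40)}, ids
        )
        train = ids[:10] + ids[20:30]
        test = ids[10:20] + ids[30:]
        plan = MonteCarloPlan(inner_folds=5, rf_n_estimators=25, seed=0)
        auc_train, auc_test = evaluate_panel(features, ["A|B"], train, test, labels, plan)
        assert auc_test == 1.0
        assert auc_train > 0.9

    def test_empty_panel_rejected(self):
        labels = _labels(5, 5)
        features = _features({"A|B": np.arange(10.0)}, labels.sample_ids)
        with pytest.raises(ValueError):
            evaluate_panel(features, [], labels.sample_ids[:6], labels.sample_ids[6:], labels, MonteCarloPlan(seed=0))


class TestRecoveryPower:
    def test_planted_pair_auc_increases_with_effect_size(self):
        # the class-discriminative power of planted pairs (rank AUC of
        # their DS feature) grows with the planted contrast
        from pathcrosstalk.crosstalk import build_feature_matrix
        from pathcrosstalk.differential_expression import log_transform
        from pathcrosstalk.synthetic_data import SimulationConfig, simulate_cohort

        means = []
        for effect in (0.5, 1.0, 2.0):
            aucs = []
            for seed in range(3):
                cfg = SimulationConfig(effect_size=effect, seed=seed)
                gene, _, sets, labels, truth = simulate_cohort(cfg)
                log = log_transform(gene)
                fm = build_feature_matrix(log, sets.restrict(set(log.feature_ids), 2))
                y = labels.y(fm.sample_ids)
                for pair in truth.planted_pairs:
                    key = "|".join(sorted(pair))
                    a = rank_auc(fm.ds[key].to_numpy(), y)
                    aucs.append(max(a, 1 - a))
            means.append(np.mean(aucs))
        assert means[0] <= means[1] <= means[2]


class TestPlanValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"train_fraction": 0.0},
            {"train_fraction": 1.0},
            {"n_repeats": 0},
            {"inner_folds": 1},
            {"screen_top": 2, "top_m": 5},
        ],
    )
    def test_invalid_plans(self, kwargs):
        with pytest.raises(ValueError):
            MonteCarloPlan(seed=0, **kwargs)
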