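import numpy as np
import pandas as pd
import pytest

from oracles import gaussian_mi
from pathcrosstalk.crosstalk import PathwayPair
from pathcrosstalk.io import ExpressionMatrix, GeneSetCollection
from pathcrosstalk.mirna_network import (
    MiRNATargetMap,
    build_network,
    degree_centrality,
    infer_targets,
    mirna_pathway_enrichment,
    mutual_information,
)


def _em(values, prefix="f"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        ),
        scale_tag="log2",
    )


class TestMutualInformation:
    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.uniform(size=2000), rng.uniform(size=2000)
        assert mutual_information(x, y) <= 0.05

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(1)
        rho = 0.8
        cov = [[1, rho], [rho, 1]]
        x, y = rng.multivariate_normal([0, 0], cov, size=2000).T
        assert mutual_information(x, y) == pytest.approx(gaussian_mi(rho), abs=0.1)

    def test_identical_vectors_large(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000)
        assert mutual_information(x, x) > 1.0

    def test_constant_vector_zero(self):
        x = np.linspace(0, 1, 50)
        assert mutual_information(x, np.full(50, 3.0)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information(np.arange(20), np.arange(21))

    def test_monotone_transform_stability(self):
        # kNN MI is nearly invariant under strictly monotone maps
        rng = np.random.default_rng(3)
        x, y = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=2000).T
        base = mutual_information(x, y)
        warped = mutual_information(np.exp(x / 2), y**3 + 5 * y)
        assert warped == pytest.approx(base, abs=0.05)

    def test_agrees_with_sklearn_ksg(self):
        # sklearn's mutual_info_regression implements the same KSG
        # estimator; use it as an independent cross-check
        from sklearn.feature_selection import mutual_info_regression

        rng = np.random.default_rng(4)
        x = rng.normal(size=800)
        y = 0.7 * x + rng.normal(size=800) * 0.5
        ours = mutual_information(x, y)
        theirs = mutual_info_regression(
            x.reshape(-1, 1), y, n_neighbors=3, random_state=0
        )[0]
        assert ours == pytest.approx(theirs, abs=0.05)


class TestInferTargets:
    def test_coupled_gene_recovered_constant_gene_never(self):
        rng = np.random.default_rng(5)
        n = 120
        x = rng.normal(5, 1, n)
        coupled = 8 - 0.9 * x + rng.normal(0, 0.3, n)
        noise = rng.normal(6, 1, (6, n))
        genes = np.vstack([coupled, noise, np.full(n, 4.0)])
        tm = infer_targets(
            _em(x, prefix="mir"), _em(genes, prefix="g"),
            n_permutations=60, alpha=0.01, seed=0,
        )
        declared = tm.target_set("mir0")
        assert "g0" in declared
        assert "g7" not in declared  # constant gene

    def test_planted_regulator_sensitivity_and_false_positive_rate(self):
        # one strong repressor (90% of target variance) among unrelated
        # genes: nearly all true targets recovered, false calls near alpha
        from pathcrosstalk.differential_expression import log_transform
        from pathcrosstalk.synthetic_data import (
            regulator_recovery_config,
            simulate_cohort,
        )

        targets = tuple(range(12))
        cfg = regulator_recovery_config(
            seed=1, n_decoy_mirnas=0, planted_regulators={0: targets}
        )
        gene, mirna, _, _, truth = simulate_cohort(cfg)
        reg = sorted(truth.regulator_mirnas)[0]
        tm = infer_targets(
            log_transform(mirna).subset_features([reg]),
            log_transform(gene),
            n_permutations=100,
            alpha=0.01,
            seed=0,
        )
        declared = tm.target_set(reg)
        true_targets = truth.regulator_targets[reg]
        sensitivity = len(declared & true_targets) / len(true_targets)
        fpr = len(declared - true_targets) / (cfg.n_genes - len(true_targets))
        assert sensitivity >= 0.8
        assert fpr <= 0.02

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(2, 60))
        genes = rng.normal(size=(10, 60))
        a = infer_targets(_em(x, "mir"), _em(genes), n_permutations=30, seed=3)
        b = infer_targets(_em(x, "mir"), _em(genes), n_permutations=30, seed=3)
        assert a.targets == b.targets

    def test_sample_mismatch_rejected(self):
        x = _em(np.random.default_rng(0).normal(size=(1, 30)), "mir")
        g = _em(np.random.default_rng(0).normal(size=(2, 31)))
        with pytest.raises(ValueError, match="samples"):
            infer_targets(x, g)


class TestDegreeCentrality:
    def _map(self, targets):
        return MiRNATargetMap({"m": {t: 1.0 for t in targets}}, 3, 100, 0.01)

    def test_toy_overlap(self):
        pathways = GeneSetCollection(
            {"A": {f"g{i}" for i in range(1, 6)}, "B": {f"g{i}" for i in range(4, 9)}}
        )
        n_reg, n_tot, n_cpl = degree_centrality(
            "m", self._map({"g1", "g4", "g8", "g9"}), pathways
        )
        assert (n_reg, n_tot, n_cpl) == (3, 8, 2)

    def test_saturation(self):
        pathways = GeneSetCollection({"A": {"g1", "g2"}})
        assert degree_centrality("m", self._map({"g1", "g2", "g3"}), pathways) == (2, 2, 1)

    def test_disjoint(self):
        pathways = GeneSetCollection({"A": {"g1", "g2"}})
        assert degree_centrality("m", self._map({"g9"}), pathways) == (0, 2, 1)


class TestPanelEnrichmentAndNetwork:
    def _pairs(self):
        g = lambda lo, hi: frozenset(f"g{i}" for i in range(lo, hi))
        return [
            PathwayPair("PA", "PB", g(0, 5), g(5, 10)),
            PathwayPair("PB", "PC", g(5, 10), g(10, 15)),
        ]

    def _universe(self):
        return frozenset(f"g{i}" for i in range(40))

    def test_concentrated_targets_retained_disjoint_not(self):
        panel_sets = GeneSetCollection(
            {"PA": {f"g{i}" for i in range(5)}, "PB": {f"g{i}" for i in range(5, 10)}}
        )
        tm = MiRNATargetMap(
            {
                "hit": {f"g{i}": 1.0 for i in range(5)},
                "miss": {f"g{i}": 1.0 for i in range(20, 24)},
            },
            3, 100, 0.01,
        )
        results = mirna_pathway_enrichment(tm, panel_sets, self._universe())
        assert results["hit"]["enriched"].any()
        assert not results["miss"]["enriched"].any()

    def test_empty_target_set_skipped(self):
        panel_sets = GeneSetCollection({"PA": {"g0", "g1"}})
        tm = MiRNATargetMap({"empty": {}}, 3, 100, 0.01)
        assert mirna_pathway_enrichment(tm, panel_sets, self._universe()) == {}

    def _enrichment(self, mirna, pathways_p):
        rows = [
            (p, 4, 5, 5, 40, pv, pv < 0.01)
            for p, pv in pathways_p.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["pathway", "k_overlap", "K_pathway", "n_query", "N_universe", "p", "enriched"],
        )

    def test_interaction_filter_removes_weak_pathway(self):
        tm = MiRNATargetMap({"m1": {f"g{i}": 1.0 for i in range(5)}}, 3, 100, 0.01)
        enr = {"m1": self._enrichment("m1", {"PA": 0.001, "PB": 0.5, "PC": 0.9})}
        net = build_network(self._pairs(), tm, enr, min_interactions=2)
        # PA: crosstalk edge + regulation edge = 2 -> kept; PC: 1 edge -> removed
        assert "PC" not in net.graph
        assert {"PA", "PB"} <= set(net.pathway_nodes)
        assert net.mirna_nodes == ["m1"]
        assert net.centrality.iloc[0]["n_regulated"] == 5

    def test_min_interactions_zero_keeps_all(self):
        tm = MiRNATargetMap({"m1": {"g0": 1.0}}, 3, 100, 0.01)
        enr = {"m1": self._enrichment("m1", {"PA": 0.5, "PB": 0.5, "PC": 0.5})}
        net = build_network(self._pairs(), tm, enr, min_interactions=0)
        assert set(net.pathway_nodes) == {"PA", "PB", "PC"}

    def test_empty_panel_rejected(self):
        tm = MiRNATargetMap({}, 3, 100, 0.01)
        with pytest.raises(ValueError):
            build_network([], tm, {})

    def test_centrality_ranks_by_regulated_genes(self):
        tm = MiRNATargetMap(
            {
                "big": {f"g{i}": 1.0 for i in range(8)},
                "small": {f"g{i}": 1.0 for i in range(3)},
            },
            3, 100, 0.01,
        )
        enr = {
            "big": self._enrichment("big", {"PA": 0.001, "PB": 0.001, "PC": 0.9}),
            "small": self._enrichment("small", {"PA": 0.001, "PB": 0.9, "PC": 0.9}),
        }
        net = build_network(self._pairs(), tm, enr, min_interactions=0)
        assert net.top_regulators(2) == ["big", "small"]
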