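"""Gene-set features, transforms and the elastic-net bootstrap machinery."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qnetcoloc.features import (
    _empirical_p,
    bootstrap_coefficients,
    compute_pair_features,
    default_transform_scheme,
    features_frame,
    fit_elastic_net_cv,
    jaccard_similarity,
    pair_assortativity,
    quantile_normalize_response,
    subnetwork_density,
    transform_features,
    weighted_mean_and_delta,
)
from qnetcoloc.graph import Network


class TestJaccard:
    def test_examples(self):
        assert jaccard_similarity({"A"}, {"A"}) == 1.0
        assert jaccard_similarity({"A"}, {"B"}) == 0.0
        assert jaccard_similarity({"A", "B", "C"}, {"B", "C", "D"}) == 0.5

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard_similarity(set(), set())


class TestSubnetworkDensity:
    def test_clique(self):
        net = Network(nx.complete_graph(["A", "B", "C", "D"]))
        assert subnetwork_density(net, {"A", "B", "C", "D"}) == 1.0

    def test_independent_set(self):
        net = Network(nx.Graph([("A", "X"), ("B", "X"), ("C", "X")]))
        assert subnetwork_density(net, {"A", "B", "C"}) == 0.0

    def test_triangle_plus_isolated_member(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("D", "E")])
        assert subnetwork_density(Network(g), {"A", "B", "C", "D"}) == pytest.approx(0.5)

    def test_fewer_than_two_members(self):
        net = Network(nx.Graph([("A", "B")]))
        assert subnetwork_density(net, {"A"}) == 0.0
        assert subnetwork_density(net, {"Z1", "Z2"}) == 0.0


class TestPairAssortativity:
    def test_two_label_pure_cliques(self):
        g = nx.compose(
            nx.complete_graph(["c1", "c2", "c3"]), nx.complete_graph(["r1", "r2", "r3"])
        )
        net = Network(g)
        val = pair_assortativity(net, {"c1", "c2", "c3"}, {"r1", "r2", "r3"})
        assert val == pytest.approx(1.0)

    def test_complete_bipartite_across_labels(self):
        g = nx.complete_bipartite_graph(2, 2)
        g = nx.relabel_nodes(g, {0: "c1", 1: "c2", 2: "r1", 3: "r2"})
        val = pair_assortativity(Network(g), {"c1", "c2"}, {"r1", "r2"})
        assert val == pytest.approx(-1.0)

    def test_single_cross_label_edge(self):
        # mixing matrix e = [[0, .5], [.5, 0]] -> coefficient -1
        net = Network(nx.Graph([("c1", "r1")]))
        val = pair_assortativity(net, {"c1"}, {"r1"})
        assert val == pytest.approx(-1.0)

    def test_no_edges_warns_zero(self):
        g = nx.Graph([("c1", "far"), ("r1", "far2"), ("far", "far2")])
        net = Network(g)
        with pytest.warns(UserWarning, match="no edges"):
            assert pair_assortativity(net, {"c1"}, {"r1"}) == 0.0

    def test_shared_genes_average_two_labelings(self):
        # J > 0: both labelings computed and averaged; value stays in [-1, 1]
        g = nx.complete_graph(["s", "c1", "r1", "r2"])
        val = pair_assortativity(Network(g), {"s", "c1"}, {"s", "r1", "r2"})
        assert -1.0 <= val <= 1.0


class TestWeightedMeanAndDelta:
    def test_hand_example(self):
        mu, delta = weighted_mean_and_delta(1.0, 2, 3.0, 2)
        assert mu == pytest.approx(2.0) and delta == pytest.approx(1.0)

    def test_equal_means_give_zero_delta(self):
        _, delta = weighted_mean_and_delta(2.5, 10, 2.5, 3)
        assert delta == 0.0

    def test_antisymmetry_example(self):
        _, delta = weighted_mean_and_delta(3.0, 5, 1.0, 5)
        assert delta == pytest.approx(-1.0)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_and_delta(-1.0, 2, 1.0, 2)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        mu_c=st.floats(0.001, 1e3),
        mu_r=st.floats(0.001, 1e3),
        g_c=st.integers(1, 500),
        g_r=st.integers(1, 500),
    )
    def test_delta_antisymmetric_and_bounded_mu_convex(self, mu_c, mu_r, g_c, g_r):
        mu, delta = weighted_mean_and_delta(mu_c, g_c, mu_r, g_r)
        _, delta_swapped = weighted_mean_and_delta(mu_r, g_r, mu_c, g_c)
        assert delta == pytest.approx(-delta_swapped, rel=1e-9)
        assert abs(delta) <= 2.0
        assert min(mu_c, mu_r) - 1e-9 <= mu <= max(mu_c, mu_r) + 1e-9


class TestComputePairFeatures:
    def test_full_record(self):
        g = nx.complete_graph(["A", "B", "C", "D"])
        net = Network(g)
        props = {"Constraint": {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}}
        feats = compute_pair_features(
            net, {"A", "B"}, {"B", "C"}, 1000, 2000, properties=props,
            is_categorical=True,
        )
        assert feats.g_common == 2 and feats.g_rare == 2
        assert feats.jaccard == pytest.approx(1 / 3)
        assert not feats.jaccard_zero
        row = feats.as_row()
        assert row["binary"] == 1.0 and "mu_Constraint" in row
        df = features_frame([feats])
        assert len(df) == 1


class TestTransforms:
    def _table(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "N_C": rng.lognormal(10, 1, n),
                "g_C": rng.integers(5, 300, n).astype(float),
                "J_CR": rng.beta(1, 20, n),
                "A_CR": rng.normal(0, 0.2, n),
                "mu_Constraint": rng.gamma(2, 1, n),
                "delta_Constraint": rng.uniform(-2, 2, n),
                "mu_nTissues": rng.integers(1, 40, n).astype(float),
                "binary": (rng.random(n) > 0.5).astype(float),
            }
        )

    def test_default_scheme_assignment(self):
        scheme = default_transform_scheme(self._table().columns)
        assert scheme["N_C"] == "quantile"
        assert scheme["g_C"] == "power"
        assert scheme["J_CR"] == "power"
        assert scheme["mu_nTissues"] == "power"
        assert scheme["mu_Constraint"] == "quantile"
        assert scheme["delta_Constraint"] == "quantile"
        assert scheme["binary"] == "one-hot"

    def test_standardized_and_rank_preserving(self):
        table = self._table()
        out = transform_features(table)
        assert np.allclose(out.mean(), 0.0, atol=1e-9)
        assert np.allclose(out.std(ddof=0), 1.0, atol=1e-6)
        for col in ("N_C", "g_C", "J_CR", "mu_Constraint"):
            rho = stats.spearmanr(table[col], out[col]).statistic
            assert rho == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        table = self._table()
        table["A_CR"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            transform_features(table)

    def test_unassigned_column_rejected(self):
        table = self._table().rename(columns={"N_C": "mystery"})
        with pytest.raises(ValueError, match="mystery"):
            transform_features(table)


class TestElasticNet:
    def _make_data(self, n=400, p=8, seed=0, noise=0.05):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[0] = 2.0
        y = X @ beta + noise * rng.standard_normal(n)
        cols = [f"f{i}" for i in range(p)]
        return pd.DataFrame(X, columns=cols), y

    def test_recovers_noise_free_coefficient(self):
        X, y = self._make_data(noise=1e-12)
        fit = fit_elastic_net_cv(X, y, rng_seed=0)
        assert fit.coefficients["f0"] == pytest.approx(2.0, abs=0.05)
        assert np.all(np.abs(fit.coefficients.drop("f0")) < 0.05)
        assert fit.explained_variance > 0.999

    def test_pure_noise_explains_nothing(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((300, 5)), columns=list("abcde"))
        y = rng.standard_normal(300)
        fit = fit_elastic_net_cv(X, y, rng_seed=0)
        assert fit.explained_variance < 0.05

    def test_deterministic_under_fixed_seed(self):
        X, y = self._make_data()
        f1 = fit_elastic_net_cv(X, y, rng_seed=5)
        f2 = fit_elastic_net_cv(X, y, rng_seed=5)
        assert f1.penalty == f2.penalty and f1.l1_ratio == f2.l1_ratio
        assert np.allclose(f1.coefficients, f2.coefficients)

    def test_too_few_rows_rejected(self):
        X, y = self._make_data(n=8)
        with pytest.raises(ValueError, match="rows"):
            fit_elastic_net_cv(X, y, k=5)


class TestBootstrap:
    def test_empirical_p_arithmetic(self):
        assert _empirical_p(2000, 0, 2000) == pytest.approx(2 / 2001)
        assert _empirical_p(0, 2000, 2000) == pytest.approx(2 / 2001)
        assert _empirical_p(1000, 1000, 2000) == 1.0  # capped
        assert _empirical_p(0, 0, 2000) == pytest.approx(2 / 2001)

    def test_signal_feature_has_tight_ci_and_small_p(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((300, 4)), columns=list("abcd"))
        y = 1.5 * X["a"].to_numpy() + 0.3 * rng.standard_normal(300)
        out = bootstrap_coefficients(X, y, penalty=0.01, l1_ratio=0.5, n_boot=200, rng_seed=0)
        row = out.table.loc["a"]
        assert row["ci_low"] > 1.0 and row["ci_high"] < 2.0
        assert row["ci_low"] <= row["coef_mean"] <= row["ci_high"]
        assert row["p"] == pytest.approx(2 / 201)
        assert row["q"] == pytest.approx(min(1.0, 4 * 2 / 201))

    def test_determinism(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
        y = rng.standard_normal(100)
        a = bootstrap_coefficients(X, y, 0.05, 0.5, n_boot=50, rng_seed=2)
        b = bootstrap_coefficients(X, y, 0.05, 0.5, n_boot=50, rng_seed=2)
        pd.testing.assert_frame_equal(a.table, b.table)


def test_quantile_normalize_response_is_rank_preserving():
    rng = np.random.default_rng(0)
    y = rng.lognormal(0, 2, 150)
    z = quantile_normalize_response(y)
    assert stats.spearmanr(y, z).statistic == pytest.approx(1.0)
    assert abs(z.mean()) < 0.2
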