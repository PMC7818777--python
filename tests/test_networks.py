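"""Delta profiles, elastic-net selection, partial correlations, network
construction and window comparison statistics."""

import numpy as np
import pytest
from scipy import stats

from triomics.networks import (
    DeltaWindow,
    build_network,
    compare_windows,
    delta_profiles,
    elastic_net_select,
    kurtosis_label,
    partial_correlations,
)

TPS = [12, 9, 6, 3, 0]


def _window(matrix, label="12to9"):
    m = np.asarray(matrix, float)
    return DeltaWindow(
        label, m, [f"f{j}" for j in range(m.shape[1])],
        [f"s{i}" for i in range(m.shape[0])], 12, 9,
    )


class TestDeltaProfiles:
    def test_five_timepoints_give_exactly_four_windows(self):
        x = np.random.default_rng(0).normal(size=(6, 4, 5))
        w = delta_profiles(x, np.ones_like(x, bool), [f"s{i}" for i in range(6)],
                           [f"f{j}" for j in range(4)], TPS, subjects="all")
        assert [v.label for v in w] == ["12to9", "9to6", "6to3", "3to0"]

    def test_later_minus_earlier_sign_convention(self):
        x = np.zeros((1, 1, 5))
        x[0, 0, :] = [2.0, 5.0, 5.0, 5.0, 5.0]  # 2.0 at 12 MBSC, 5.0 at 9
        w = delta_profiles(x, np.ones_like(x, bool), ["s1"], ["f1"], TPS,
                           subjects="all")
        assert w[0].matrix[0, 0] == pytest.approx(3.0)

    def test_constant_profile_has_zero_deltas(self):
        x = np.full((3, 2, 5), 1.7)
        w = delta_profiles(x, np.ones_like(x, bool), list("abc"), ["f1", "f2"],
                           TPS, subjects="all")
        for v in w:
            np.testing.assert_allclose(v.matrix, 0.0)

    def test_cases_only_restriction(self):
        x = np.random.default_rng(1).normal(size=(4, 3, 5))
        labels = np.array(["case", "control", "case", "control"])
        w = delta_profiles(x, np.ones_like(x, bool), list("abcd"),
                           ["f1", "f2", "f3"], TPS, labels=labels)
        assert w[0].matrix.shape[0] == 2
        assert w[0].subject_ids == ["a", "c"]

    def test_fewer_than_five_timepoints_errors(self):
        x = np.zeros((2, 2, 3))
        with pytest.raises(ValueError, match="5-timepoint"):
            delta_profiles(x, np.ones_like(x, bool), ["a", "b"], ["f1", "f2"],
                           [12, 9, 6], subjects="all")


class TestPartialCorrelations:
    def test_three_variable_recursive_formula_oracle(self):
        """Precision-matrix route equals the classical recursion
        (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2)) on 100 instances."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            X = rng.normal(size=(200, 3)) @ A
            p = partial_correlations(X, shrink="never")
            r = np.corrcoef(X, rowvar=False)
            expected = (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt(
                (1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)
            )
            assert p[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_independent_features_have_small_pcor(self):
        X = np.random.default_rng(3).normal(size=(500, 5))
        p = partial_correlations(X, shrink="never")
        off = p[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.2

    def test_zero_cross_block_covariance_recovered(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(1000, 3)) @ (rng.normal(size=(3, 3)) + 2 * np.eye(3))
        b = rng.normal(size=(1000, 3)) @ (rng.normal(size=(3, 3)) + 2 * np.eye(3))
        p = partial_correlations(np.hstack([a, b]), shrink="never")
        assert np.max(np.abs(p[:3, 3:])) < 0.05

    def test_symmetry_and_unit_diagonal(self):
        X = np.random.default_rng(5).normal(size=(50, 8))
        p = partial_correlations(X)
        np.testing.assert_allclose(p, p.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(p), 1.0, atol=1e-12)

    def test_shrunk_route_used_when_p_close_to_n(self):
        X = np.random.default_rng(6).normal(size=(20, 15))
        p = partial_correlations(X)  # n <= p + 10 -> Ledoit-Wolf
        assert np.all(np.abs(p) <= 1.0 + 1e-12)

    def test_collinear_pair_raises_naming_columns(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 4))
        X[:, 3] = 2.0 * X[:, 1]
        with pytest.raises(ValueError, match="collinear"):
            partial_correlations(X)

    def test_minimum_size_requirements(self):
        with pytest.raises(ValueError, match="3 variables"):
            partial_correlations(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="4 samples"):
            partial_correlations(np.zeros((3, 5)))


class TestBuildNetwork:
    def _pcor(self, entries, p=4):
        m = np.eye(p)
        for (i, j), v in entries.items():
            m[i, j] = m[j, i] = v
        return m

    def test_edges_only_above_threshold(self):
        m = self._pcor({(0, 1): 0.71, (1, 2): 0.69, (2, 3): -0.8})
        net = build_network(m, ["a", "b", "c", "d"], threshold=0.7)
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset({"a", "b"}), frozenset({"c", "d"})
        }
        assert net.graph.edges["a", "b"]["sign"] == "positive"
        assert net.graph.edges["a", "b"]["weight"] == pytest.approx(0.71)
        assert net.graph.edges["c", "d"]["sign"] == "negative"

    def test_no_edges_below_threshold(self):
        m = self._pcor({(0, 1): 0.5})
        net = build_network(m, ["a", "b", "c", "d"], threshold=0.7)
        assert net.n_edges == 0

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 6))
        X[:, 1] = X[:, 0] * 0.9 + 0.1 * rng.normal(size=30)
        p = partial_correlations(X, shrink="never")
        ids = [f"f{j}" for j in range(6)]
        lo = build_network(p, ids, threshold=0.5)
        hi = build_network(p, ids, threshold=0.8)
        assert set(hi.graph.edges) <= set(lo.graph.edges)

    def test_node_annotations_and_kinds(self):
        m = self._pcor({(0, 1): 0.9})
        net = build_network(
            m, ["g", "m", "v", "x"], threshold=0.7,
            kinds={"g": "gene", "m": "metabolite", "v": "vitamin"},
            node_values={"g": 1.5, "m": -0.3, "v": 0.0},
        )
        assert net.graph.nodes["g"]["kind"] == "gene"
        assert net.graph.nodes["g"]["regulation"] == "up"
        assert net.graph.nodes["m"]["regulation"] == "down"
        assert net.graph.nodes["v"]["regulation"] == "flat"
        assert net.graph.nodes["x"]["isolated"]


class TestElasticNet:
    def _problem(self, seed, n=60, p=12, informative=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:informative] = 2.0
        y = np.where(X @ beta + rng.normal(size=n) > 0, "case", "control")
        return _window(X), y

    def test_identical_seed_identical_selection(self):
        w, y = self._problem(0)
        s1, a1 = elastic_net_select(w, y, n_tune=5, n_final=20, seed=3)
        s2, a2 = elastic_net_select(w, y, n_tune=5, n_final=20, seed=3)
        assert s1 == s2 and a1 == a2

    def test_informative_features_recovered(self):
        hits = []
        for seed in range(3):
            w, y = self._problem(seed)
            sel, _ = elastic_net_select(w, y, n_tune=5, n_final=30, seed=seed)
            hits.append(len(set(sel) & {"f0", "f1", "f2"}) / 3)
        assert np.mean(hits) >= 0.8

    def test_constant_features_dropped_with_warning(self):
        w, y = self._problem(1)
        w.matrix[:, 5] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            sel, _ = elastic_net_select(w, y, n_tune=3, n_final=10, seed=0)
        assert "f5" not in sel


class TestCompareWindows:
    def test_standard_normal_excess_kurtosis_near_zero(self):
        vals = np.random.default_rng(9).normal(size=100_000)
        k = float(stats.kurtosis(vals, fisher=True))
        kurt, _ = compare_windows({"a": vals, "b": vals})
        assert abs(kurt["a"]) < 0.2
        assert kurt["a"] == pytest.approx(k, abs=1e-6)

    def test_identical_value_sets_ks_zero(self):
        vals = np.random.default_rng(10).normal(size=500)
        _, ks = compare_windows({"a": vals, "b": vals.copy()})
        assert ks[0]["ks_stat"] == pytest.approx(0.0)
        assert ks[0]["ks_p"] == pytest.approx(1.0)

    def test_distinct_distributions_detected(self):
        rng = np.random.default_rng(11)
        u = rng.uniform(-1, 1, size=500)
        n = rng.normal(0, 0.3, size=500)
        _, ks = compare_windows({"a": u, "b": n})
        assert ks[0]["ks_p"] < 1e-6

    def test_kurtosis_shape_labels(self):
        assert kurtosis_label(-0.12) == "platykurtic"
        assert kurtosis_label(1.18) == "leptokurtic"
        assert kurtosis_label(0.0) == "mesokurtic"

    def test_too_few_values_or_windows_error(self):
        with pytest.raises(ValueError, match="two windows"):
            compare_windows({"a": np.zeros(50)})
        with pytest.raises(ValueError, match=">= 20"):
            compare_windows({"a": np.zeros(5), "b": np.zeros(50)})
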