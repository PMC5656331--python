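"""Slopes, permutation p-values, stabilisation diagnostics and (MR)QAP."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from socialnull import (
    NodeTable,
    NullChainSpec,
    PermutationResult,
    WeightedNetwork,
    compare_networks,
    dyad_category_matrix,
    mrqap_custom_null,
    mrqap_dsp,
    node_statistic_slope,
    ols_fit,
    permutation_pvalues,
    qap_regression,
    simple_ratio_index,
    stabilisation_series,
)

from conftest import random_gbi


class TestSlope:
    def test_two_group_slope_is_mean_difference(self):
        nodes = NodeTable(
            list("abcd"), {"sex": np.array(list("MMFF"), dtype=object)}
        )
        # F coded 0 (alphabetically first), M coded 1: slope = mean(M) - mean(F)
        assert node_statistic_slope([1, 1, 2, 2], nodes, "sex") == pytest.approx(-1.0)

    def test_constant_values_give_zero_slope(self):
        nodes = NodeTable(
            list("abcd"), {"sex": np.array(list("MMFF"), dtype=object)}
        )
        assert node_statistic_slope([3, 3, 3, 3], nodes, "sex") == 0.0

    def test_invariant_to_individual_ordering(self, rng):
        n = 12
        values = rng.random(n)
        sex = np.array(["M", "F"] * 6, dtype=object)
        nodes = NodeTable([f"i{k}" for k in range(n)], {"sex": sex})
        base = node_statistic_slope(values, nodes, "sex")
        perm = rng.permutation(n)
        nodes2 = NodeTable([f"i{k}" for k in perm], {"sex": sex[perm]})
        assert node_statistic_slope(values[perm], nodes2, "sex") == pytest.approx(base)

    def test_constant_predictor_rejected(self):
        nodes = NodeTable(list("abc"), {"sex": np.array(["F"] * 3, dtype=object)})
        with pytest.raises(ValueError):
            node_statistic_slope([1.0, 2.0, 3.0], nodes, "sex")

    def test_parametric_fit_matches_closed_form_slope(self, rng):
        n = 20
        values = rng.random(n)
        nodes = NodeTable(
            [f"i{k}" for k in range(n)],
            {"sex": np.array(["M", "F"] * 10, dtype=object)},
        )
        fit = ols_fit(values, nodes, "sex")
        assert fit.coefficients["sex"] == pytest.approx(
            node_statistic_slope(values, nodes, "sex")
        )
        assert 0 <= fit.p_values["sex"] <= 1


class TestPermutationPvalues:
    def test_two_and_a_half_percent_greater_gives_p05(self):
        # 25 of 1000 null values above the observed, no ties
        nulls = np.concatenate([np.full(975, -1.0), np.full(25, 2.0)])
        p_up, p_lo, p2 = permutation_pvalues(0.0, nulls)
        assert p_up == 0.025
        assert p2 == pytest.approx(0.05)

    def test_ninety_seven_and_a_half_percent_greater_gives_p05(self):
        nulls = np.concatenate([np.full(975, 2.0), np.full(25, -1.0)])
        p_up, p_lo, p2 = permutation_pvalues(0.0, nulls)
        assert p_up == 0.975 and p_lo == 0.025
        assert p2 == pytest.approx(0.05)

    def test_all_ties_give_p_one(self):
        p_up, p_lo, p2 = permutation_pvalues(1.5, np.full(100, 1.5))
        assert (p_up, p_lo, p2) == (1.0, 1.0, 1.0)

    @given(
        st.lists(st.integers(-3, 3), min_size=1, max_size=40),
        st.integers(-3, 3),
    )
    def test_brute_force_oracle_with_heavy_ties(self, nulls, observed):
        p_up, p_lo, p2 = permutation_pvalues(observed, np.array(nulls, dtype=float))
        n = len(nulls)
        assert p_up == sum(v >= observed for v in nulls) / n
        assert p_lo == sum(v <= observed for v in nulls) / n
        assert p2 == min(1.0, 2 * min(p_up, p_lo))


class TestStabilisation:
    def test_final_row_reproduces_full_series_pvalue(self):
        rng = np.random.default_rng(5)
        res = PermutationResult.from_series(0.3, rng.normal(size=200))
        tab = stabilisation_series(res)
        assert tab["running_p_two_tailed"].iloc[-1] == pytest.approx(res.p_two_tailed)
        assert len(tab) == 200

    def test_first_row_is_clamped_to_unit_interval(self):
        res = PermutationResult.from_series(0.0, [5.0, -5.0, 5.0])
        tab = stabilisation_series(res)
        assert 0.0 <= tab["running_p_two_tailed"].iloc[0] <= 1.0

    def test_running_mean_monotone_for_monotone_series(self):
        res = PermutationResult.from_series(0.0, np.arange(50, dtype=float))
        tab = stabilisation_series(res)
        assert (np.diff(tab["running_mean"]) >= 0).all()


def _random_symmetric(rng, n, ids=None):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return WeightedNetwork(a, ids or [f"i{k}" for k in range(n)])


class TestQap:
    def test_identical_matrices_give_unit_coefficient(self, rng):
        net = _random_symmetric(rng, 8)
        res = qap_regression(net, [net], n_perm=50, seed=1)
        assert res.coefficients["x1"] == pytest.approx(1.0)

    def test_constant_predictor_rejected(self, rng):
        net = _random_symmetric(rng, 6)
        flat = WeightedNetwork(0.5 * (1 - np.eye(6)), net.individual_ids)
        with pytest.raises(ValueError, match="constant"):
            qap_regression(net, [flat], n_perm=10, seed=0)

    def test_type_one_error_calibrated_under_independence(self):
        # independent dep/predictor: rejections at alpha=0.05 must sit inside
        # the exact binomial 95% envelope over 200 replicates
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            dep = _random_symmetric(rng, 10)
            pred = _random_symmetric(rng, 10, dep.individual_ids)
            res = qap_regression(dep, [pred], n_perm=200, seed=int(rng.integers(2**31)))
            rejections += res.p_values["x1"] < 0.05
        assert 0.024 <= rejections / n_rep <= 0.085

    def test_null_coefficient_series_lengths(self, rng):
        net = _random_symmetric(rng, 8)
        pred = _random_symmetric(rng, 8, net.individual_ids)
        res = qap_regression(net, [pred], n_perm=77, seed=3)
        assert res.n_permutations == 77
        assert len(res.null_coefficients["x1"]) == 77


class TestMrqapDsp:
    def test_single_predictor_agrees_with_qap(self, rng):
        dep = _random_symmetric(rng, 15)
        pred = WeightedNetwork(
            np.round(dep.adjacency * 0.5 + _random_symmetric(rng, 15).adjacency, 6),
            dep.individual_ids,
        )
        q = qap_regression(dep, [pred], n_perm=1000, seed=21)
        d = mrqap_dsp(dep, [pred], n_perm=1000, seed=22)
        assert abs(q.p_values["x1"] - d.p_values["x1"]) < 0.05

    def test_coefficients_equal_plain_ols_regardless_of_scheme(self, rng):
        dep = _random_symmetric(rng, 10)
        p1 = _random_symmetric(rng, 10, dep.individual_ids)
        p2 = _random_symmetric(rng, 10, dep.individual_ids)
        q = qap_regression(dep, [p1, p2], n_perm=20, seed=1)
        d = mrqap_dsp(dep, [p1, p2], n_perm=20, seed=2)
        for name in ("x1", "x2"):
            assert q.coefficients[name] == pytest.approx(d.coefficients[name])

    def test_signal_and_noise_predictors_separate(self, rng):
        n = 20
        x1 = _random_symmetric(rng, n)
        x2 = _random_symmetric(rng, n, x1.individual_ids)
        noise = _random_symmetric(rng, n, x1.individual_ids)
        dep = WeightedNetwork(
            2 * x1.adjacency + 0.3 * noise.adjacency, x1.individual_ids
        )
        res = mrqap_dsp(dep, [x1, x2], n_perm=500, seed=9)
        assert res.p_values["x1"] < 0.01
        assert res.p_values["x2"] > 0.05
        assert res.coefficients["x1"] == pytest.approx(2.0, abs=0.25)


class TestMrqapCustomNull:
    def test_degenerate_null_identical_to_observed_gives_p_one(self, rng):
        dep = _random_symmetric(rng, 8)
        pred = _random_symmetric(rng, 8, dep.individual_ids)
        res = mrqap_custom_null(dep, [pred], [dep.copy() for _ in range(30)])
        assert res.p_values["x1"] == 1.0
        assert res.n_permutations == 30

    def test_node_permuted_nulls_reproduce_qap(self, rng):
        dep = _random_symmetric(rng, 12)
        pred = WeightedNetwork(
            np.round(0.6 * dep.adjacency + 0.4 * _random_symmetric(rng, 12).adjacency, 6),
            dep.individual_ids,
        )
        q = qap_regression(dep, [pred], n_perm=1000, seed=31)
        perm_rng = np.random.default_rng(32)
        nulls = []
        for _ in range(1000):
            p = perm_rng.permutation(12)
            nulls.append(
                WeightedNetwork(dep.adjacency[np.ix_(p, p)], dep.individual_ids)
            )
        c = mrqap_custom_null(dep, [pred], nulls)
        assert abs(q.p_values["x1"] - c.p_values["x1"]) < 0.05

    def test_mismatched_nodes_rejected(self, rng):
        dep = _random_symmetric(rng, 6)
        pred = _random_symmetric(rng, 6, dep.individual_ids)
        alien = _random_symmetric(rng, 6, [f"x{k}" for k in range(6)])
        with pytest.raises(ValueError, match="share"):
            mrqap_custom_null(dep, [pred], [alien])


class TestSexCategoryPredictor:
    def test_category_matrix_plugs_into_qap(self, rng):
        gbi = random_gbi(rng, n_max=10, k_max=40)
        n = gbi.n_individuals
        nodes = NodeTable(
            list(gbi.individual_ids),
            {"sex": np.array((["M", "F"] * n)[:n], dtype=object)},
        )
        net = simple_ratio_index(gbi)
        res = qap_regression(net, [dyad_category_matrix(nodes)], n_perm=100, seed=2)
        assert "sex_category" in res.coefficients
        assert 0 <= res.p_values["sex_category"] <= 1


class TestCompareNetworks:
    def test_identical_data_give_zero_observed_difference(self, rng):
        gbi = random_gbi(rng, n_max=8, k_max=30)
        res = compare_networks(
            gbi,
            gbi.copy(),
            "mean_strength",
            method="datastream",
            chain=NullChainSpec(30, seed=3),
        )
        assert res.observed_statistic == pytest.approx(0.0)

    def test_swapping_networks_negates_the_observed_statistic(self, rng):
        a = random_gbi(np.random.default_rng(1), n_max=8, k_max=30)
        b = random_gbi(np.random.default_rng(2), n_max=8, k_max=30)
        r1 = compare_networks(a, b, "density", chain=NullChainSpec(10, seed=5))
        r2 = compare_networks(b, a, "density", chain=NullChainSpec(10, seed=5))
        assert r1.observed_statistic == pytest.approx(-r2.observed_statistic)

    def test_datastream_comparison_requires_gbi_inputs(self, rng):
        net = _random_symmetric(rng, 5)
        with pytest.raises(TypeError, match="GBI"):
            compare_networks(net, net, "density", method="datastream",
                             chain=NullChainSpec(5, seed=1))

    def test_edge_method_runs_on_networks(self, rng):
        a = simple_ratio_index(random_gbi(np.random.default_rng(3), n_max=8, k_max=30))
        b = simple_ratio_index(random_gbi(np.random.default_rng(4), n_max=8, k_max=30))
        res = compare_networks(a, b, "cv_edge_weights", method="edge",
                               chain=NullChainSpec(20, seed=9))
        assert res.n_permutations == 20
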