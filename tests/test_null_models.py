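"""Permutation engines: conservation laws, uniformity, reproducibility."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from socialnull import (
    FocalSample,
    FocalSampleSet,
    GroupByIndividualMatrix,
    NodeTable,
    NullChainSpec,
    SwapRestriction,
    TrajectorySet,
    WeightedNetwork,
    datastream_swap,
    edge_permutation,
    find_checkerboard,
    focal_swap,
    node_permutation,
    restricted_node_permutation,
    run_null_chain,
    track_identity_swap,
    trajectory_day_shuffle,
)
from socialnull.null_models import _FocalWorkspace

from conftest import random_gbi


class TestNodePermutation:
    def test_preserves_attribute_multiset_and_network_is_untouched(self, rng):
        nodes = NodeTable(
            [f"i{k}" for k in range(6)],
            {"sex": np.array(list("MMMFFF"), dtype=object)},
        )
        perm = node_permutation(nodes, rng)
        assert sorted(perm.get("sex")) == sorted(nodes.get("sex"))
        assert perm.individual_ids == nodes.individual_ids

    def test_single_attribute_value_is_invariant(self, rng):
        nodes = NodeTable(["a", "b", "c"], {"sex": np.array(["F"] * 3, dtype=object)})
        assert node_permutation(nodes, rng).get("sex").tolist() == ["F"] * 3

    def test_uniform_over_label_permutations(self):
        # 3 distinct labels -> 6 equally likely arrangements
        rng = np.random.default_rng(99)
        nodes = NodeTable(["a", "b", "c"], {"v": np.array(["x", "y", "z"], dtype=object)})
        counts = {}
        n_draws = 6000
        for _ in range(n_draws):
            key = tuple(node_permutation(nodes, rng).get("v"))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 0.01

    def test_joint_permutation_keeps_attributes_coherent(self, rng):
        nodes = NodeTable(
            ["a", "b", "c", "d"],
            {
                "sex": np.array(list("MFMF"), dtype=object),
                "rank": np.array([1, 2, 3, 4]),
            },
        )
        pairs = set(zip(nodes.get("sex"), nodes.get("rank")))
        perm = node_permutation(nodes, rng)
        assert set(zip(perm.get("sex"), perm.get("rank"))) == pairs


class TestRestrictedNodePermutation:
    def test_labels_never_cross_classes(self, rng):
        nodes = NodeTable(
            ["a", "b", "c", "d"],
            {"sex": np.array(list("MFMF"), dtype=object)},
        )
        grouping = np.array(["east", "east", "west", "west"])
        for _ in range(50):
            perm = restricted_node_permutation(nodes, grouping, rng)
            assert sorted(perm.get("sex")[:2]) == ["F", "M"]
            assert sorted(perm.get("sex")[2:]) == ["F", "M"]

    def test_singleton_classes_force_identity(self, rng):
        nodes = NodeTable(["a", "b"], {"sex": np.array(["M", "F"], dtype=object)})
        perm = restricted_node_permutation(nodes, np.array([0, 1]), rng)
        assert perm.get("sex").tolist() == ["M", "F"]

    def test_grouping_by_attribute_name(self, rng):
        nodes = NodeTable(
            ["a", "b", "c"],
            {
                "sex": np.array(list("MFF"), dtype=object),
                "site": np.array(["n", "n", "s"], dtype=object),
            },
        )
        perm = restricted_node_permutation(nodes, "site", rng)
        assert perm.get("sex")[2] == "F"


class TestEdgePermutation:
    def test_single_edge_moves_among_dyads(self, rng):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.7
        net = WeightedNetwork(a, list("abc"))
        seen = set()
        for _ in range(60):
            out = edge_permutation(net, rng)
            w = out.upper_triangle()
            assert np.count_nonzero(w) == 1 and w.sum() == pytest.approx(0.7)
            seen.add(int(np.nonzero(w)[0][0]))
        assert seen == {0, 1, 2}  # every dyad is reachable

    def test_weight_multiset_preserved(self, rng):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.2
        a[2, 3] = a[3, 2] = 0.7
        net = WeightedNetwork(a, list("abcd"))
        out = edge_permutation(net, rng)
        assert sorted(out.nonzero_edge_weights()) == [0.2, 0.7]

    def test_complete_network_keeps_density_one(self, rng):
        a = np.array(
            [[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]]
        )
        net = WeightedNetwork(a, list("abc"))
        out = edge_permutation(net, rng)
        assert sorted(out.nonzero_edge_weights()) == [1.0, 2.0, 3.0]
        assert np.count_nonzero(out.upper_triangle()) == 3


class TestCheckerboard:
    def test_unique_checkerboard_found(self, rng):
        gbi = GroupByIndividualMatrix(np.array([[1, 0], [0, 1]]), ["A", "B"])
        i, j, a, b = find_checkerboard(gbi, rng=rng)
        assert {(i, a), (j, b)} == {(0, 0), (1, 1)} or {(i, b), (j, a)} == {
            (0, 1),
            (1, 0),
        }

    def test_saturated_matrix_has_none(self, rng):
        gbi = GroupByIndividualMatrix(np.ones((2, 2), dtype=int), ["A", "B"])
        assert find_checkerboard(gbi, rng=rng, max_attempts=2000) is None

    def test_day_restriction_can_block_all_swaps(self, rng):
        gbi = GroupByIndividualMatrix(
            np.array([[1, 0], [0, 1]]), ["A", "B"], event_day=[1, 2]
        )
        r = SwapRestriction(within_day=True)
        assert find_checkerboard(gbi, r, rng, max_attempts=2000) is None

    def test_restriction_without_metadata_rejected(self, rng):
        gbi = GroupByIndividualMatrix(np.array([[1, 0], [0, 1]]), ["A", "B"])
        with pytest.raises(ValueError, match="event_day"):
            find_checkerboard(gbi, SwapRestriction(within_day=True), rng)

    def test_uniform_among_candidates(self):
        # [[1,0],[0,1]] has exactly 2 ordered candidate tuples; check both 50/50
        rng = np.random.default_rng(4)
        gbi = GroupByIndividualMatrix(np.array([[1, 0], [0, 1]]), ["A", "B"])
        counts = {}
        for _ in range(2000):
            found = find_checkerboard(gbi, rng=rng)
            counts[found] = counts.get(found, 0) + 1
        assert len(counts) == 2
        assert stats.chisquare(list(counts.values())).pvalue > 0.01

    def test_two_by_two_swap_flips_the_board(self, rng):
        gbi = GroupByIndividualMatrix(np.array([[1, 0], [0, 1]]), ["A", "B"])
        out = datastream_swap(gbi, rng=rng)
        assert out.membership.tolist() == [[0, 1], [1, 0]]

    @pytest.mark.filterwarnings("ignore:no swappable checkerboard")
    @given(st.integers(0, 10_000))
    def test_margins_conserved_under_chained_swaps(self, seed):
        rng = np.random.default_rng(seed)
        gbi = random_gbi(rng, n_max=8, k_max=20, with_metadata=True)
        rows, cols = gbi.group_sizes, gbi.observation_counts
        working = gbi
        for _ in range(20):
            working = datastream_swap(working, rng=rng, max_attempts=500)
        assert np.array_equal(working.group_sizes, rows)
        assert np.array_equal(working.observation_counts, cols)

    def test_time_restricted_swaps_stay_within_period(self):
        rng = np.random.default_rng(8)
        gbi = random_gbi(rng, n_max=8, k_max=30, with_metadata=True)
        r = SwapRestriction(within_time=True)
        for _ in range(100):
            found = find_checkerboard(gbi, r, rng)
            if found is None:
                continue
            _, _, a, b = found
            assert gbi.event_time[a] == gbi.event_time[b]


class TestFocalSwap:
    def _set(self, pairs):
        return FocalSampleSet(
            [
                FocalSample(f"s{k}", focal, frozenset(assoc))
                for k, (focal, assoc) in enumerate(pairs)
            ],
            individual_ids=list("ABCDEF"),
        )

    def test_smallest_legal_swap(self, rng):
        focals = self._set([("A", {"B"}), ("C", {"D"})])
        out = focal_swap(focals, rng=rng)
        assert out.samples[0].associate_ids == {"D"}
        assert out.samples[1].associate_ids == {"B"}

    def test_shared_individual_blocks_swap(self, rng):
        focals = self._set([("A", {"B"}), ("C", {"B"})])
        with pytest.warns(UserWarning, match="no legal focal swap"):
            out = focal_swap(focals, rng=rng, max_attempts=200)
        assert [s.associate_ids for s in out] == [{"B"}, {"B"}]

    def test_associate_equal_to_other_focal_blocks_swap(self, rng):
        focals = self._set([("A", {"C"}), ("C", {"A"})])
        with pytest.warns(UserWarning):
            out = focal_swap(focals, rng=rng, max_attempts=200)
        assert [s.associate_ids for s in out] == [{"C"}, {"A"}]

    def test_conservation_over_many_swaps(self, rng):
        samples = []
        ids = [f"i{k}" for k in range(12)]
        for k in range(30):
            focal = ids[rng.integers(0, 12)]
            others = [i for i in ids if i != focal]
            assoc = frozenset(
                others[j] for j in rng.choice(11, rng.integers(1, 5), replace=False)
            )
            samples.append(FocalSample(f"s{k}", focal, assoc))
        focals = FocalSampleSet(samples, ids)
        sizes = [len(s.associate_ids) for s in focals]
        occ = focals.occurrence_counts()
        ws = _FocalWorkspace(focals)
        done = sum(
            ws.try_swap(SwapRestriction(), rng, None, 500) for _ in range(500)
        )
        assert done > 0
        out = ws.to_focal_set()
        assert [len(s.associate_ids) for s in out] == sizes
        assert out.occurrence_counts() == occ
        for s in out:
            assert s.focal_id not in s.associate_ids


class TestTrajectoryNulls:
    def _traj(self, rng, n=3, d=4, s=5):
        pos = rng.integers(0, 6, (n, d, s, 2))
        return TrajectorySet([f"i{k}" for k in range(n)], pos, (6, 6))

    def test_two_day_shuffle_has_two_outcomes(self, rng):
        pos = np.zeros((1, 2, 2, 2), dtype=int)
        pos[0, 1] = 3  # day 2 distinct from day 1
        traj = TrajectorySet(["a"], pos, (6, 6))
        outcomes = set()
        for _ in range(40):
            out = trajectory_day_shuffle(traj, rng)
            outcomes.add(out.positions.tobytes())
        assert len(outcomes) == 2

    def test_day_shuffle_preserves_each_individuals_track_multiset(self, rng):
        traj = self._traj(rng)
        out = trajectory_day_shuffle(traj, rng)
        for i in range(traj.n_individuals):
            before = sorted(traj.positions[i, d].tobytes() for d in range(traj.n_days))
            after = sorted(out.positions[i, d].tobytes() for d in range(traj.n_days))
            assert before == after

    def test_day_shuffle_on_identical_constant_tracks_is_invariant(self, rng):
        from socialnull import simple_ratio_index, trajectories_to_gbi

        pos = np.tile(np.array([2, 2]), (3, 4, 5, 1))
        traj = TrajectorySet(["a", "b", "c"], pos, (6, 6))
        net = simple_ratio_index(trajectories_to_gbi(traj))
        out = trajectory_day_shuffle(traj, rng)
        net2 = simple_ratio_index(trajectories_to_gbi(out))
        assert np.array_equal(net.adjacency, net2.adjacency)

    def test_identity_swap_preserves_daily_track_sets_not_individual_ones(self, rng):
        traj = self._traj(rng)
        out = track_identity_swap(traj, rng)
        for d in range(traj.n_days):
            before = sorted(traj.positions[i, d].tobytes() for i in range(3))
            after = sorted(out.positions[i, d].tobytes() for i in range(3))
            assert before == after
        # across many draws some individual's own track multiset must change
        changed = False
        for _ in range(20):
            out = track_identity_swap(traj, rng)
            for i in range(3):
                if sorted(
                    traj.positions[i, d].tobytes() for d in range(4)
                ) != sorted(out.positions[i, d].tobytes() for d in range(4)):
                    changed = True
        assert changed

    def test_day_shuffle_requires_two_days(self, rng):
        pos = np.zeros((1, 1, 2, 2), dtype=int)
        with pytest.raises(ValueError, match="2 days"):
            trajectory_day_shuffle(TrajectorySet(["a"], pos, (3, 3)), rng)


class TestChainRunner:
    def _statistic(self):
        def stat(data, nodes):
            return float(data.membership.sum(axis=0)[0])  # observations of id 0

        return stat

    def test_null_series_has_requested_length(self, rng):
        gbi = random_gbi(rng, n_max=8, k_max=30)
        res = run_null_chain(
            gbi, "datastream", NullChainSpec(n_permutations=100, seed=5), self._statistic()
        )
        assert res.n_permutations == 100
        assert len(res.null_statistics) == 100

    def test_conserved_statistic_gives_constant_null_series(self, rng):
        gbi = random_gbi(rng, n_max=8, k_max=30)

        def total_observations(data, nodes):
            return float(data.membership.sum())

        res = run_null_chain(
            gbi, "datastream", NullChainSpec(50, seed=2), total_observations
        )
        assert np.all(res.null_statistics == res.observed_statistic)
        assert res.p_two_tailed == 1.0

    def test_single_swap_changes_at_most_four_cells(self):
        rng = np.random.default_rng(0)
        gbi = random_gbi(rng, n_max=8, k_max=30)
        observed = gbi.membership.copy()
        diffs = []

        def track_diff(data, nodes):
            diffs.append(int(np.abs(data.membership - observed).sum()))
            return 0.0

        run_null_chain(gbi, "datastream", NullChainSpec(1, 1, 0, seed=3), track_diff)
        # first call is the observed data, second the chain after one swap
        assert diffs[0] == 0 and diffs[1] <= 4

    def test_identical_seed_gives_bit_identical_results(self, rng):
        gbi = random_gbi(rng, n_max=8, k_max=30)
        stat = self._statistic()
        spec = NullChainSpec(50, 2, 10, seed=77)
        a = run_null_chain(gbi, "datastream", spec, stat)
        b = run_null_chain(gbi, "datastream", spec, stat)
        assert a.observed_statistic == b.observed_statistic
        assert np.array_equal(a.null_statistics, b.null_statistics)
        assert a.summary() == b.summary()

    def test_node_chain_leaves_data_untouched_and_uses_fresh_draws(self, rng):
        gbi = random_gbi(rng, n_max=6, k_max=20)
        membership_before = gbi.membership.copy()
        nodes = NodeTable(
            list(gbi.individual_ids),
            {"sex": np.array(["F", "M"] * (gbi.n_individuals // 2 + 1), dtype=object)[
                : gbi.n_individuals
            ]},
        )

        def label_hash(data, nd):
            return float(sum(v == "F" for v in nd.get("sex")[:2]))

        res = run_null_chain(
            gbi, "node", NullChainSpec(80, seed=6), label_hash, nodes=nodes
        )
        assert np.array_equal(gbi.membership, membership_before)
        assert len(set(res.null_statistics.tolist())) > 1  # independent redraws vary

    def test_missing_statistics_excluded_from_denominator(self, rng):
        gbi = random_gbi(rng, n_max=6, k_max=20)
        calls = {"n": 0}

        def flaky(data, nodes):
            calls["n"] += 1
            return np.nan if calls["n"] % 2 == 0 else 1.0

        res = run_null_chain(gbi, "datastream", NullChainSpec(10, seed=4), flaky)
        assert res.n_missing > 0
        assert res.n_missing + np.isfinite(res.null_statistics).sum() == 10

    def test_unswappable_data_records_unchanged_statistic(self):
        gbi = GroupByIndividualMatrix(np.ones((2, 2), dtype=int), ["A", "B"])

        def stat(data, nodes):
            return float(data.membership[0, 0])

        res = run_null_chain(
            gbi, "datastream", NullChainSpec(5, seed=1), stat, max_attempts=200
        )
        assert res.n_failed_swaps == 5
        assert np.all(res.null_statistics == res.observed_statistic)

    def test_incompatible_method_and_data_rejected(self, rng):
        gbi = random_gbi(rng)
        with pytest.raises(TypeError, match="FocalSampleSet"):
            run_null_chain(gbi, "focal", NullChainSpec(5, seed=1), self._statistic())
        with pytest.raises(ValueError, match="unknown null method"):
            run_null_chain(gbi, "bootstrap", NullChainSpec(5, seed=1), self._statistic())

    def test_chain_spec_validation(self):
        with pytest.raises(ValueError):
            NullChainSpec(n_permutations=0)
        with pytest.raises(ValueError):
            NullChainSpec(burn_in=-1)

    def test_datastream_chain_states_uniform_on_permutation_matrices(self):
        # 3x3 permutation-matrix GBIs form a symmetric swap graph over 6 states:
        # the chain's stationary law is uniform there.
        rng = np.random.default_rng(11)
        gbi = GroupByIndividualMatrix(np.eye(3, dtype=int), ["A", "B", "C"])
        working = gbi.copy()
        counts = {}
        for _ in range(3000):
            for _ in range(5):
                found = find_checkerboard(working, rng=rng)
                if found is not None:
                    i, j, a, b = found
                    working.membership[a, i] = 0
                    working.membership[a, j] = 1
                    working.membership[b, i] = 1
                    working.membership[b, j] = 0
            counts[working.membership.tobytes()] = (
                counts.get(working.membership.tobytes(), 0) + 1
            )
        assert len(counts) == 6
        assert stats.chisquare(list(counts.values())).pvalue > 0.01
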