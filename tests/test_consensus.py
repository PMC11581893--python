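"""Consensus builders: ladder, distance-dependent and consistency."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynconsensus import (
    BinaryConnectome,
    Cohort,
    WeightedConnectome,
    build_ladder,
    consistency_consensus,
    density,
    distance_dependent_consensus,
    edge_prevalence,
    euclidean_distance_matrix,
    min_subject_count,
    prevalence_histogram,
    uniform_consensus,
)
from dynconsensus.synthetic import synthetic_node_table

from conftest import adjacency_from_edges, make_binary, make_weighted, random_binary_cohort


class TestEdgePrevalence:
    def test_identical_members_counts_zero_or_n(self):
        net = make_binary(adjacency_from_edges(5, [(0, 1), (2, 3)]))
        prev = edge_prevalence(Cohort(members=[net] * 4))
        assert set(np.unique(prev)) <= {0, 4}
        assert prev[0, 1] == 4 and prev[0, 2] == 0

    def test_hand_count(self):
        a = make_binary(adjacency_from_edges(3, [(0, 1), (1, 2)]))
        b = make_binary(adjacency_from_edges(3, [(0, 1)]))
        c = make_binary(adjacency_from_edges(3, [(0, 2)]))
        prev = edge_prevalence(Cohort(members=[a, b, c]))
        assert prev[0, 1] == 2 and prev[1, 2] == 1 and prev[0, 2] == 1

    def test_weighted_cohort_rejected(self):
        w = make_weighted(np.zeros((3, 3)))
        with pytest.raises(TypeError, match="binarize"):
            edge_prevalence(Cohort(members=[w, w]))

    def test_empty_members(self):
        net = make_binary(np.zeros((4, 4), dtype=np.int8))
        prev = edge_prevalence(Cohort(members=[net, net]))
        assert prev.sum() == 0


class TestPrevalenceHistogram:
    def test_identical_members_mass_at_extremes(self):
        net = make_binary(adjacency_from_edges(4, [(0, 1), (2, 3), (0, 2)]))
        cohort = Cohort(members=[net] * 3)
        hist = prevalence_histogram(edge_prevalence(cohort), 3)
        rho = density(net)
        assert hist[3] == pytest.approx(rho)
        assert hist[0] == pytest.approx(1 - rho)
        assert hist[1] == hist[2] == 0

    def test_sums_to_one_and_matches_enumeration(self):
        cohort = random_binary_cohort(3, 6, p=0.4, seed=5)
        hist = prevalence_histogram(edge_prevalence(cohort), 3)
        assert hist.sum() == pytest.approx(1.0)
        # brute force over pairs
        counts = np.zeros(4)
        for i, j in itertools.combinations(range(6), 2):
            c = sum(m.adjacency[i, j] for m in cohort)
            counts[c] += 1
        np.testing.assert_allclose(hist, counts / counts.sum())


class TestUniformConsensus:
    def test_min_count_anchor_42_5_of_40(self):
        assert min_subject_count(42.5, 40) == 17

    def test_min_count_exact_on_all_ladder_thresholds(self):
        for n in (3, 7, 40, 41):
            for k in range(1, n + 1):
                assert min_subject_count(k * 100.0 / n, n) == k

    def test_union_and_intersection_limits(self):
        cohort = random_binary_cohort(4, 8, p=0.3, seed=2)
        prev = edge_prevalence(cohort)
        union = uniform_consensus(cohort, 100.0 / 4)
        inter = uniform_consensus(cohort, 100.0)
        np.testing.assert_array_equal(union.adjacency, (prev >= 1).astype(np.int8))
        np.testing.assert_array_equal(inter.adjacency, (prev >= 4).astype(np.int8))

    def test_threshold_667_brute_force(self):
        cohort = random_binary_cohort(3, 6, p=0.5, seed=9)
        net = uniform_consensus(cohort, 66.7)
        for i, j in itertools.combinations(range(6), 2):
            expected = int(sum(m.adjacency[i, j] for m in cohort) >= 2)
            assert net.adjacency[i, j] == expected

    def test_invalid_threshold(self):
        cohort = random_binary_cohort(2, 4, seed=0)
        for t in (0, -5, 101):
            with pytest.raises(ValueError):
                uniform_consensus(cohort, t)


class TestBuildLadder:
    def test_ladder_size_equals_cohort_size(self):
        cohort = random_binary_cohort(5, 8, seed=1)
        ladder = build_ladder(cohort)
        assert len(ladder) == 5
        assert ladder.thresholds[0] == pytest.approx(20.0)
        assert ladder.thresholds[-1] == pytest.approx(100.0)

    def test_single_member_ladder(self):
        cohort = random_binary_cohort(1, 6, seed=3)
        ladder = build_ladder(cohort)
        assert len(ladder) == 1
        np.testing.assert_array_equal(
            ladder[100.0].adjacency, cohort[0].adjacency
        )

    def test_identical_cohort_all_rungs_equal(self):
        net = make_binary(adjacency_from_edges(5, [(0, 1), (3, 4)]))
        ladder = build_ladder(Cohort(members=[net] * 4))
        for t in ladder:
            np.testing.assert_array_equal(ladder[t].adjacency, net.adjacency)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_subj=st.integers(2, 8))
    def test_nesting_property(self, seed, n_subj):
        cohort = random_binary_cohort(n_subj, 7, p=0.5, seed=seed)
        ladder = build_ladder(cohort)
        prev_edges = None
        for t in ladder:
            edges = ladder[t].edge_set()
            if prev_edges is not None:
                assert edges <= prev_edges
            prev_edges = edges
        union = {e for m in cohort for e in m.edge_set()}
        inter = set.intersection(*(m.edge_set() for m in cohort))
        assert ladder[ladder.thresholds[0]].edge_set() == union
        assert ladder[100.0].edge_set() == inter


class TestEuclideanDistanceMatrix:
    def test_three_four_five(self):
        nodes = synthetic_node_table(["a", "b"], rng_seed=0)
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        nodes = type(nodes)(labels=nodes.labels, hemispheres=nodes.hemispheres,
                            coords=coords)
        d = euclidean_distance_matrix(nodes)
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        nodes = synthetic_node_table(6, rng_seed=seed)
        d = euclidean_distance_matrix(nodes)
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9


class TestDistanceDependentConsensus:
    def test_identical_cohort_fixed_point(self):
        cohort = random_binary_cohort(1, 10, p=0.5, seed=4)
        members = [cohort[0]] * 5
        cohort5 = Cohort(members=members)
        out = distance_dependent_consensus(cohort5)
        np.testing.assert_array_equal(out.adjacency, cohort5[0].adjacency)

    def test_tie_rule_shorter_distance_wins(self):
        # 4 left-hemisphere nodes on a line; one bin spanning all pairs
        nodes = synthetic_node_table(["a", "b", "c", "d"], rng_seed=0)
        coords = np.array([[-10.0, 0, 0], [-9.0, 0, 0], [-5.0, 0, 0], [-1.0, 0, 0]])
        nodes = type(nodes)(labels=nodes.labels,
                            hemispheres=("left",) * 4, coords=coords)
        # prevalences: (0,1): 2 subjects; (0,2): 1; (0,3): 1
        s1 = BinaryConnectome(adjacency=adjacency_from_edges(4, [(0, 1), (0, 2)]),
                              nodes=nodes)
        s2 = BinaryConnectome(adjacency=adjacency_from_edges(4, [(0, 1), (0, 3)]),
                              nodes=nodes)
        cohort = Cohort(members=[s1, s2])
        out = distance_dependent_consensus(cohort, n_bins=1)
        # m = round(mean edges) = 2: keep (0,1) [prevalence 2] and the
        # shorter of (0,2) vs (0,3): distance 5 vs 9 -> (0,2)
        assert out.edge_set() == {(0, 1), (0, 2)}

    def test_density_close_to_mean_member_density(self):
        cohort = random_binary_cohort(8, 30, p=0.4, seed=6)
        n_bins = 10
        out = distance_dependent_consensus(cohort, n_bins=n_bins)
        mean_edges = np.mean([m.n_edges for m in cohort])
        # rounding slack: at most 0.5 edges per (class, bin)
        assert abs(out.n_edges - mean_edges) <= 2 * n_bins * 0.5 + 1

    def test_never_retains_universally_absent_pair(self):
        cohort = random_binary_cohort(6, 12, p=0.3, seed=7)
        out = distance_dependent_consensus(cohort)
        union = {e for m in cohort for e in m.edge_set()}
        assert out.edge_set() <= union

    def test_invalid_bins(self):
        cohort = random_binary_cohort(2, 5, seed=0)
        with pytest.raises(ValueError):
            distance_dependent_consensus(cohort, n_bins=0)


class TestConsistencyConsensus:
    def _weighted_cohort(self, weight_lists, n):
        """Cohort from per-pair weight sequences (dict pair -> per-subject)."""
        n_subj = len(next(iter(weight_lists.values())))
        nodes = synthetic_node_table(n, rng_seed=0)
        members = []
        for s in range(n_subj):
            w = np.zeros((n, n))
            for (i, j), vals in weight_lists.items():
                w[i, j] = w[j, i] = vals[s]
            members.append(WeightedConnectome(weights=w, nodes=nodes))
        return Cohort(members=members, nodes=nodes)

    def test_cv_ranking_hand_arithmetic(self):
        cohort = self._weighted_cohort(
            {(0, 1): (10, 10, 10), (0, 2): (10, 20, 30)}, n=4
        )
        # CV(0,1) = 0; CV(0,2) = 10/20 = 0.5; keep only the lowest-CV pair
        out = consistency_consensus(cohort, target_density=1 / 6)
        assert out.edge_set() == {(0, 1)}

    def test_exact_edge_count(self):
        rng = np.random.default_rng(8)
        nodes = synthetic_node_table(10, rng_seed=0)
        members = []
        for _ in range(5):
            w = np.triu(rng.random((10, 10)), k=1)
            w = w + w.T
            members.append(WeightedConnectome(weights=w, nodes=nodes))
        cohort = Cohort(members=members, nodes=nodes)
        for target in (0.2, 0.5, 0.8):
            out = consistency_consensus(cohort, target)
            assert out.n_edges == int(np.floor(target * 45))

    def test_identical_members_fixed_point_at_member_density(self):
        rng = np.random.default_rng(9)
        w = np.triu((rng.random((8, 8)) < 0.5) * rng.integers(1, 50, (8, 8)), k=1)
        w = (w + w.T).astype(float)
        member = make_weighted(w)
        cohort = Cohort(members=[member] * 4)
        target = (w > 0).sum() / 2 / 28
        out = consistency_consensus(cohort, target)
        np.testing.assert_array_equal(out.adjacency, (w > 0).astype(np.int8))

    def test_infeasible_target_keeps_all_and_warns(self):
        cohort = self._weighted_cohort({(0, 1): (5, 5)}, n=4)
        with pytest.warns(UserWarning, match="nonzero mean"):
            out = consistency_consensus(cohort, target_density=1.0)
        assert out.edge_set() == {(0, 1)}

    def test_binary_cohort_rejected(self):
        net = make_binary(np.zeros((3, 3), dtype=np.int8))
        with pytest.raises(TypeError, match="weighted"):
            consistency_consensus(Cohort(members=[net, net]), 0.5)
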