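import itertools

import numpy as np
import pytest

from hungclust.assignment import Permutation, decompose_cycles, is_identity
from hungclust.core import (
    ClusterState,
    Config,
    build_cost_matrix,
    compute_eta,
    init_state,
    inter_cluster_matrix,
    iterate_once,
    merge_clusters,
    run,
    single_cycle_stop_check,
)
from hungclust.geometry import DistanceMatrix, PointSet, pairwise_distances


def exhaustive_objective(C: np.ndarray, eta: float) -> float:
    """Brute-force oracle for the per-iteration objective O(sigma)."""
    k = C.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(k)):
        cost = sum(eta if perm[j] == j else C[j, perm[j]] for j in range(k))
        best = min(best, cost)
    return best


class TestInitState:
    def test_singletons(self):
        state = init_state(3)
        assert state.k == 3 and state.members == ((0,), (1,), (2,))

    def test_representatives_are_the_points(self, two_pairs):
        state = init_state(4, two_pairs, Config())
        np.testing.assert_allclose(state.representatives[2].coords, [10.0, 0.0])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            init_state(0)


class TestComputeEta:
    def test_two_clusters(self):
        assert compute_eta(np.array([[0.0, 10.0], [10.0, 0.0]])) == pytest.approx(5.0)

    def test_equilateral(self):
        C = np.ones((3, 3)) - np.eye(3)
        assert compute_eta(C) == pytest.approx(0.5)

    def test_two_pair_centers(self, two_pairs):
        # sum of the 6 pairwise distances is 42.0998; eta = that / 12
        C = pairwise_distances(two_pairs).values
        assert compute_eta(C) == pytest.approx(3.5083, abs=1e-4)

    def test_both_printed_forms_agree(self, rng):
        # sum_{j<l} / (k(k-1)) vs full ordered double sum / (2k(k-1))
        for _ in range(20):
            k = int(rng.integers(2, 10))
            C = pairwise_distances(PointSet(coords=rng.normal(size=(k, 2)))).values
            upper = sum(C[j, l] for j in range(k) for l in range(j + 1, k))
            assert compute_eta(C) == pytest.approx(upper / (k * (k - 1)), abs=1e-12)

    def test_undefined_below_two(self):
        with pytest.raises(ValueError):
            compute_eta(np.zeros((1, 1)))


class TestCostMatrix:
    def test_diagonal_is_penalty(self):
        C = np.array([[0.0, 10.0], [10.0, 0.0]])
        M = build_cost_matrix(C, [5.0, 5.0])
        np.testing.assert_allclose(M, [[5.0, 10.0], [10.0, 5.0]])

    def test_k2_identity_beats_swap(self):
        # identity cost 2*eta = 10 < swap cost 20: the last two never merge
        M = build_cost_matrix(np.array([[0.0, 10.0], [10.0, 0.0]]), [5.0, 5.0])
        assert M[0, 0] + M[1, 1] < M[0, 1] + M[1, 0]

    def test_rejects_negative_penalty(self):
        with pytest.raises(ValueError, match="nonnegative"):
            build_cost_matrix(np.zeros((2, 2)), [-1.0, 1.0])


class TestInterClusterMatrix:
    def test_singletons_reproduce_point_distances(self, two_pairs):
        state = init_state(4, two_pairs, Config())
        C = inter_cluster_matrix(state, None, Config())
        np.testing.assert_allclose(C, pairwise_distances(two_pairs).values, atol=1e-12)

    def test_centroid_mode_two_pairs(self, two_pairs):
        state = ClusterState(
            members=((0, 1), (2, 3)),
            representatives=tuple(
                __import__("hungclust.geometry", fromlist=["representative"]).representative(two_pairs, S)
                for S in ((0, 1), (2, 3))
            ),
        )
        C = inter_cluster_matrix(state, None, Config())
        np.testing.assert_allclose(C, [[0.0, 10.0], [10.0, 0.0]])

    def test_average_mode_two_pairs(self, two_pairs):
        state = ClusterState(members=((0, 1), (2, 3)))
        D = pairwise_distances(two_pairs)
        C = inter_cluster_matrix(state, D, Config(cluster_distance_mode="average"))
        assert C[0, 1] == pytest.approx((20 + 2 * np.sqrt(101)) / 4)

    def test_centroid_mode_needs_points(self, two_pairs):
        state = ClusterState(members=((0, 1), (2, 3)))
        with pytest.raises(ValueError, match="centroid"):
            inter_cluster_matrix(state, pairwise_distances(two_pairs), Config())

    def test_average_matmul_matches_pairwise_loop(self, rng):
        from hungclust.geometry import cluster_distance

        coords = rng.normal(size=(9, 2))
        D = pairwise_distances(PointSet(coords=coords))
        members = ((0, 3, 4), (1, 2), (5, 6, 7, 8))
        state = ClusterState(members=members)
        C = inter_cluster_matrix(state, D, Config(cluster_distance_mode="average"))
        for a in range(3):
            for b in range(a + 1, 3):
                assert C[a, b] == pytest.approx(
                    cluster_distance(D, members[a], members[b], "average"))


class TestMergeClusters:
    def test_six_cluster_worked_example(self):
        # clusters {0},{1},... merged along cycles (1)(2,3,5)(4,6)
        coords = np.arange(12.0).reshape(6, 2)
        points = PointSet(coords=coords)
        state = init_state(6, points, Config())
        cycles = decompose_cycles(Permutation(mapping=(1, 3, 5, 6, 2, 4)))
        merged = merge_clusters(state, cycles, points, Config())
        assert merged.members == ((0,), (1, 2, 4), (3, 5))

    def test_identity_preserves_state(self, two_pairs):
        state = init_state(4, two_pairs, Config())
        cycles = decompose_cycles(Permutation(mapping=(1, 2, 3, 4)))
        assert merge_clusters(state, cycles, two_pairs, Config()).members == state.members

    def test_merged_representative_is_recomputed_mean(self):
        points = PointSet(coords=np.array([[0.0, 0.0], [0.0, 1.0]]))
        state = init_state(2, points, Config())
        cycles = decompose_cycles(Permutation(mapping=(2, 1)))
        merged = merge_clusters(state, cycles, points, Config())
        np.testing.assert_allclose(merged.representatives[0].coords, [0.0, 0.5])


class TestIterateOnce:
    def test_two_pair_first_iteration(self, two_pairs):
        state = init_state(4, two_pairs, Config())
        new_state, rec = iterate_once(state, None, two_pairs, Config())
        assert rec.permutation.mapping == (2, 1, 4, 3)
        assert rec.objective == pytest.approx(4.0)
        assert rec.eta == pytest.approx(42.0998 / 12, abs=1e-3)
        assert new_state.members == ((0, 1), (2, 3))

    def test_two_pair_second_iteration_is_identity(self, two_pairs):
        state = init_state(4, two_pairs, Config())
        state, _ = iterate_once(state, None, two_pairs, Config())
        state, rec = iterate_once(state, None, two_pairs, Config())
        assert is_identity(rec.permutation)
        assert rec.objective == pytest.approx(10.0)  # 2*eta with eta = 5

    def test_objective_matches_exhaustive_minimum(self, rng):
        for k in (3, 4, 5, 6):
            coords = rng.normal(size=(k, 2)) * 2
            points = PointSet(coords=coords)
            state = init_state(k, points, Config())
            C = inter_cluster_matrix(state, None, Config())
            eta = compute_eta(C)
            _, rec = iterate_once(state, None, points, Config())
            assert rec.objective == pytest.approx(exhaustive_objective(C, eta), abs=1e-10)

    def test_coincident_singletons_stay_apart(self):
        # d = 0 so eta = 0: zero-cost tie resolves to the identity
        points = PointSet(coords=np.zeros((2, 2)))
        state = init_state(2, points, Config())
        _, rec = iterate_once(state, None, points, Config())
        assert is_identity(rec.permutation)


class TestRun:
    def test_two_pair_full_run(self, two_pairs):
        res = run(two_pairs)
        assert res.k == 2
        np.testing.assert_array_equal(res.labels, [1, 1, 2, 2])
        assert res.n_iterations == 2
        assert is_identity(res.trace[-1].permutation)

    def test_single_point(self):
        res = run(np.array([[1.0, 2.0]]))
        assert res.k == 1 and res.n_iterations == 0 and res.labels[0] == 1

    def test_k_non_increasing_and_bounded_iterations(self, rng):
        coords = rng.normal(size=(30, 2))
        res = run(coords)
        ks = [r.k_before for r in res.trace] + [res.k]
        assert all(a >= b for a, b in zip(ks, ks[1:]))
        assert res.n_iterations <= 30
        assert res.converged

    def test_partition_valid_after_every_iteration(self, rng):
        points = PointSet(coords=rng.normal(size=(20, 2)))
        config = Config()
        state = init_state(20, points, config)
        while state.k >= 2:
            new_state, rec = iterate_once(state, None, points, config)
            covered = sorted(i for S in new_state.members for i in S)
            assert covered == list(range(20))
            if is_identity(rec.permutation):
                break
            state = new_state

    def test_k2_endpoint_never_merges(self, rng):
        # whenever the loop reaches exactly k = 2 distinct centroids,
        # identity cost 2*eta = d < merge cost 2d
        for seed in range(5):
            r = np.random.default_rng(seed)
            coords = np.vstack([r.normal(0, 0.05, (10, 2)), r.normal(5, 0.05, (10, 2))])
            res = run(coords)
            assert res.k == 2

    def test_relabeling_rows_permutes_labels(self, rng):
        coords = rng.normal(size=(15, 2)) * 3
        perm = rng.permutation(15)
        res1 = run(coords)
        res2 = run(coords[perm])
        # same partition modulo cluster renumbering: compare co-membership pairs
        pairs1 = {frozenset((a, b)) for S in res1.members for a in S for b in S if a < b}
        pairs2 = {frozenset((int(perm[a]), int(perm[b])))
                  for S in res2.members for a in S for b in S if a < b}
        assert pairs1 == pairs2

    def test_distance_matrix_mode(self, two_pairs):
        D = pairwise_distances(two_pairs)
        res = run(D, Config(cluster_distance_mode="average"))
        np.testing.assert_array_equal(res.labels, [1, 1, 2, 2])

    def test_distance_mode_falls_back_from_centroid_default(self, two_pairs):
        res = run(pairwise_distances(two_pairs))
        assert res.settings.cluster_distance_mode == "average"
        np.testing.assert_array_equal(res.labels, [1, 1, 2, 2])

    def test_max_iterations_flags_non_convergence(self, rng):
        coords = rng.normal(size=(40, 2))
        res = run(coords, Config(max_iterations=1))
        assert res.n_iterations == 1
        assert not res.converged or is_identity(res.trace[-1].permutation)

    def test_standardize_rescales_columns(self):
        # a dominating second column: without standardization it drives the
        # clustering; with it, both columns contribute equally
        rng = np.random.default_rng(5)
        coords = np.column_stack([rng.normal(0, 1, 40), rng.normal(0, 1000, 40)])
        res = run(coords, Config(standardize=True))
        assert res.k >= 1  # runs cleanly; scale no longer explodes eta
        assert max(r.eta for r in res.trace) < 10

    def test_cluster_utility_penalty_mode(self, two_pairs):
        res = run(two_pairs, Config(penalty_mode="cluster_utility"))
        assert res.k == 2
        np.testing.assert_array_equal(res.labels, [1, 1, 2, 2])

    def test_sphere_medoid_distance_only(self, rng):
        # medoid representatives work in a general metric
        coords = rng.normal(size=(12, 3))
        coords /= np.linalg.norm(coords, axis=1, keepdims=True)
        ps = PointSet(coords=coords, geometry="unit_sphere")
        res = run(ps, Config(metric="arc_length", representative_method="medoid"))
        assert sorted(i for S in res.members for i in S) == list(range(12))


class TestStopCheck:
    def test_k2_never_merges(self):
        assert single_cycle_stop_check(np.array([[0.0, 10.0], [10.0, 0.0]]))

    def test_equilateral_stops(self):
        C = np.ones((3, 3)) - np.eye(3)
        assert single_cycle_stop_check(C)

    def test_tiny_side_indicates_merge(self):
        # centroids at 0, 0.01, 10 on a line
        coords = np.array([[0.0], [0.01], [10.0]])
        C = pairwise_distances(PointSet(coords=coords)).values
        assert not single_cycle_stop_check(C)

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError, match="k <= 9"):
            single_cycle_stop_check(np.zeros((10, 10)))

    def test_equivalent_to_identity_being_strictly_optimal(self, rng):
        # additivity over cycles makes the single-cycle check certify the
        # full assignment optimum
        for _ in range(15):
            k = int(rng.integers(2, 7))
            C = pairwise_distances(PointSet(coords=rng.normal(size=(k, 2)) * 2)).values
            eta = compute_eta(C)
            identity_cost = k * eta
            best_other = min(
                sum(eta if p[j] == j else C[j, p[j]] for j in range(k))
                for p in itertools.permutations(range(k))
                if any(p[j] != j for j in range(k))
            )
            assert single_cycle_stop_check(C) == (identity_cost < best_other)
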