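"""The Hungarian clustering loop.

Agglomerative clustering with an automatic stopping rule.  Starting from n
singleton clusters, each iteration

1. builds the k x k inter-cluster distance matrix C (centroid-to-centroid
   by default, or a linkage distance computed purely from the point
   distances);
2. computes the merge penalty ``eta`` — half the average pairwise distance
   between the k current representatives,
   eta = sum_{j<l} C[j,l] / (k(k-1));
3. minimizes  O(sigma) = sum_j [ d(c_j, c_sigma(j)) + eta * 1(sigma(j)=j) ]
   over all permutations sigma on {1..k}, by exact linear assignment on the
   matrix whose off-diagonal is C and whose diagonal is the penalty;
4. merges the clusters lying on each cycle of the optimal permutation.

A cluster maps to itself only when staying alone (price eta) beats joining
a tour through other clusters, so the identity permutation is a natural
stopping point: the loop ends when sigma is the identity (or a single
cluster remains).  k never increases, so termination is guaranteed within
n iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .assignment import (
    CycleDecomposition,
    Permutation,
    assignment_cost,
    decompose_cycles,
    is_identity,
    solve_assignment,
)
from .geometry import (
    Centroid,
    DistanceMatrix,
    PointSet,
    cluster_distance,
    metric_distance,
    pairwise_distances,
    representative,
)
from .values import tour_value

CLUSTER_DISTANCE_MODES = ("centroid", "single", "average", "complete")
PENALTY_MODES = ("eta", "cluster_utility")


@dataclass(frozen=True)
class Config:
    """Settings of a clustering run.

    Parameters
    ----------
    metric
        Point-to-point distance: ``euclidean`` (default), ``sqeuclidean``
        for k-means-style comparisons, or ``arc_length`` for unit-sphere
        data.
    representative_method
        ``mean`` (arithmetic mean), ``extrinsic_sphere`` (renormalized
        mean), or ``medoid``.
    cluster_distance_mode
        ``centroid`` (distance between representatives, default for point
        input) or a linkage mode ``single`` / ``average`` / ``complete``
        computed from the member points only (required, default
        ``average``, when only a distance matrix is supplied).
    penalty_mode
        ``eta`` puts the penalty eta on every diagonal entry;
        ``cluster_utility`` prices staying alone at the cluster's own tour
        value u(S_j) for |S_j| > 1 (eta for singletons).
    max_iterations
        0 means unbounded; the loop terminates on its own regardless.
    standardize
        If true, each coordinate column is centred and scaled to unit
        standard deviation before distances are computed (point input only).
    seed
        Recorded for provenance; the algorithm itself is deterministic.
    """

    metric: str = "euclidean"
    representative_method: str = "mean"
    cluster_distance_mode: str = "centroid"
    penalty_mode: str = "eta"
    max_iterations: int = 0
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_distance_mode not in CLUSTER_DISTANCE_MODES:
            raise ValueError(f"unknown cluster_distance_mode {self.cluster_distance_mode!r}")
        if self.penalty_mode not in PENALTY_MODES:
            raise ValueError(f"unknown penalty_mode {self.penalty_mode!r}")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")


@dataclass(frozen=True)
class ClusterState:
    """A partition of {0..n-1} into k member sets with optional representatives."""

    members: tuple[tuple[int, ...], ...]
    representatives: tuple[Centroid, ...] | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        total = 0
        for S in self.members:
            if len(S) == 0:
                raise ValueError("clusters must be non-empty")
            total += len(S)
            seen.update(S)
        if len(seen) != total:
            raise ValueError("clusters must be pairwise disjoint")
        if seen != set(range(total)):
            raise ValueError("clusters must cover 0..n-1 exactly")
        if self.representatives is not None and len(self.representatives) != len(self.members):
            raise ValueError("one representative per cluster required")

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def n(self) -> int:
        return sum(len(S) for S in self.members)


@dataclass(frozen=True)
class IterationRecord:
    """What one iteration of the loop did."""

    iteration: int
    k_before: int
    k_after: int
    eta: float
    permutation: Permutation
    cycles: CycleDecomposition
    objective: float


@dataclass(frozen=True)
class ClusteringResult:
    """Final labels plus the per-iteration trace.

    ``labels[i]`` is the 1-based cluster of input row i; clusters are
    numbered in ascending order of their smallest member index.
    """

    labels: np.ndarray
    members: tuple[tuple[int, ...], ...]
    trace: tuple[IterationRecord, ...]
    settings: Config
    converged: bool
    ids: tuple[str, ...] | None = None

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def n_iterations(self) -> int:
        return len(self.trace)


def init_state(n: int, points: PointSet | None = None, config: Config | None = None) -> ClusterState:
    """n singleton clusters; each point is its own representative."""
    if n < 1:
        raise ValueError("need at least one observation")
    members = tuple((i,) for i in range(n))
    reps: tuple[Centroid, ...] | None = None
    if points is not None:
        method = (config or Config()).representative_method
        reps = tuple(Centroid(coords=points.coords[i], method=method) for i in range(n))
    return ClusterState(members=members, representatives=reps)


def compute_eta(C: np.ndarray) -> float:
    """Merge penalty: half the average pairwise distance between centroids.

    eta = sum_{j<l} C[j,l] / (k(k-1)), equivalently the full ordered double
    sum divided by 2k(k-1).  Undefined for k < 2.
    """
    C = np.asarray(C, dtype=float)
    k = C.shape[0]
    if k < 2:
        raise ValueError("eta is undefined for fewer than two clusters")
    return float(C.sum() / (2.0 * k * (k - 1)))


def build_cost_matrix(C: np.ndarray, penalty: Sequence[float] | np.ndarray) -> np.ndarray:
    """Assignment costs: off-diagonal = inter-cluster distance, diagonal = penalty."""
    C = np.asarray(C, dtype=float)
    pen = np.asarray(penalty, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("inter-cluster matrix must be square")
    if C.shape[0] < 2:
        raise ValueError("cost matrix needs at least two clusters")
    if pen.shape != (C.shape[0],):
        raise ValueError("one penalty per cluster required")
    if np.any(pen < 0):
        raise ValueError("penalties must be nonnegative")
    M = C.copy()
    np.fill_diagonal(M, pen)
    return M


def inter_cluster_matrix(
    state: ClusterState,
    D: DistanceMatrix | None,
    config: Config,
) -> np.ndarray:
    """k x k symmetric zero-diagonal matrix of distances between clusters."""
    k = state.k
    mode = config.cluster_distance_mode
    if mode == "centroid":
        if state.representatives is None:
            raise ValueError("centroid mode needs point coordinates; use a linkage mode "
                             "(single/average/complete) for distance-only input")
        reps = np.asarray([r.coords for r in state.representatives], dtype=float)
        if config.metric == "euclidean":
            C = cdist(reps, reps)
        elif config.metric == "sqeuclidean":
            C = cdist(reps, reps, metric="sqeuclidean")
        elif config.metric == "arc_length":
            C = np.arccos(np.clip(reps @ reps.T, -1.0, 1.0))
        else:
            raise ValueError(f"unknown metric {config.metric!r}")
        C = 0.5 * (C + C.T)
        np.fill_diagonal(C, 0.0)
        return C
    if D is None:
        raise ValueError("linkage modes require the point distance matrix")
    d = D.values
    if all(len(S) == 1 for S in state.members):  # singleton fast path
        order = [S[0] for S in state.members]
        return d[np.ix_(order, order)].copy()
    if mode == "average":
        # indicator aggregation: C = P^T D P / (sizes outer sizes)
        n = state.n
        P = np.zeros((n, k))
        for j, S in enumerate(state.members):
            P[list(S), j] = 1.0
        sizes = P.sum(axis=0)
        C = P.T @ d @ P / np.outer(sizes, sizes)
    else:
        C = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                C[a, b] = C[b, a] = cluster_distance(d, state.members[a], state.members[b], mode)
    np.fill_diagonal(C, 0.0)
    return 0.5 * (C + C.T)


def _penalties(state: ClusterState, D: DistanceMatrix | None, eta: float, config: Config) -> np.ndarray:
    if config.penalty_mode == "eta":
        return np.full(state.k, eta)
    if D is None:
        raise ValueError("cluster_utility penalty needs the point distance matrix")
    pen = np.empty(state.k)
    for j, S in enumerate(state.members):
        if len(S) == 1:
            pen[j] = eta
        else:
            idx = np.asarray(S, dtype=int)
            sub = D.values[np.ix_(idx, idx)]
            method = "exact" if len(S) <= 12 else "heuristic"
            pen[j] = tour_value(sub, method=method)
    return pen


def merge_clusters(
    state: ClusterState,
    cycles: CycleDecomposition,
    points: PointSet | None,
    config: Config,
) -> ClusterState:
    """One new cluster per orbit: the union of the member sets on the cycle.

    Representatives are recomputed from the raw member points of each union,
    not averaged from the previous centroids.
    """
    if cycles.count > state.k or sum(len(c) for c in cycles.cycles) != state.k:
        raise ValueError("cycle decomposition inconsistent with state")
    new_members: list[tuple[int, ...]] = []
    for cycle in cycles.cycles:
        merged: list[int] = []
        for cluster_index in cycle:  # 1-based cluster ids
            merged.extend(state.members[cluster_index - 1])
        new_members.append(tuple(sorted(merged)))
    new_members.sort(key=lambda S: S[0])
    reps: tuple[Centroid, ...] | None = None
    if points is not None:
        reps = tuple(
            representative(points, S, method=config.representative_method, metric=config.metric)
            for S in new_members
        )
    return ClusterState(members=tuple(new_members), representatives=reps)


def iterate_once(
    state: ClusterState,
    D: DistanceMatrix | None,
    points: PointSet | None,
    config: Config,
    iteration: int = 1,
) -> tuple[ClusterState, IterationRecord]:
    """One assignment-and-merge step; requires k >= 2."""
    if state.k < 2:
        raise ValueError("iteration requires at least two clusters")
    C = inter_cluster_matrix(state, D, config)
    # eta = 0 only when all representatives coincide; the zero-cost tie
    # between identity and any merge then resolves to the identity via the
    # lexicographic tie-break of the assignment solver
    eta = compute_eta(C)
    M = build_cost_matrix(C, _penalties(state, D, eta, config))
    perm = solve_assignment(M)
    cyc = decompose_cycles(perm)
    record = IterationRecord(
        iteration=iteration,
        k_before=state.k,
        k_after=cyc.count,
        eta=float(eta),
        permutation=perm,
        cycles=cyc,
        objective=assignment_cost(M, perm),
    )
    new_state = state if is_identity(perm) else merge_clusters(state, cyc, points, config)
    return new_state, record


def single_cycle_stop_check(C: np.ndarray) -> bool:
    """True when no further merging is indicated at the current k.

    Compares the average self cohesion eta against the cheapest permutation
    containing a single non-trivial cycle: fixed points keep their
    self-cohesion price eta, the points on the cycle pay the tour legs.
    The check is true iff

        eta < min_sigma (1/k) sum_i [ d(c_i, c_sigma(i)) + eta 1(sigma(i)=i) ]

    over permutations sigma with exactly one cycle of length >= 2.  Because
    the objective is additive over cycles, this is equivalent to the identity
    permutation being the strict optimum of the full assignment problem —
    the loop's actual stopping condition.  Exhaustive enumeration, guarded
    to k <= 9.
    """
    import itertools

    C = np.asarray(C, dtype=float)
    k = C.shape[0]
    if k < 2:
        raise ValueError("stop check requires at least two clusters")
    if k > 9:
        raise ValueError("single-cycle enumeration limited to k <= 9")
    eta = compute_eta(C)
    best = np.inf
    for m in range(2, k + 1):
        for subset in itertools.combinations(range(k), m):
            first, rest = subset[0], subset[1:]
            for order_rest in itertools.permutations(rest):
                order = (first,) + order_rest
                tour = sum(C[order[i], order[(i + 1) % m]] for i in range(m))
                best = min(best, (tour + (k - m) * eta) / k)
    return eta < best


def _standardize(coords: np.ndarray) -> np.ndarray:
    sd = coords.std(axis=0, ddof=0)
    sd[sd < 1e-12] = 1.0
    return (coords - coords.mean(axis=0)) / sd


def run(
    data: PointSet | DistanceMatrix | np.ndarray,
    config: Config | None = None,
) -> ClusteringResult:
    """Run the full clustering loop from n singletons to the identity.

    Parameters
    ----------
    data
        A :class:`PointSet` (or raw n x p array, treated as flat Euclidean
        points), or a precomputed :class:`DistanceMatrix`.  With a distance
        matrix, ``cluster_distance_mode`` must be a linkage mode; if the
        config still carries the point-input default ``centroid``, the run
        falls back to ``average`` linkage.
    config
        Run settings; defaults to :class:`Config()`.

    Returns
    -------
    ClusteringResult
        1-based labels in input row order, the full iteration trace, and a
        ``converged`` flag (False only if ``max_iterations`` cut the loop
        short of the identity permutation).
    """
    config = config or Config()
    points: PointSet | None = None
    ids: tuple[str, ...] | None = None

    if isinstance(data, DistanceMatrix):
        if config.cluster_distance_mode == "centroid":
            config = replace(config, cluster_distance_mode="average")
        D: DistanceMatrix | None = data
        n = data.n
    else:
        points = data if isinstance(data, PointSet) else PointSet(coords=np.asarray(data, dtype=float))
        if config.standardize:
            if points.geometry == "unit_sphere":
                raise ValueError("standardization is not meaningful for unit-sphere data")
            points = PointSet(coords=_standardize(points.coords), geometry=points.geometry, ids=points.ids)
        ids = points.ids
        n = points.n
        # the point distance matrix is needed for linkage modes and the
        # cluster-utility penalty; centroid/eta runs can skip it
        needs_D = config.cluster_distance_mode != "centroid" or config.penalty_mode == "cluster_utility"
        D = pairwise_distances(points, config.metric) if needs_D else None

    state = init_state(n, points, config)
    trace: list[IterationRecord] = []
    converged = True
    iteration = 0
    while state.k >= 2:
        if config.max_iterations and iteration >= config.max_iterations:
            converged = False
            break
        iteration += 1
        state, record = iterate_once(state, D, points, config, iteration=iteration)
        trace.append(record)
        if is_identity(record.permutation):
            break
    labels = np.empty(n, dtype=int)
    for label, S in enumerate(state.members, start=1):
        labels[list(S)] = label
    return ClusteringResult(
        labels=labels,
        members=state.members,
        trace=tuple(trace),
        settings=config,
        converged=converged,
        ids=ids,
    )
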