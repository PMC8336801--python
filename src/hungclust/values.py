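"""Cluster valuation and cohesion diagnostics.

Two competing ways to score a cluster S of points:

* the k-means value ``v(S) = sum_{i in S} d(c, x_i)`` — distances from the
  cluster representative c to each member; and
* the tour value ``u(S)`` — the length of the shortest closed walk visiting
  every member exactly once (the minimum over single-cycle permutations of
  sum_i d(x_i, x_sigma(i))).

The tour value is sensitive to how condensed a cluster is in a way the
centroid value is not: collapsing the four vertices of a unit square onto
two opposite corners leaves v(S) at 2*sqrt(2) but drops u(S) from 4 to
2*sqrt(2).  For |S| = 2 both values equal the distance between the two
points (the transposition's doubled edge is counted once).

Cohesion measures quantify the "binding force" between points relative to
the whole point set Omega, and between current cluster centroids; the
average self-cohesion of the centroids recovers the merge penalty eta used
by the clustering loop:  eta = sum_j gamma(c_j, c_j) / (2(k-1)).
"""

from __future__ import annotations

from itertools import permutations
from typing import Sequence

import numpy as np

from .geometry import DistanceMatrix, PointSet, representative, metric_distance

#: exact dynamic programming is used up to this cluster size
TOUR_EXACT_LIMIT = 12


def _as_array(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    return D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)


def _held_karp_cycle(d: np.ndarray) -> float:
    # bitmask DP over subsets containing point 0; O(2^m m^2)
    m = d.shape[0]
    nsub = 1 << (m - 1)  # subsets of {1..m-1}
    dp = np.full((nsub, m - 1), np.inf)
    for j in range(m - 1):
        dp[1 << j, j] = d[0, j + 1]
    for mask in range(1, nsub):
        row = dp[mask]
        active = np.flatnonzero(np.isfinite(row))
        for j in active:
            nxt = np.flatnonzero(~((mask >> np.arange(m - 1)) & 1))
            if nxt.size == 0:
                continue
            cand = row[j] + d[j + 1, nxt + 1]
            tgt = mask | (1 << nxt)
            better = cand < dp[tgt, nxt]
            dp[tgt[better], nxt[better]] = cand[better]
    full = nsub - 1
    return float(np.min(dp[full] + d[1:, 0]))


def _tour_heuristic(d: np.ndarray, rng: np.random.Generator | None = None) -> float:
    # nearest-neighbour construction + 2-opt improvement
    m = d.shape[0]
    tour = [0]
    unvisited = set(range(1, m))
    while unvisited:
        last = tour[-1]
        nxt = min(unvisited, key=lambda j: (d[last, j], j))
        tour.append(nxt)
        unvisited.remove(nxt)
    tour = np.asarray(tour)
    improved = True
    while improved:
        improved = False
        for a in range(m - 1):
            for b in range(a + 2, m):
                if a == 0 and b == m - 1:
                    continue
                i, j = tour[a], tour[(a + 1) % m]
                k, l = tour[b], tour[(b + 1) % m]
                if d[i, k] + d[j, l] < d[i, j] + d[k, l] - 1e-12:
                    tour[a + 1:b + 1] = tour[a + 1:b + 1][::-1]
                    improved = True
    return float(d[tour, np.roll(tour, -1)].sum())


def tour_value(D: DistanceMatrix | np.ndarray, method: str = "exact") -> float:
    """Minimum single-cycle tour length over the points of ``D``.

    Parameters
    ----------
    D
        Distance matrix restricted to the cluster members (m x m).
    method
        ``"exact"`` solves the tour by Held-Karp dynamic programming and is
        available for m <= 12; ``"heuristic"`` uses nearest-neighbour
        construction with 2-opt improvement and carries no optimality
        guarantee.

    Returns
    -------
    float
        0 for a singleton; the pairwise distance for m = 2 (the undirected
        edge counted once); the exact (or heuristic) minimum closed-tour
        length for m >= 3.
    """
    d = _as_array(D)
    m = d.shape[0]
    if m == 1:
        return 0.0
    if m == 2:
        return float(d[0, 1])
    if method == "exact":
        if m > TOUR_EXACT_LIMIT:
            raise ValueError(
                f"exact tour limited to {TOUR_EXACT_LIMIT} points (got {m}); "
                "pass method='heuristic' to accept an approximate value"
            )
        return _held_karp_cycle(d)
    if method == "heuristic":
        return _tour_heuristic(d)
    raise ValueError(f"unknown method {method!r}; choose 'exact' or 'heuristic'")


def tour_value_brute(D: DistanceMatrix | np.ndarray) -> float:
    """Enumeration oracle for :func:`tour_value`: all (m-1)! single cycles."""
    d = _as_array(D)
    m = d.shape[0]
    if m == 1:
        return 0.0
    if m == 2:
        return float(d[0, 1])
    best = np.inf
    for rest in permutations(range(1, m)):
        order = (0,) + rest
        length = sum(d[order[i], order[(i + 1) % m]] for i in range(m))
        best = min(best, length)
    return float(best)


def kmeans_value(
    points: PointSet,
    members: Sequence[int],
    representative_method: str = "mean",
    metric: str = "euclidean",
) -> float:
    """Sum of distances from the cluster representative to each member."""
    idx = sorted(set(int(i) for i in members))
    c = representative(points, idx, method=representative_method, metric=metric)
    return float(sum(metric_distance(c.coords, points.coords[i], metric) for i in idx))


def partition_value(
    D: DistanceMatrix | np.ndarray,
    partition: Sequence[Sequence[int]],
    eta: float,
    method: str = "exact",
) -> float:
    """Total value of a partition: sum of per-cluster tour values.

    A singleton cluster has no tour; it contributes the penalty ``eta``
    (the price of staying alone) instead.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    d = _as_array(D)
    total = 0.0
    for S in partition:
        idx = np.asarray(sorted(set(int(i) for i in S)), dtype=int)
        if idx.size == 0:
            raise ValueError("partition contains an empty cluster")
        if idx.size == 1:
            total += eta
        else:
            total += tour_value(d[np.ix_(idx, idx)], method=method)
    return float(total)


def point_cohesion(D: DistanceMatrix | np.ndarray, x: int, y: int) -> float:
    """Binding force gamma(x, y) between two points of the full set Omega.

    gamma(x, y) = mean_z d(x, z) + mean_z d(y, z) - K/n^2 - d(x, y),
    with K the sum of all ordered pairwise distances.  Symmetric;
    gamma(x, x) >= 0 and gamma(x, x) >= gamma(x, y) for every y.
    Indices are 0-based rows of ``D``.
    """
    d = _as_array(D)
    n = d.shape[0]
    K = float(d.sum())
    return float(d[x].mean() + d[y].mean() - K / n**2 - d[x, y])


def set_cohesion(D: DistanceMatrix | np.ndarray, S: Sequence[int]) -> float:
    """Cohesion of a proper subset S: the double sum of gamma over S x S.

    Equal, by construction, to the cohesion of the complement S' — the
    reason this quantity cannot rank k > 2 candidate clusters independently.
    """
    d = _as_array(D)
    n = d.shape[0]
    idx = np.asarray(sorted(set(int(i) for i in S)), dtype=int)
    if idx.size == 0 or idx.size == n:
        raise ValueError("S must be a proper non-empty subset of the point set")
    row_means = d.mean(axis=1)
    K = float(d.sum())
    s = idx.size
    sub = d[np.ix_(idx, idx)]
    # sum_{x,y in S} gamma(x,y) expanded term by term
    return float(2 * s * row_means[idx].sum() - s * s * K / n**2 - sub.sum())


def set_cohesion_closed_form(D: DistanceMatrix | np.ndarray, S: Sequence[int]) -> float:
    """Closed form of :func:`set_cohesion` in terms of block distance sums.

    With f = |S|/n and d(A, B) the sum of d over A x B:
    gamma(S) = 2(1-f) f d(S, S') - f^2 d(S', S') - (1-f)^2 d(S, S).
    """
    d = _as_array(D)
    n = d.shape[0]
    idx = np.asarray(sorted(set(int(i) for i in S)), dtype=int)
    if idx.size == 0 or idx.size == n:
        raise ValueError("S must be a proper non-empty subset of the point set")
    comp = np.setdiff1d(np.arange(n), idx)
    f = idx.size / n
    d_s_sc = float(d[np.ix_(idx, comp)].sum())
    d_sc_sc = float(d[np.ix_(comp, comp)].sum())
    d_s_s = float(d[np.ix_(idx, idx)].sum())
    return 2 * (1 - f) * f * d_s_sc - f**2 * d_sc_sc - (1 - f) ** 2 * d_s_s


def relative_distance(C: DistanceMatrix | np.ndarray, i: int, j: int) -> float:
    """Relative distance RD(c_i || c_j): d(c_i, c_j) minus the mean distance
    from c_i to all points."""
    c = _as_array(C)
    return float(c[i, j] - c[i].mean())


def self_cohesion(C: DistanceMatrix | np.ndarray, j: int) -> float:
    """Self cohesion gamma(c_j, c_j) of centroid j among k centroids.

    gamma(c_j, c_j) = (2/k) sum_l d(c_j, c_l) - (1/k^2) sum_{l,m} d(c_l, c_m).
    Summed over j this gives (1/k) of the full double sum, so
    eta = sum_j gamma(c_j, c_j) / (2(k-1)) recovers the merge penalty.
    """
    c = _as_array(C)
    k = c.shape[0]
    if k < 2:
        raise ValueError("self cohesion requires at least two centroids")
    return float(2.0 / k * c[j].sum() - c.sum() / k**2)
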