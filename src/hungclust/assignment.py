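"""Exact linear assignment and permutation-cycle decomposition.

The clustering loop needs, at every iteration, the permutation sigma
minimizing sum_i M[i, sigma(i)] over a square cost matrix M, and the orbit
(cycle) structure of that permutation.  The solver here is a shortest
augmenting path method with dual potentials (Jonker-Volgenant), an O(k^3)
exact algorithm from the Hungarian-method family.

Permutation images are 1-based throughout, matching the usual cycle notation
(1)(5,2,3)(6,4) for permutations on {1, ..., k}.

Ties between cost-minimizing permutations are broken toward the
lexicographically smallest mapping.  The refinement that guarantees this is
combinatorial (it re-solves reduced problems with forced assignments) and is
applied for k <= LEX_REFINE_LIMIT; above that size the solver's deterministic
output is returned directly — with continuous distance data, exact ties
between distinct permutations do not occur in practice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

#: exact lexicographic tie-breaking is applied up to this matrix size
LEX_REFINE_LIMIT = 12


@dataclass(frozen=True)
class Permutation:
    """A bijection on {1, ..., k} stored as the image array (1-based)."""

    mapping: tuple[int, ...]

    def __post_init__(self) -> None:
        mapping = tuple(int(m) for m in self.mapping)
        k = len(mapping)
        if k == 0 or sorted(mapping) != list(range(1, k + 1)):
            raise ValueError(f"mapping {mapping} is not a bijection on 1..{k}")
        object.__setattr__(self, "mapping", mapping)

    @property
    def k(self) -> int:
        return len(self.mapping)

    def __call__(self, i: int) -> int:
        """Image of ``i`` (1-based)."""
        return self.mapping[i - 1]


@dataclass(frozen=True)
class CycleDecomposition:
    """Orbits of a permutation; each cycle starts at its smallest element."""

    cycles: tuple[tuple[int, ...], ...]

    @property
    def count(self) -> int:
        return len(self.cycles)

    def to_permutation(self) -> Permutation:
        """Recompose the orbits into the permutation they came from."""
        k = sum(len(c) for c in self.cycles)
        mapping = [0] * k
        for cycle in self.cycles:
            for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                mapping[a - 1] = b
        return Permutation(mapping=tuple(mapping))


def _lap_jv(cost: np.ndarray) -> np.ndarray:
    """Jonker-Volgenant shortest augmenting path; returns row -> column (0-based).

    Column index ``n`` is a virtual root from which each augmenting search
    starts.  Dual feasibility (cost[i, j] - u[i] - v[j] >= 0 on matched pairs)
    is maintained throughout, which makes every augmenting path shortest.
    """
    n = cost.shape[0]
    u = np.zeros(n)
    v = np.zeros(n + 1)
    # p[j] = row currently matched to column j (-1 = free); p[n] = search root
    p = np.full(n + 1, -1, dtype=np.intp)
    for i in range(n):
        p[n] = i
        j0 = n
        minv = np.full(n + 1, np.inf)
        way = np.full(n + 1, -1, dtype=np.intp)
        used = np.zeros(n + 1, dtype=bool)
        while True:
            used[j0] = True
            i0 = p[j0]
            free = np.flatnonzero(~used[:n])
            cur = cost[i0, free] - u[i0] - v[free]
            upd = cur < minv[free]
            if np.any(upd):
                cols = free[upd]
                minv[cols] = cur[upd]
                way[cols] = j0
            j1 = free[np.argmin(minv[free])]
            delta = minv[j1]
            used_cols = np.flatnonzero(used)
            u[p[used_cols]] += delta
            v[used_cols] -= delta
            minv[~used] -= delta
            j0 = j1
            if p[j0] == -1:
                break
        while j0 != n:  # augment along the alternating path
            j1 = way[j0]
            p[j0] = p[j1]
            j0 = j1
    row_to_col = np.empty(n, dtype=np.intp)
    row_to_col[p[:n]] = np.arange(n)
    return row_to_col


def assignment_cost(M: np.ndarray, perm: Permutation) -> float:
    """Objective sum_i M[i, sigma(i)] of a permutation on the cost matrix."""
    M = np.asarray(M, dtype=float)
    idx = np.asarray(perm.mapping, dtype=int) - 1
    return float(M[np.arange(M.shape[0]), idx].sum())


def _lex_smallest_optimal(M: np.ndarray, opt: float, tol: float) -> np.ndarray:
    """Lexicographically smallest row -> column map attaining cost ``opt``.

    Fixes sigma(1), sigma(2), ... in turn to the smallest column that still
    admits an optimal completion, each feasibility check being a LAP solve on
    the reduced matrix.
    """
    n = M.shape[0]
    chosen: list[int] = []
    cols_left = list(range(n))
    fixed_cost = 0.0
    for i in range(n):
        for j in cols_left:
            rest = [c for c in cols_left if c != j]
            sub_opt = 0.0
            if rest:
                sub = M[np.ix_(range(i + 1, n), rest)]
                sub_opt = float(sub[np.arange(n - i - 1), _lap_jv(sub)].sum())
            if fixed_cost + M[i, j] + sub_opt <= opt + tol:
                chosen.append(j)
                cols_left.remove(j)
                fixed_cost += M[i, j]
                break
        else:  # pragma: no cover - an optimal completion always exists
            raise RuntimeError("no optimal completion found; numerical tolerance too tight")
    return np.asarray(chosen, dtype=np.intp)


def solve_assignment(M: np.ndarray) -> Permutation:
    """Exactly minimize sum_i M[i, sigma(i)] over permutations sigma.

    Parameters
    ----------
    M
        Square matrix of finite real costs.

    Returns
    -------
    Permutation
        A global minimizer; for k <= 12 the lexicographically smallest
        mapping among all minimizers.
    """
    M = np.ascontiguousarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"cost matrix must be square, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError("cost matrix has non-finite entries")
    k = M.shape[0]
    if k == 1:
        return Permutation(mapping=(1,))
    row_to_col = _lap_jv(M)
    if k <= LEX_REFINE_LIMIT:
        opt = float(M[np.arange(k), row_to_col].sum())
        tol = 1e-9 * (1.0 + float(np.abs(M).max()))
        row_to_col = _lex_smallest_optimal(M, opt, tol)
    return Permutation(mapping=tuple(int(j) + 1 for j in row_to_col))


def decompose_cycles(perm: Permutation) -> CycleDecomposition:
    """Orbits of ``perm``, each started at its smallest element.

    Cycles are ordered by smallest element, so the k = 6 permutation
    1->1, 2->3, 3->5, 5->2, 4->6, 6->4 decomposes as (1)(2,3,5)(4,6).
    """
    k = perm.k
    seen = [False] * k
    cycles: list[tuple[int, ...]] = []
    for start in range(1, k + 1):
        if seen[start - 1]:
            continue
        cycle = [start]
        seen[start - 1] = True
        j = perm(start)
        while j != start:
            cycle.append(j)
            seen[j - 1] = True
            j = perm(j)
        cycles.append(tuple(cycle))
    return CycleDecomposition(cycles=tuple(cycles))


def is_identity(perm: Permutation) -> bool:
    """True iff sigma(i) = i for every i."""
    return all(perm(i) == i for i in range(1, perm.k + 1))


def brute_force_assignment(M: np.ndarray) -> tuple[Permutation, float]:
    """Exhaustive-search oracle: minimum over all k! permutations.

    Intended for validation at small k; returns the lexicographically
    smallest minimizer and its cost.
    """
    M = np.asarray(M, dtype=float)
    k = M.shape[0]
    best: tuple[int, ...] | None = None
    best_cost = np.inf
    rows = np.arange(k)
    for cols in itertools.permutations(range(k)):
        c = float(M[rows, cols].sum())
        if c < best_cost - 1e-15 * (1 + abs(c)):
            best_cost = c
            best = cols
    assert best is not None
    return Permutation(mapping=tuple(j + 1 for j in best)), best_cost
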