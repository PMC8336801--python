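"""Metrics, pairwise distances, and cluster representatives.

The clustering algorithm in :mod:`hungclust.core` only ever talks to the data
through this layer: a :class:`PointSet` (raw coordinates, possibly living on
the unit sphere), a validated :class:`DistanceMatrix`, a per-cluster
representative (arithmetic mean, extrinsic spherical mean, or medoid), and a
linkage-style distance between member sets.  Everything is deterministic:
medoid ties break toward the lowest member index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

METRICS = ("euclidean", "sqeuclidean", "arc_length")
REPRESENTATIVE_METHODS = ("mean", "extrinsic_sphere", "medoid")
LINKAGE_MODES = ("single", "average", "complete")

#: rows must lie this close to unit norm to count as on the sphere
UNIT_NORM_TOL = 1e-9
#: rows within this distance of unit norm are renormalized, beyond it rejected
UNIT_NORM_REPAIR_TOL = 1e-6


@dataclass(frozen=True)
class PointSet:
    """``n x p`` observations, optionally constrained to the unit sphere.

    Parameters
    ----------
    coords
        Real matrix with one observation per row.
    geometry
        ``"flat"`` for Euclidean data or ``"unit_sphere"`` for directional
        data (every row must have Euclidean norm 1; rows within 1e-6 of unit
        norm are renormalized, anything further off is rejected).
    ids
        Optional per-row labels carried through to output files.
    """

    coords: np.ndarray
    geometry: str = "flat"
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.ndim != 2 or coords.shape[0] < 1:
            raise ValueError("coords must be a non-empty n x p matrix")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        if self.geometry not in ("flat", "unit_sphere"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "unit_sphere":
            norms = np.linalg.norm(coords, axis=1)
            if np.any(np.abs(norms - 1.0) > UNIT_NORM_REPAIR_TOL):
                worst = int(np.argmax(np.abs(norms - 1.0)))
                raise ValueError(
                    f"row {worst} has norm {norms[worst]:.6g}; unit_sphere "
                    f"points must have norm 1 within {UNIT_NORM_REPAIR_TOL}"
                )
            if np.any(np.abs(norms - 1.0) > UNIT_NORM_TOL):
                coords = coords / norms[:, None]
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        if self.ids is not None:
            ids = tuple(str(i) for i in self.ids)
            if len(ids) != coords.shape[0]:
                raise ValueError("ids length must match number of rows")
            object.__setattr__(self, "ids", ids)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def p(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class DistanceMatrix:
    """Validated ``n x n`` symmetric nonnegative distance matrix.

    Symmetry is required within 1e-12 relative to the largest entry;
    the diagonal is forced to exactly zero.
    """

    values: np.ndarray
    metric_name: str = "unknown"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(values)):
            raise ValueError("distance matrix has non-finite entries")
        scale = max(1.0, float(np.max(np.abs(values), initial=0.0)))
        if np.max(np.abs(values - values.T)) > 1e-12 * scale:
            raise ValueError("distance matrix is not symmetric within 1e-12")
        values = 0.5 * (values + values.T)
        if np.any(values < -1e-12 * scale):
            raise ValueError("distance matrix has negative entries")
        values = np.maximum(values, 0.0)
        np.fill_diagonal(values, 0.0)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Centroid:
    """A cluster representative: coordinates plus the method that produced it."""

    coords: np.ndarray
    method: str

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("centroid coordinates must be finite")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)


def metric_distance(x: np.ndarray, y: np.ndarray, metric: str = "euclidean") -> float:
    """Distance between two points under the named metric.

    ``arc_length`` is the great-circle distance arccos(<x, y>) for unit
    vectors; the inner product is clamped to [-1, 1] to guard rounding.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(x - y))
    if metric == "sqeuclidean":
        return float(np.dot(x - y, x - y))
    if metric == "arc_length":
        for v, name in ((x, "x"), (y, "y")):
            if abs(np.linalg.norm(v) - 1.0) > UNIT_NORM_REPAIR_TOL:
                raise ValueError(f"arc_length requires unit vectors; {name} has "
                                 f"norm {np.linalg.norm(v):.6g}")
        return float(np.arccos(np.clip(np.dot(x, y), -1.0, 1.0)))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def pairwise_distances(points: PointSet, metric: str = "euclidean") -> DistanceMatrix:
    """Full ``n x n`` distance matrix between the rows of ``points``."""
    coords = points.coords
    if metric in ("euclidean", "sqeuclidean"):
        if coords.shape[0] == 1:
            values = np.zeros((1, 1))
        else:
            values = squareform(pdist(coords, metric=metric))
    elif metric == "arc_length":
        if points.geometry != "unit_sphere":
            norms = np.linalg.norm(coords, axis=1)
            if np.any(np.abs(norms - 1.0) > UNIT_NORM_REPAIR_TOL):
                raise ValueError("arc_length metric requires unit-sphere points")
        gram = np.clip(coords @ coords.T, -1.0, 1.0)
        values = np.arccos(gram)
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return DistanceMatrix(values=values, metric_name=metric)


def representative(
    points: PointSet,
    members: Iterable[int],
    method: str = "mean",
    metric: str = "euclidean",
) -> Centroid:
    """Representative of the cluster formed by ``members`` (0-based rows).

    ``mean`` is the coordinate-wise arithmetic mean; ``extrinsic_sphere``
    renormalizes that mean back onto the unit sphere (the extrinsic mean of
    directional statistics); ``medoid`` is the member minimizing the summed
    distance to all members, ties toward the lowest row index.
    """
    idx = np.asarray(sorted(set(int(i) for i in members)), dtype=int)
    if idx.size == 0:
        raise ValueError("member set is empty")
    sub = points.coords[idx]
    if method == "mean":
        return Centroid(coords=sub.mean(axis=0), method=method)
    if method == "extrinsic_sphere":
        m = sub.mean(axis=0)
        norm = np.linalg.norm(m)
        if norm < 1e-12:
            raise ValueError("extrinsic mean undefined: mean vector is "
                             "numerically zero (antipodal members)")
        return Centroid(coords=m / norm, method=method)
    if method == "medoid":
        sums = np.array([
            sum(metric_distance(sub[a], sub[b], metric) for b in range(idx.size))
            for a in range(idx.size)
        ])
        # argmin returns the first minimum -> lowest member index wins ties
        return Centroid(coords=sub[int(np.argmin(sums))], method=method)
    raise ValueError(
        f"unknown representative method {method!r}; choose from {REPRESENTATIVE_METHODS}"
    )


def cluster_distance(
    D: DistanceMatrix | np.ndarray,
    A: Sequence[int],
    B: Sequence[int],
    mode: str = "average",
) -> float:
    """Linkage distance between disjoint member sets ``A`` and ``B``.

    ``single`` = minimum, ``complete`` = maximum, ``average`` = mean of all
    |A| x |B| cross distances.
    """
    values = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    a = np.asarray(sorted(set(int(i) for i in A)), dtype=int)
    b = np.asarray(sorted(set(int(i) for i in B)), dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("cluster sets must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("cluster sets must be disjoint")
    cross = values[np.ix_(a, b)]
    if mode == "single":
        return float(cross.min())
    if mode == "complete":
        return float(cross.max())
    if mode == "average":
        return float(cross.mean())
    raise ValueError(f"unknown linkage mode {mode!r}; choose from {LINKAGE_MODES}")
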