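"""Synthetic data generators for the two study designs.

Planar design: Gaussian blobs around five fixed centres in the plane,

    C1 = (0, 0), C2 = (1, 3), C3 = (3, 3), C4 = (3, 1), C5 = (0, 1.5),

either split evenly (90 points each, noise sd 0.3) or with deliberately
unbalanced sizes 180/80/110/60/20 at a chosen per-coordinate noise
variance.  The closest pair of centres (C1, C5) is 1.5 apart, so at sd 0.3
the groups are visibly separated but not trivially so.

Spherical design: two groups of unit vectors (sizes 50 and 40) obtained by
projecting Gaussian perturbations of two mean directions back onto the
sphere — projected-normal directional data.  The default mean directions
are 90 degrees apart with perturbation sd 0.2, giving two clearly distinct
caps.

Every generator is driven by a single integer seed; replicate experiments
spawn independent child streams from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Config, run
from .geometry import PointSet

#: the five planar blob centres used throughout
DEFAULT_CENTERS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (1.0, 3.0),
    (3.0, 3.0),
    (3.0, 1.0),
    (0.0, 1.5),
)

#: equal allocation of 450 points over the five centres
EQUAL_SIZES: tuple[int, ...] = (90, 90, 90, 90, 90)

#: the unbalanced allocation used in the noise-sweep experiment
BIASED_SIZES: tuple[int, ...] = (180, 80, 110, 60, 20)

#: default mean directions of the spherical design, 90 degrees apart
DEFAULT_SPHERE_MEANS: tuple[tuple[float, float, float], ...] = (
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
)

DEFAULT_SPHERE_SIZES: tuple[int, ...] = (50, 40)


@dataclass(frozen=True)
class BlobSpec:
    """Gaussian blobs: one isotropic normal per centre.

    ``sd`` is the per-coordinate noise standard deviation (0.3 in the
    even-split design).
    """

    centers: tuple[tuple[float, ...], ...] = DEFAULT_CENTERS
    sizes: tuple[int, ...] = EQUAL_SIZES
    sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.sizes):
            raise ValueError("need one size per centre")
        if any(s < 1 for s in self.sizes):
            raise ValueError("sizes must be positive")
        if not self.sd > 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class SphereSpec:
    """Projected-normal groups on the unit sphere.

    Points are mean_direction + N(0, sd^2 I), renormalized to unit length;
    draws landing numerically at the origin are resampled.
    """

    mean_directions: tuple[tuple[float, ...], ...] = DEFAULT_SPHERE_MEANS
    sizes: tuple[int, ...] = DEFAULT_SPHERE_SIZES
    sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mean_directions) != len(self.sizes):
            raise ValueError("need one size per mean direction")
        if any(s < 1 for s in self.sizes):
            raise ValueError("sizes must be positive")
        if sum(self.sizes) < 2:
            raise ValueError("need at least two points in total")
        if not self.sd > 0:
            raise ValueError("sd must be positive")
        for m in self.mean_directions:
            if abs(np.linalg.norm(m) - 1.0) > 1e-9:
                raise ValueError(f"mean direction {m} is not unit length")


def gen_blobs(spec: BlobSpec) -> tuple[PointSet, np.ndarray]:
    """Draw the planar blob design.

    Returns the points (in centre order: all of group 1, then group 2, ...)
    and the 1-based generating-centre labels.
    """
    rng = np.random.default_rng(spec.seed)
    chunks = []
    labels = []
    for g, (center, size) in enumerate(zip(spec.centers, spec.sizes), start=1):
        c = np.asarray(center, dtype=float)
        chunks.append(c + rng.normal(0.0, spec.sd, size=(size, c.size)))
        labels.extend([g] * size)
    return PointSet(coords=np.vstack(chunks)), np.asarray(labels, dtype=int)


def gen_sphere(spec: SphereSpec) -> tuple[PointSet, np.ndarray]:
    """Draw the projected-normal spherical design; all rows unit norm."""
    rng = np.random.default_rng(spec.seed)
    chunks = []
    labels = []
    for g, (mean, size) in enumerate(zip(spec.mean_directions, spec.sizes), start=1):
        m = np.asarray(mean, dtype=float)
        raw = m + rng.normal(0.0, spec.sd, size=(size, m.size))
        norms = np.linalg.norm(raw, axis=1)
        while np.any(norms < 1e-12):  # resample degenerate zero draws
            bad = norms < 1e-12
            raw[bad] = m + rng.normal(0.0, spec.sd, size=(int(bad.sum()), m.size))
            norms = np.linalg.norm(raw, axis=1)
        chunks.append(raw / norms[:, None])
        labels.extend([g] * size)
    return PointSet(coords=np.vstack(chunks), geometry="unit_sphere"), np.asarray(labels, dtype=int)


def table1_experiment(
    noise_variance: float,
    replicates: int = 50,
    seed: int = 0,
    config: Config | None = None,
) -> list[int]:
    """Noise-sweep experiment on the unbalanced planar design.

    For each replicate, draws clusters of sizes 180/80/110/60/20 at the five
    fixed centres with per-coordinate Gaussian *variance* ``noise_variance``
    (so sd = sqrt(variance)), runs the full clustering loop, and records the
    final number of clusters.

    Returns
    -------
    list of int
        The final cluster count of each replicate.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if not noise_variance > 0:
        raise ValueError("noise_variance must be positive")
    config = config or Config()
    sd = float(np.sqrt(noise_variance))
    children = np.random.SeedSequence(seed).spawn(replicates)
    counts: list[int] = []
    for child in children:
        rep_seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        spec = BlobSpec(sizes=BIASED_SIZES, sd=sd, seed=rep_seed)
        points, _ = gen_blobs(spec)
        counts.append(run(points, config).k)
    return counts


def modal_count(counts: list[int]) -> int:
    """Most frequent value; ties toward the smaller count."""
    vals, freq = np.unique(np.asarray(counts), return_counts=True)
    return int(vals[np.argmax(freq)])
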