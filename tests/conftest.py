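import numpy as np
import pytest

from hungclust.geometry import PointSet


@pytest.fixture
def unit_square() -> PointSet:
    """Four points at the corners of the unit square."""
    return PointSet(coords=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def collapsed_square() -> PointSet:
    """Two points on each of two diagonally opposite unit-square corners."""
    return PointSet(coords=np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]]))


@pytest.fixture
def two_pairs() -> PointSet:
    """Two tight vertical pairs 10 apart: (0,0),(0,1) and (10,0),(10,1)."""
    return PointSet(coords=np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
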