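import numpy as np
import pytest

from growrisk import GridSpec, PointSet, PredictorStack, Raster


@pytest.fixture
def grid5():
    """Small 5x5 grid at 90 m with top-left origin at (0, 450)."""
    return GridSpec(5, 5, 90.0, origin_x=0.0)


@pytest.fixture
def grid10():
    return GridSpec(10, 10, 90.0, origin_x=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_raster(grid5):
    """Values 0..24 row-major."""
    return Raster(grid5, np.arange(25, dtype=float).reshape(5, 5))


def make_stack(grid, **fields):
    stack = PredictorStack(grid)
    for name, values in fields.items():
        stack.add(name, Raster(grid, np.asarray(values, dtype=float)))
    return stack


def points_at_cells(grid, cells, ids=None):
    """PointSet at the centers of the given (row, col) cells."""
    rows = np.array([r for r, _ in cells])
    cols = np.array([c for _, c in cells])
    x, y = grid.cell_center(rows, cols)
    return PointSet.from_xy(x, y, ids=ids)
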