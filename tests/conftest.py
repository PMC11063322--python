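import numpy as np
import pytest

from vegtrend import GridTransform, RasterGrid, RasterStack


@pytest.fixture
def rng():
    return np.random.default_rng(20160701)


@pytest.fixture
def transform():
    return GridTransform(x0=0.0, y0=1000.0, cell_size=250.0)


@pytest.fixture
def small_grid(transform):
    vals = np.array([[0.1, 0.2], [np.nan, 0.9]])
    return RasterGrid(vals, transform)


def make_stack(values_cube, transform=None, years=None):
    """Build a stack from a (time, rows, cols) array; NaN means NoData."""
    cube = np.asarray(values_cube, dtype=float)
    if transform is None:
        transform = GridTransform(0.0, cube.shape[1] * 250.0, 250.0)
    if years is None:
        years = 2016.0 + np.arange(cube.shape[0])
    grids = [RasterGrid(layer, transform) for layer in cube]
    return RasterStack(grids, years)


@pytest.fixture
def stack_factory():
    return make_stack
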