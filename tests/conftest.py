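import numpy as np
import pytest

from paleoeval.grids import GridTransform, SuitabilityGrid


def make_grid(values, x_origin=0.0, y_origin=5.0, cell_size=1.0, mask=None):
    """Build a SuitabilityGrid from a 2-D array; NaN cells become invalid."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = ~np.isnan(values)
    transform = GridTransform(
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size=cell_size,
        nrows=values.shape[0],
        ncols=values.shape[1],
    )
    return SuitabilityGrid(
        values=np.where(mask, values, np.nan), transform=transform, mask=mask
    )


@pytest.fixture
def grid_factory():
    return make_grid


@pytest.fixture
def uniform_grid():
    """5x5 fully valid grid with row-major increasing values."""
    vals = np.linspace(0.0, 1.0, 25).reshape(5, 5)
    return make_grid(vals)


@pytest.fixture
def coastal_grid():
    """5x5 grid whose western column is invalid (a 'sea' strip)."""
    vals = np.linspace(0.0, 1.0, 25).reshape(5, 5)
    mask = np.ones((5, 5), dtype=bool)
    mask[:, 0] = False
    return make_grid(vals, mask=mask)


def random_masked_grid(rng, nrows=8, ncols=8, p_valid=0.7):
    vals = rng.random((nrows, ncols))
    mask = rng.random((nrows, ncols)) < p_valid
    if not mask.any():
        mask[nrows // 2, ncols // 2] = True
    return make_grid(vals, mask=mask)
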