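import numpy as np
import pytest

from rseikit.raster_core import BandStack, GridTransform, RasterGrid

TRANSFORM = GridTransform(500000.0, 4600000.0, 500.0)


def make_grid(values, mask=None, cell_size=500.0, origin=(500000.0, 4600000.0),
              crs="EPSG:32649"):
    """Small helper: wrap an array (any shape) into a RasterGrid."""
    t = GridTransform(origin[0], origin[1], cell_size)
    return RasterGrid(np.asarray(values, dtype=float), t, crs, mask)


def make_stack(b1, b2, b4, b6, b7, lst_dn=None, label="2001"):
    arrs = {"b1": b1, "b2": b2, "b4": b4, "b6": b6, "b7": b7}
    grids = {k: make_grid(v) for k, v in arrs.items()}
    if lst_dn is None:
        lst_dn = np.full(np.asarray(b1, dtype=float).shape, 14900.0)
    return BandStack(bands=grids, lst_dn=make_grid(lst_dn), epoch_label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_factory():
    return make_grid


@pytest.fixture
def stack_factory():
    return make_stack
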