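import numpy as np
import pytest

from centaur import BinaryMask, PhantomSpec, TemplateGrid, VolumeImage, default_grid


@pytest.fixture
def grid8() -> TemplateGrid:
    """Small centered 8x8x8 grid, 2 mm isotropic."""
    return default_grid((8, 8, 8), 2.0)


@pytest.fixture
def phantom_spec() -> PhantomSpec:
    return PhantomSpec()


def make_mask(grid: TemplateGrid, where) -> BinaryMask:
    """Mask from a boolean array or an iterable of (i, j, k) voxel indices."""
    if isinstance(where, np.ndarray) and where.dtype == bool:
        return BinaryMask(grid=grid, membership=where)
    membership = np.zeros(grid.shape, dtype=bool)
    for idx in where:
        membership[tuple(idx)] = True
    return BinaryMask(grid=grid, membership=membership)


def const_volume(grid: TemplateGrid, value: float) -> VolumeImage:
    return VolumeImage(grid=grid, values=np.full(grid.shape, float(value)))
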