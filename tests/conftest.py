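import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from radstab import ImageVolume, ROIPatch, VOIMask
from radstab.preprocessing import DiscretizedROI


def make_disc(levels_grid: np.ndarray, n_levels: int | None = None,
              spacing=(1.0, 1.0, 1.0)) -> DiscretizedROI:
    """Wrap an integer level grid (0 = outside mask) as a DiscretizedROI."""
    levels_grid = np.asarray(levels_grid)
    if levels_grid.ndim == 1:
        levels_grid = levels_grid[:, None, None]
    mask = levels_grid > 0
    ng = int(n_levels if n_levels is not None else levels_grid.max())
    return DiscretizedROI(
        levels=levels_grid.flatten(order="F")[mask.flatten(order="F")],
        n_levels=ng,
        mask_crop=mask,
        spacing=spacing,
        bin_edges=np.arange(ng + 1, dtype=float),
    )


def make_roi(values_grid: np.ndarray, mask: np.ndarray | None = None,
             spacing=(1.0, 1.0, 1.0)) -> ROIPatch:
    """Wrap a 3D intensity grid (full or masked) as an ROIPatch."""
    values_grid = np.asarray(values_grid, dtype=float)
    if mask is None:
        mask = np.ones(values_grid.shape, dtype=bool)
    return ROIPatch(
        values=values_grid.flatten(order="F")[mask.flatten(order="F")],
        mask_crop=mask,
        spacing=spacing,
        intensity_crop=values_grid,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_volume(rng):
    """A seeded 16^3 random volume at 1.5 mm isotropic spacing."""
    return ImageVolume(rng.normal(100.0, 10.0, (16, 16, 16)), (1.5, 1.5, 1.5))


@pytest.fixture
def ball_mask_volume():
    """A 25^3 unit-spacing volume with a radius-10 ball mask."""
    from radstab import make_sphere_mask

    vol = ImageVolume(np.zeros((25, 25, 25)), (1.0, 1.0, 1.0))
    mask = make_sphere_mask(vol, (12.0, 12.0, 12.0), 10.0)
    return vol, mask
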