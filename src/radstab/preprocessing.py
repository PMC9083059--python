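"""Gray-level discretization and optional intensity normalization.

Histogram and texture features operate on integer gray levels ``1..Ng``.
The default scheme is fixed bin number (FBN) over the per-ROI min-max
range, which makes discretized features invariant to any positive affine
transform of the raw intensities -- the conservative choice when the
question under study is multiplicative session-to-session gain drift.
A fixed-bin-size (FBS) dialect is provided for sensitivity experiments.

Intensity normalization defaults to ``none``: a single-scanner
longitudinal study assumes the system produces comparable images, and
normalization would mask exactly the drift being quantified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EmptyMaskError, ImageVolume, ROIPatch

__all__ = [
    "DiscretizedROI",
    "NormalizationError",
    "discretize_fbn",
    "discretize_fbs",
    "normalize_intensity",
]


class NormalizationError(ValueError):
    """Invalid normalization request (e.g. z-score of a constant volume)."""


@dataclass(frozen=True)
class DiscretizedROI:
    """ROI voxels mapped to integer gray levels 1..Ng.

    ``levels`` is ordered like :attr:`ROIPatch.values` (x-fastest scan
    order); ``level_crop`` holds the same levels placed back on the
    cropped grid with 0 outside the mask, which is what the texture
    matrix builders consume.
    """

    levels: np.ndarray
    n_levels: int
    mask_crop: np.ndarray
    spacing: tuple[float, float, float]
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=np.int64)
        if levels.size == 0:
            raise EmptyMaskError("discretized ROI is empty")
        if levels.min() < 1 or levels.max() > self.n_levels:
            raise ValueError("levels must lie in 1..Ng")
        if levels.size != int(np.asarray(self.mask_crop).sum()):
            raise ValueError("level count must match mask foreground count")
        object.__setattr__(self, "levels", levels)

    @property
    def voxel_count(self) -> int:
        return int(self.levels.size)

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing))

    @property
    def level_crop(self) -> np.ndarray:
        """Levels on the cropped grid, 0 outside the mask."""
        grid = np.zeros(self.mask_crop.shape, dtype=np.int64)
        flat = grid.flatten(order="F")
        flat[np.asarray(self.mask_crop, bool).flatten(order="F")] = self.levels
        return flat.reshape(grid.shape, order="F")

    def histogram(self) -> np.ndarray:
        """Occupancy of each level 1..Ng (sums to the voxel count)."""
        return np.bincount(self.levels, minlength=self.n_levels + 1)[1:]


def discretize_fbn(roi: ROIPatch, n_bins: int = 64) -> DiscretizedROI:
    """Fixed-bin-number discretization over the per-ROI min-max range.

    level = 1 + floor(n_bins * (v - min) / (max - min)), clamped to
    ``n_bins`` at v = max.  A constant ROI maps every voxel to level 1
    (Ng is still reported as ``n_bins``).
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    v = roi.values
    if v.size == 0:
        raise EmptyMaskError("cannot discretize an empty ROI")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        levels = np.ones(v.size, dtype=np.int64)
        edges = np.array([vmin, vmax])
    else:
        levels = 1 + np.floor(n_bins * (v - vmin) / (vmax - vmin)).astype(np.int64)
        np.clip(levels, 1, n_bins, out=levels)
        edges = np.linspace(vmin, vmax, n_bins + 1)
    return DiscretizedROI(
        levels=levels,
        n_levels=int(n_bins),
        mask_crop=roi.mask_crop,
        spacing=roi.spacing,
        bin_edges=edges,
    )


def discretize_fbs(roi: ROIPatch, bin_width: float) -> DiscretizedROI:
    """Fixed-bin-size discretization: level = 1 + floor((v - min)/w)."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    v = roi.values
    if v.size == 0:
        raise EmptyMaskError("cannot discretize an empty ROI")
    vmin = float(v.min())
    levels = 1 + np.floor((v - vmin) / bin_width).astype(np.int64)
    n_levels = int(levels.max())
    edges = vmin + bin_width * np.arange(n_levels + 1)
    return DiscretizedROI(
        levels=levels,
        n_levels=n_levels,
        mask_crop=roi.mask_crop,
        spacing=roi.spacing,
        bin_edges=edges,
    )


def normalize_intensity(volume: ImageVolume, method: str = "none") -> ImageVolume:
    """Whole-volume intensity normalization: none (default), zscore, rescale01."""
    if method == "none":
        return volume
    data = volume.data
    if method == "zscore":
        sd = float(data.std())
        if sd == 0:
            raise NormalizationError("z-score of a zero-variance volume")
        out = (data - data.mean()) / sd
    elif method == "rescale01":
        lo, hi = float(data.min()), float(data.max())
        if hi == lo:
            raise NormalizationError("rescale01 of a constant volume")
        out = (data - lo) / (hi - lo)
    else:
        raise NormalizationError(f"unknown normalization method {method!r}")
    return ImageVolume(out, volume.spacing, volume.origin)
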