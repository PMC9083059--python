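"""Laws, wavelet and LoG filter banks plus fractal features.

Filters are applied to the whole volume (not the ROI crop) so that mask
boundaries see true image context rather than crop-padding artifacts;
the original VOI mask then selects the filtered values the 22-statistic
panel is computed from.

Conventions:

* Laws -- classic unnormalized 5-tap kernels L5 = (1,4,6,4,1),
  E5 = (-1,-2,0,2,1), S5 = (-1,0,2,0,-1), applied separably (name "XYZ"
  means kernel X along the x axis, ...), mirror boundary handling.
* Wavelet -- single-level undecimated separable Haar with unit-sum low
  pass (0.5, 0.5) and zero-sum high pass (0.5, -0.5); sub-band "HLL"
  means high pass along x, low along y and z.  Outputs stay congruent
  with the input grid so the unshifted VOI mask applies directly, and
  the eight sub-bands sum exactly back to the input.
* LoG -- physical scale: sigma is given in mm and converted per axis to
  voxels through the spacing (required on anisotropic patient-like
  grids); Gaussian truncation at 4 sigma, mirror boundaries.  The
  response is the sum of per-axis second derivatives scaled by
  1/spacing^2, i.e. a Laplacian in mm^-2.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .core import ImageVolume, ROIPatch
from .registry import (
    FRACTAL_FEATURES,
    LAWS_CATEGORIES,
    LOG_SIGMAS_MM,
    WAVELET_CATEGORIES,
)

logger = logging.getLogger("radstab")

__all__ = [
    "FilterSizeError",
    "LAWS_KERNELS",
    "laws_bank",
    "wavelet_bank",
    "log_filter",
    "fractal_features",
]


class FilterSizeError(ValueError):
    """Volume too small for the requested kernel."""


LAWS_KERNELS: dict[str, np.ndarray] = {
    "L": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
}


def laws_bank(volume: ImageVolume) -> dict[str, np.ndarray]:
    """All 27 Laws responses, keyed by category name ('Laws EEE', ...)."""
    data = volume.data.astype(float)
    if min(data.shape) < 5:
        raise FilterSizeError("Laws kernels need at least 5 voxels per axis")
    out: dict[str, np.ndarray] = {}
    cache: dict[str, np.ndarray] = {"": data}

    def convolved(prefix: str) -> np.ndarray:
        # prefix = kernels applied so far, one per leading axis
        if prefix not in cache:
            parent = convolved(prefix[:-1])
            k = LAWS_KERNELS[prefix[-1]]
            cache[prefix] = ndimage.correlate1d(
                parent, k, axis=len(prefix) - 1, mode="mirror"
            )
        return cache[prefix]

    for cat in LAWS_CATEGORIES:
        name = cat.split()[1]  # e.g. "EEL"
        out[cat] = convolved(name)
    return out


def _haar_pair(data: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Undecimated Haar low/high pass along one axis, mirror boundary."""
    last = [slice(None)] * data.ndim
    last[axis] = slice(-1, None)
    padded = np.concatenate([data, data[tuple(last)]], axis=axis)
    a = [slice(None)] * data.ndim
    b = [slice(None)] * data.ndim
    a[axis] = slice(0, data.shape[axis])
    b[axis] = slice(1, data.shape[axis] + 1)
    x0, x1 = padded[tuple(a)], padded[tuple(b)]
    return 0.5 * (x0 + x1), 0.5 * (x0 - x1)


def wavelet_bank(volume: ImageVolume) -> dict[str, np.ndarray]:
    """The 8 undecimated Haar sub-bands ('Wavelet LLL' ... 'Wavelet HHH')."""
    data = volume.data.astype(float)
    if min(data.shape) < 2:
        raise FilterSizeError("wavelet transform needs at least 2 voxels per axis")
    bands = {"": data}
    for axis in range(3):
        new: dict[str, np.ndarray] = {}
        for name, arr in bands.items():
            lo, hi = _haar_pair(arr, axis)
            new[name + "L"] = lo
            new[name + "H"] = hi
        bands = new
    return {f"Wavelet {name}": bands[name] for name in
            (cat.split()[1] for cat in WAVELET_CATEGORIES)}


def log_filter(volume: ImageVolume, sigma_mm: float) -> np.ndarray:
    """Laplacian-of-Gaussian response at physical scale ``sigma_mm``."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    if sigma_mm < 0.1 * min(volume.spacing):
        logger.warning(
            "LoG sigma %.3g mm is below a tenth of the smallest spacing "
            "%.3g mm; response is noise-dominated",
            sigma_mm,
            min(volume.spacing),
        )
    data = volume.data.astype(float)
    sigma_vox = [sigma_mm / s for s in volume.spacing]

    def kernels(sv: float) -> tuple[np.ndarray, np.ndarray]:
        r = max(int(np.ceil(4.0 * sv)), 1)
        t = np.arange(-r, r + 1, dtype=float)
        g = np.exp(-(t**2) / (2.0 * sv**2))
        g /= g.sum()
        g2 = g * (t**2 - sv**2) / sv**4
        # Truncation leaves a tiny nonzero sum; remove it so the Laplacian
        # of a constant volume is exactly zero.
        g2 -= g2.sum() / g2.size
        return g, g2

    smooth = [kernels(sv) for sv in sigma_vox]
    out = np.zeros_like(data)
    for axis in range(3):
        term = data
        for ax2 in range(3):
            k = smooth[ax2][1] if ax2 == axis else smooth[ax2][0]
            term = ndimage.correlate1d(term, k, axis=ax2, mode="mirror")
        out += term / volume.spacing[axis] ** 2
    return out


def log_bank(volume: ImageVolume, sigmas_mm=LOG_SIGMAS_MM) -> dict[str, np.ndarray]:
    """The canonical LoG sweep (0.5 mm .. 3.0 mm in 0.5 mm steps)."""
    return {
        f"LoG sigma = {s:.1f} mm": log_filter(volume, s) for s in sigmas_mm
    }


# ---------------------------------------------------------------------------
# Fractal features
# ---------------------------------------------------------------------------

def _box_sizes(shape) -> list[int]:
    sizes = []
    s = 1
    while s <= min(shape):
        sizes.append(s)
        s *= 2
    return sizes


def _integral(arr: np.ndarray) -> np.ndarray:
    out = np.zeros(tuple(n + 1 for n in arr.shape))
    out[1:, 1:, 1:] = arr.cumsum(0).cumsum(1).cumsum(2)
    return out


def _box_sums(integral: np.ndarray, b: int) -> np.ndarray:
    """Sums of all b^3 gliding boxes fully inside the array (stride 1)."""
    s = integral
    n0, n1, n2 = (n - 1 - b + 1 for n in s.shape)
    if min(n0, n1, n2) < 1:
        return np.empty((0,))
    i = np.arange(n0)[:, None, None]
    j = np.arange(n1)[None, :, None]
    k = np.arange(n2)[None, None, :]
    return (
        s[i + b, j + b, k + b]
        - s[i, j + b, k + b]
        - s[i + b, j, k + b]
        - s[i + b, j + b, k]
        + s[i, j, k + b]
        + s[i, j + b, k]
        + s[i + b, j, k]
        - s[i, j, k]
    ).ravel()


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return float("nan")
    return float(np.polyfit(x, y, 1)[0])


def _fd_boxcount(mask: np.ndarray) -> float:
    """Box-counting dimension of the binary mask (dyadic partition boxes)."""
    sizes = _box_sizes(mask.shape)
    if len(sizes) < 2:
        return float("nan")
    counts = []
    for s in sizes:
        view = mask[
            : mask.shape[0] // s * s, : mask.shape[1] // s * s, : mask.shape[2] // s * s
        ]
        blocks = view.reshape(
            view.shape[0] // s, s, view.shape[1] // s, s, view.shape[2] // s, s
        )
        occupied = blocks.any(axis=(1, 3, 5))
        # Edge remainders: any foreground voxel outside the trimmed view
        # falls into additional partial boxes.
        n = int(occupied.sum())
        n += _partial_boxes(mask, view.shape, s)
        counts.append(max(n, 1))
    return _slope(np.log(1.0 / np.asarray(sizes, float)), np.log(counts))


def _partial_boxes(mask: np.ndarray, trimmed_shape, s: int) -> int:
    """Occupied partition boxes that straddle the trimmed edges."""
    if mask.shape == tuple(trimmed_shape):
        return 0
    grid = tuple(int(np.ceil(n / s)) for n in mask.shape)
    occ = np.zeros(grid, dtype=bool)
    pos = np.argwhere(mask)
    if pos.size:
        occ[tuple((pos // s).T)] = True
    full = np.zeros(grid, dtype=bool)
    full[: trimmed_shape[0] // s, : trimmed_shape[1] // s, : trimmed_shape[2] // s] = True
    return int((occ & ~full).sum())


def _fd_differential(intensity: np.ndarray, mask: np.ndarray) -> float:
    """Differential box counting generalized to 3D masked intensity grids."""
    sizes = _box_sizes(mask.shape)
    if len(sizes) < 2:
        return float("nan")
    vals = intensity[mask]
    vrange = float(vals.max() - vals.min())
    lmax = max(mask.shape)
    counts = []
    for s in sizes:
        if s == 1:
            # Single-voxel cells have zero internal range: one count each.
            counts.append(max(int(mask.sum()), 1))
            continue
        grid = tuple(int(np.ceil(n / s)) for n in mask.shape)
        total = 0
        h = vrange * s / lmax
        for bi in range(grid[0]):
            for bj in range(grid[1]):
                for bk in range(grid[2]):
                    sl = (
                        slice(bi * s, (bi + 1) * s),
                        slice(bj * s, (bj + 1) * s),
                        slice(bk * s, (bk + 1) * s),
                    )
                    msub = mask[sl]
                    if not msub.any():
                        continue
                    cell = intensity[sl][msub]
                    if h > 0:
                        total += int(np.floor((cell.max() - cell.min()) / h)) + 1
                    else:
                        total += 1
        counts.append(max(total, 1))
    return _slope(np.log(1.0 / np.asarray(sizes, float)), np.log(counts))


def _lacunarity(occupancy: np.ndarray, b: int) -> float:
    """Gliding-box lacunarity Λ = 1 + var/mean^2 of box mass at size b."""
    if min(occupancy.shape) < b:
        return float("nan")
    masses = _box_sums(_integral(occupancy.astype(float)), b)
    if masses.size == 0:
        return float("nan")
    mean = masses.mean()
    if mean == 0:
        return float("nan")
    return float(1.0 + masses.var() / mean**2)


def fractal_features(roi: ROIPatch) -> dict[str, float]:
    """The 6-entry fractal panel on one ROI.

    FD boxcount works on the binary mask; FD differential on the masked
    intensity surface; MeanLac1/2/3 are gliding-box lacunarities at box
    sizes 2, 4 and 8 voxels of the ROI binarized at its mean intensity;
    Lac slope is the log-log slope of lacunarity against box size.  ROIs
    whose bounding box is under 4 voxels on any axis yield NaN flags.
    """
    mask = roi.mask_crop
    out = {name: float("nan") for name in FRACTAL_FEATURES}
    if min(mask.shape) < 4:
        return out
    out["FD boxcount"] = _fd_boxcount(mask)
    if roi.intensity_crop is not None:
        out["FD differential"] = _fd_differential(roi.intensity_crop, mask)
    # Binarize at the ROI mean: occupied = in-mask voxel >= mean.
    thr = roi.values.mean()
    occupancy = np.zeros(mask.shape, dtype=bool)
    if roi.intensity_crop is not None:
        occupancy[mask] = roi.intensity_crop[mask] >= thr
    lac = {b: _lacunarity(occupancy, b) for b in (2, 4, 8)}
    out["MeanLac1"], out["MeanLac2"], out["MeanLac3"] = lac[2], lac[4], lac[8]
    defined = [(b, l) for b, l in lac.items() if np.isfinite(l) and l > 0]
    if len(defined) >= 2:
        bs = np.log([b for b, _ in defined])
        ls = np.log([l for _, l in defined])
        out["Lac slope"] = _slope(bs, ls)
    return {name: out[name] for name in FRACTAL_FEATURES}
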