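"""Second-order texture matrices on 26-connected 3D neighborhoods.

All four matrix families operate on a :class:`DiscretizedROI`: voxels
carry integer gray levels 1..Ng, out-of-mask voxels are ignored.

Direction conventions (recorded in output provenance):

* GLCM -- co-occurrences are accumulated over the 13 unique 3D offsets at
  Chebyshev distance 1 (each pair counted in both orders), merged into a
  single matrix, then normalized to unit mass and features computed once.
* GLRLM -- runs of equal level are found per direction; features are
  computed per direction and averaged over the 13 directions.
* GLSZM -- zones are maximal 26-connected components of one gray level.
* NGTDM -- per-voxel deviation from the mean of its in-mask 26-neighbors;
  voxels with no in-mask neighbor are excluded.

Level coordinates: features are computed over the occupied part of the
level range; ``Gnorm`` variants rescale level coordinates to [0, 1] using
the full 1..Ng range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocessing import DiscretizedROI
from .registry import (
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
)

__all__ = [
    "TextureMatrix",
    "DegenerateMatrixError",
    "DIRECTIONS_3D",
    "build_glcm",
    "glcm_features",
    "build_glrlm",
    "glrlm_features",
    "build_glszm",
    "glszm_features",
    "build_ngtdm",
    "ngtdm_features",
]

_EPS = 1e-12


class DegenerateMatrixError(ValueError):
    """ROI too small or disconnected to populate a texture matrix."""


# The 13 unique offsets of the 26-neighborhood (lexicographically positive
# half of all nonzero {-1,0,1}^3 vectors).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


@dataclass
class TextureMatrix:
    """A texture matrix plus the ROI metadata its features need.

    ``cells`` meaning depends on ``kind``: GLCM -> normalized joint
    probabilities P(i, j); GLRLM -> list of per-direction count matrices
    r(i, l); GLSZM -> counts over (level, zone size); NGTDM -> dict with
    the per-level totals ``s``, counts ``n`` and probabilities ``p``.
    """

    kind: str
    cells: object
    n_levels: int
    n_voxels: int
    roi_volume_mm3: float
    meta: dict = field(default_factory=dict)


def _pair_slices(shape, d):
    """Slices (src, dst) so that arr[src] and arr[dst] are offset by d."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step == 1:
            src.append(slice(0, n - 1))
            dst.append(slice(1, n))
        else:
            src.append(slice(1, n))
            dst.append(slice(0, n - 1))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def build_glcm(disc: DiscretizedROI, distance: int = 1) -> TextureMatrix:
    """Symmetric merged GLCM over the 13 directions at Chebyshev ``distance``."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    lev = disc.level_crop
    ng = disc.n_levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    for d in DIRECTIONS_3D:
        dd = tuple(distance * c for c in d)
        if any(abs(c) >= n for c, n in zip(dd, lev.shape)):
            continue
        src, dst = _pair_slices(lev.shape, dd)
        a, b = lev[src], lev[dst]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
        np.add.at(counts, (b[valid] - 1, a[valid] - 1), 1)
    total = counts.sum()
    if total < 2:
        raise DegenerateMatrixError("fewer than 2 in-mask neighbor pairs")
    return TextureMatrix(
        kind="GLCM",
        cells=counts / total,
        n_levels=ng,
        n_voxels=disc.voxel_count,
        roi_volume_mm3=disc.volume_mm3,
        meta={"distance": distance, "aggregation": "merged-13-directions"},
    )


def glcm_features(m: TextureMatrix) -> dict[str, float]:
    """The 40-entry GLCM panel (Haralick base + Gnorm/Vnorm/Vgnorm variants)."""
    if m.kind != "GLCM":
        raise ValueError("expected a GLCM TextureMatrix")
    p = np.asarray(m.cells, dtype=float)
    ng = m.n_levels
    levels = np.arange(1, ng + 1, dtype=float)
    i = levels[:, None]
    j = levels[None, :]
    absdiff = np.abs(i - j)
    px = p.sum(axis=1)  # == py by symmetry
    nz = p[p > 0]

    mu = float((i * p).sum())
    var = float((((i - mu) ** 2) * p).sum())
    entropy = float(-(nz * np.log2(nz)).sum())
    autocorr = float((i * j * p).sum())

    # Marginal sums p_{x+y}, p_{x-y}.
    ksum = (np.add.outer(np.arange(ng), np.arange(ng))).ravel()
    psum = np.bincount(ksum, weights=p.ravel(), minlength=2 * ng - 1)
    kdiff = np.abs(np.subtract.outer(np.arange(ng), np.arange(ng))).ravel()
    pdiff = np.bincount(kdiff, weights=p.ravel(), minlength=ng)
    sum_coords = np.arange(2, 2 * ng + 1, dtype=float)
    diff_coords = np.arange(0, ng, dtype=float)

    sum_avg = float((sum_coords * psum).sum())
    sum_var = float((((sum_coords - sum_avg) ** 2) * psum).sum())
    nzs = psum[psum > 0]
    sum_entropy = float(-(nzs * np.log2(nzs)).sum()) if nzs.size else 0.0
    diff_avg = float((diff_coords * pdiff).sum())
    diff_var = float((((diff_coords - diff_avg) ** 2) * pdiff).sum())
    nzd = pdiff[pdiff > 0]
    diff_entropy = float(-(nzd * np.log2(nzd)).sum()) if nzd.size else 0.0

    # Information measures of correlation.
    pxpy = np.outer(px, px)
    mask_joint = (p > 0) & (pxpy > 0)
    hxy = entropy
    hxy1 = float(-(p[mask_joint] * np.log2(pxpy[mask_joint])).sum())
    mask_marg = pxpy > 0
    hxy2 = float(-(pxpy[mask_marg] * np.log2(pxpy[mask_marg])).sum())
    nzx = px[px > 0]
    hx = float(-(nzx * np.log2(nzx)).sum())
    imc1 = (hxy - hxy1) / hx if hx > _EPS else float("nan")
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    correlation = (
        (autocorr - mu * mu) / var if var > _EPS else float("nan")
    )
    off_diag = absdiff > 0
    inv_var = float((p[off_diag] / (absdiff[off_diag] ** 2)).sum())

    out = {
        "Energy": float((p**2).sum()),
        "Contrast": float((((i - j) ** 2) * p).sum()),
        "Correlation": correlation,
        "Variance": var,
        "Inverse diff. moment": float((p / (1.0 + (i - j) ** 2)).sum()),
        "Sum average": sum_avg,
        "Sum variance": sum_var,
        "Sum entropy": sum_entropy,
        "Entropy": entropy,
        "Difference average": diff_avg,
        "Difference variance": diff_var,
        "Difference entropy": diff_entropy,
        "IMC1": imc1,
        "IMC2": imc2,
        "Autocorrelation": autocorr,
        "Cluster shade": float((((i + j - 2 * mu) ** 3) * p).sum()),
        "Cluster prominence": float((((i + j - 2 * mu) ** 4) * p).sum()),
        "Cluster tendency": float((((i + j - 2 * mu) ** 2) * p).sum()),
        "Maximum probability": float(p.max()),
        "Mean": mu,
        "Dissimilarity": float((absdiff * p).sum()),
        "Inverse difference": float((p / (1.0 + absdiff)).sum()),
        "Inverse difference normalized": float((p / (1.0 + absdiff / ng)).sum()),
        "Inverse diff. moment normalized": float(
            (p / (1.0 + ((i - j) / ng) ** 2)).sum()
        ),
        "Inverse variance": inv_var,
    }

    # Gnorm variants: level coordinates rescaled to [0, 1] over 1..Ng.
    g = (levels - 1.0) / (ng - 1.0) if ng > 1 else np.zeros(ng)
    gi, gj = g[:, None], g[None, :]
    g_mu = float((gi * p).sum())
    out["Gnorm entropy"] = entropy  # invariant under level relabeling
    out["Gnorm sum entropy"] = sum_entropy
    out["Gnorm mean"] = g_mu
    out["Gnorm variance"] = float((((gi - g_mu) ** 2) * p).sum())
    out["Gnorm contrast"] = float((((gi - gj) ** 2) * p).sum())
    out["Gnorm dissimilarity"] = float((np.abs(gi - gj) * p).sum())

    vol = m.roi_volume_mm3
    out["Vnorm mean"] = mu / vol
    out["Vnorm entropy"] = entropy / vol
    out["Vnorm sum entropy"] = sum_entropy / vol
    out["Vnorm energy"] = out["Energy"] / vol
    out["Vnorm variance"] = var / vol
    out["Vgnorm Mean"] = g_mu / vol
    out["Vgnorm Entropy"] = out["Gnorm entropy"] / vol
    out["Vgnorm Sum entropy"] = out["Gnorm sum entropy"] / vol
    out["Vgnorm Variance"] = out["Gnorm variance"] / vol

    ordered = {name: out[name] for name in GLCM_FEATURES}
    assert len(ordered) == 40
    return ordered


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs_along(lev: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of all runs along direction d (in-mask voxels only)."""
    shape = lev.shape
    pos = np.argwhere(lev > 0)
    if pos.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    dv = np.asarray(d)
    prev = pos - dv
    inb = np.all((prev >= 0) & (prev < shape), axis=1)
    same_as_prev = np.zeros(len(pos), dtype=bool)
    if inb.any():
        pi = prev[inb]
        same_as_prev[inb] = lev[pi[:, 0], pi[:, 1], pi[:, 2]] == lev[
            pos[inb, 0], pos[inb, 1], pos[inb, 2]
        ]
    starts = pos[~same_as_prev]
    run_levels = lev[starts[:, 0], starts[:, 1], starts[:, 2]]
    lengths = np.ones(len(starts), dtype=np.int64)
    cur = starts.copy()
    alive = np.arange(len(starts))
    while alive.size:
        nxt = cur[alive] + dv
        ok = np.all((nxt >= 0) & (nxt < shape), axis=1)
        if ok.any():
            ni = nxt[ok]
            ok2 = lev[ni[:, 0], ni[:, 1], ni[:, 2]] == run_levels[alive[ok]]
            ok[np.nonzero(ok)[0][~ok2]] = False
        cont = alive[ok]
        lengths[cont] += 1
        cur[cont] += dv
        alive = cont
    return run_levels, lengths


def build_glrlm(
    disc: DiscretizedROI, directions=None
) -> TextureMatrix:
    """Per-direction run-length count matrices r(level, length)."""
    lev = disc.level_crop
    ng = disc.n_levels
    dirs = tuple(directions) if directions is not None else DIRECTIONS_3D
    max_len = int(np.ceil(np.sqrt(sum(n**2 for n in lev.shape)))) + 1
    mats = []
    for d in dirs:
        mat = np.zeros((ng, max_len), dtype=np.int64)
        levels, lengths = _runs_along(lev, d)
        if levels.size:
            np.add.at(mat, (levels - 1, lengths - 1), 1)
        mats.append(mat)
    return TextureMatrix(
        kind="GLRLM",
        cells=mats,
        n_levels=ng,
        n_voxels=disc.voxel_count,
        roi_volume_mm3=disc.volume_mm3,
        meta={"directions": dirs, "aggregation": "feature-average-over-directions"},
    )


def _glrlm_one(mat: np.ndarray, n_vox: int) -> dict[str, float]:
    nr = mat.sum()
    if nr == 0:
        return {name: float("nan") for name in GLRLM_FEATURES}
    levels = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    lengths = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    p = mat / nr
    r_i = mat.sum(axis=1)
    r_l = mat.sum(axis=0)
    mu_i = float((levels * p).sum())
    mu_l = float((lengths * p).sum())
    nz = p[p > 0]
    return {
        "Short-run emphasis": float((mat / lengths**2).sum() / nr),
        "Long-run emphasis": float((mat * lengths**2).sum() / nr),
        "Gray-level non-uniformity": float((r_i.astype(float) ** 2).sum() / nr),
        "Gray-level non-uniformity normalized": float(
            (r_i.astype(float) ** 2).sum() / nr**2
        ),
        "Run length non-uniformity": float((r_l.astype(float) ** 2).sum() / nr),
        "Run length non-uniformity normalized": float(
            (r_l.astype(float) ** 2).sum() / nr**2
        ),
        "Run percentage": float(nr / n_vox),
        "Low gray-level run emphasis": float((mat / levels**2).sum() / nr),
        "High gray-level run emphasis": float((mat * levels**2).sum() / nr),
        "Short-run low gray-level emphasis": float(
            (mat / (levels**2 * lengths**2)).sum() / nr
        ),
        "Short-run high gray-level emphasis": float(
            (mat * levels**2 / lengths**2).sum() / nr
        ),
        "Long-run low gray-level emphasis": float(
            (mat * lengths**2 / levels**2).sum() / nr
        ),
        "Long-run high gray-level emphasis": float(
            (mat * levels**2 * lengths**2).sum() / nr
        ),
        "Gray-level variance": float((((levels - mu_i) ** 2) * p).sum()),
        "Run length variance": float((((lengths - mu_l) ** 2) * p).sum()),
        "Run entropy": float(-(nz * np.log2(nz)).sum()),
        "Number of runs": float(nr),
    }


def glrlm_features(m: TextureMatrix) -> dict[str, float]:
    """The 17-entry run-length panel, averaged over directions."""
    if m.kind != "GLRLM":
        raise ValueError("expected a GLRLM TextureMatrix")
    per_dir = [_glrlm_one(mat, m.n_voxels) for mat in m.cells]
    out = {
        name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_FEATURES
    }
    assert len(out) == 17
    return out


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def build_glszm(disc: DiscretizedROI) -> TextureMatrix:
    """Size-zone counts: zone = maximal 26-connected equal-level component."""
    lev = disc.level_crop
    ng = disc.n_levels
    max_size = disc.voxel_count
    counts = np.zeros((ng, max_size), dtype=np.int64)
    for level in np.unique(lev[lev > 0]):
        labeled, n = ndimage.label(lev == level, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        np.add.at(counts, (int(level) - 1, sizes - 1), 1)
    return TextureMatrix(
        kind="GLSZM",
        cells=counts,
        n_levels=ng,
        n_voxels=disc.voxel_count,
        roi_volume_mm3=disc.volume_mm3,
    )


def glszm_features(m: TextureMatrix) -> dict[str, float]:
    """The 12-entry size-zone panel."""
    if m.kind != "GLSZM":
        raise ValueError("expected a GLSZM TextureMatrix")
    mat = np.asarray(m.cells)
    nz_total = mat.sum()
    if nz_total == 0:
        return {name: float("nan") for name in GLSZM_FEATURES}
    levels = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    sizes = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    p = mat / nz_total
    s_i = mat.sum(axis=1).astype(float)
    s_z = mat.sum(axis=0).astype(float)
    nzp = p[p > 0]
    out = {
        "Small zone emphasis": float((mat / sizes**2).sum() / nz_total),
        "Large zone emphasis": float((mat * sizes**2).sum() / nz_total),
        "Gray-level non-uniformity": float((s_i**2).sum() / nz_total),
        "Zone size non-uniformity": float((s_z**2).sum() / nz_total),
        "Zone percentage": float(nz_total / m.n_voxels),
        "Low gray-level zone emphasis": float((mat / levels**2).sum() / nz_total),
        "High gray-level zone emphasis": float((mat * levels**2).sum() / nz_total),
        "Small zone low gray-level emphasis": float(
            (mat / (levels**2 * sizes**2)).sum() / nz_total
        ),
        "Small zone high gray-level emphasis": float(
            (mat * levels**2 / sizes**2).sum() / nz_total
        ),
        "Large zone low gray-level emphasis": float(
            (mat * sizes**2 / levels**2).sum() / nz_total
        ),
        "Large zone high gray-level emphasis": float(
            (mat * levels**2 * sizes**2).sum() / nz_total
        ),
        "Zone size entropy": float(-(nzp * np.log2(nzp)).sum()),
    }
    ordered = {name: out[name] for name in GLSZM_FEATURES}
    assert len(ordered) == 12
    return ordered


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def build_ngtdm(disc: DiscretizedROI) -> TextureMatrix:
    """Per-level accumulated deviation from the in-mask 26-neighbor mean."""
    lev = disc.level_crop
    ng = disc.n_levels
    inmask = (lev > 0).astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nsum = ndimage.correlate(lev.astype(float) * inmask, kernel, mode="constant")
    ncnt = ndimage.correlate(inmask, kernel, mode="constant")
    valid = (lev > 0) & (ncnt > 0)
    if not valid.any():
        raise DegenerateMatrixError("every ROI voxel is neighborless")
    levels_v = lev[valid]
    mean_nb = nsum[valid] / ncnt[valid]
    dev = np.abs(levels_v - mean_nb)
    s = np.zeros(ng)
    np.add.at(s, levels_v - 1, dev)
    n = np.bincount(levels_v - 1, minlength=ng).astype(float)
    p = n / n.sum()
    return TextureMatrix(
        kind="NGTDM",
        cells={"s": s, "n": n, "p": p},
        n_levels=ng,
        n_voxels=disc.voxel_count,
        roi_volume_mm3=disc.volume_mm3,
    )


def _ngtdm_panel(
    s: np.ndarray, p: np.ndarray, coords: np.ndarray, n_total: float
) -> dict[str, float]:
    occ = p > 0
    i_occ = coords[occ]
    p_occ = p[occ]
    s_occ = s[occ]
    ngp = int(occ.sum())
    denom = float((p_occ * s_occ).sum())
    coarseness = 1.0 / max(denom, _EPS)
    capped = coarseness > 1e12
    if capped:
        coarseness = 1e12
    pi = p_occ[:, None]
    pj = p_occ[None, :]
    di = i_occ[:, None] - i_occ[None, :]
    if ngp > 1:
        contrast = float(
            (pi * pj * di**2).sum() / (ngp * (ngp - 1)) * (s_occ.sum() / n_total)
        )
        busy_den = float(np.abs(i_occ[:, None] * pi - i_occ[None, :] * pj).sum())
        busyness = denom / busy_den if busy_den > _EPS else 0.0
        complexity = float(
            (
                np.abs(di)
                * (pi * s_occ[:, None] + pj * s_occ[None, :])
                / (pi + pj)
            ).sum()
            / n_total
        )
        s_sum = float(s_occ.sum())
        strength = (
            float(((pi + pj) * di**2).sum()) / s_sum if s_sum > _EPS else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def ngtdm_features(m: TextureMatrix) -> dict[str, float]:
    """The 11-entry NGTDM panel (base + Gnorm variants + Vnorm coarseness)."""
    if m.kind != "NGTDM":
        raise ValueError("expected a NGTDM TextureMatrix")
    s = np.asarray(m.cells["s"], float)
    p = np.asarray(m.cells["p"], float)
    n_total = float(np.asarray(m.cells["n"]).sum())
    ng = m.n_levels
    coords = np.arange(1, ng + 1, dtype=float)
    base = _ngtdm_panel(s, p, coords, n_total)
    # Gnorm: level axis rescaled to [0, 1]; deviations scale by 1/(Ng-1).
    if ng > 1:
        gcoords = (coords - 1.0) / (ng - 1.0)
        gbase = _ngtdm_panel(s / (ng - 1.0), p, gcoords, n_total)
    else:
        gbase = base
    out = {
        "Coarseness": base["Coarseness"],
        "Contrast": base["Contrast"],
        "Busyness": base["Busyness"],
        "Complexity": base["Complexity"],
        "Strength": base["Strength"],
        "Gnorm coarseness": gbase["Coarseness"],
        "Gnorm contrast": gbase["Contrast"],
        "Gnorm busyness": gbase["Busyness"],
        "Gnorm complexity": gbase["Complexity"],
        "Gnorm strength": gbase["Strength"],
        "Vnorm coarseness": base["Coarseness"] / m.roi_volume_mm3,
    }
    ordered = {name: out[name] for name in NGTDM_FEATURES}
    assert len(ordered) == 11
    return ordered
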