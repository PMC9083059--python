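"""First-order (intensity histogram) feature panels.

All features are computed from the ordered ROI intensity vector and its
FBN-discretized levels.  Features whose definition involves a vanishing
denominator (coefficient of variation of a zero-mean ROI, skewness of a
constant ROI, ...) return NaN, the package-wide flag for "undefined";
the robustness stage excludes flagged values with a logged reason and
never imputes them.
"""

from __future__ import annotations

import numpy as np

from .core import EmptyMaskError, ROIPatch
from .preprocessing import DiscretizedROI, discretize_fbn
from .registry import (
    FILTERED_PANEL,
    FIRSTORDER_FEATURES,
    VOLUME_FRACTION_THRESHOLDS,
)

__all__ = ["firstorder_features", "filtered_panel"]

_EPS = 1e-12


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _safe_div(num: float, den: float) -> float:
    return float(num / den) if abs(den) > _EPS else float("nan")


def _skewness(v: np.ndarray) -> float:
    sd = v.std()
    if sd < _EPS:
        return float("nan")
    return float(((v - v.mean()) ** 3).mean() / sd**3)


def _kurtosis_excess(v: np.ndarray) -> float:
    sd = v.std()
    if sd < _EPS:
        return float("nan")
    return float(((v - v.mean()) ** 4).mean() / sd**4 - 3.0)


def _mode_from_histogram(v: np.ndarray, n_bins: int) -> float:
    """Center of the most occupied of n_bins equal-width bins (ties -> lowest)."""
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return lo
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def _coeff_vari(v: np.ndarray) -> float:
    """Population sd / |mean|; NaN when the mean is unstably close to zero."""
    sd = float(v.std())
    mean = float(v.mean())
    if abs(mean) <= _EPS * max(sd, 1.0):
        return float("nan")
    return sd / abs(mean)


def _base_stats(v: np.ndarray, disc_bins: int) -> dict[str, float]:
    """The 26 base statistics shared by raw and gray-normalized panels."""
    n = v.size
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    mean = float(v.mean())
    robust = v[(v >= p10) & (v <= p90)]
    out = {
        "Mean": mean,
        "Median": float(np.median(v)),
        "Mode": _mode_from_histogram(v, disc_bins),
        "Minimum": float(v.min()),
        "Maximum": float(v.max()),
        "Range": float(v.max() - v.min()),
        "Variance": float(v.var()),
        "Standard deviation": float(v.std()),
        "Coeff vari": _coeff_vari(v),
        "Skewness": _skewness(v),
        "Kurtosis": _kurtosis_excess(v),
        "Energy": float((v**2).sum()),
        "RMS": float(np.sqrt((v**2).mean())),
        "MAD": float(np.abs(v - mean).mean()),
        "Robust MAD": (
            float(np.abs(robust - robust.mean()).mean()) if robust.size else float("nan")
        ),
        "Median MAD": float(np.median(np.abs(v - np.median(v)))),
        "P10": float(p10),
        "P90": float(p90),
        "IQR": float(p75 - p25),
        "Quartile dispersion": _safe_div(p75 - p25, p75 + p25),
        "Min location fraction": float(np.argmin(v)) / n,
        "Max location fraction": float(np.argmax(v)) / n,
        "Interdecile range": float(p90 - p10),
    }
    return out


def _raw_entropy_bits(v: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy of the raw-intensity histogram (fixed 256 bins)."""
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
    return _entropy_bits(counts / counts.sum())


def firstorder_features(roi: ROIPatch, disc: DiscretizedROI) -> dict[str, float]:
    """The 62-entry first-order panel.

    ``disc`` must be the discretization of ``roi`` (same ordering); the
    histogram features (Hist entropy, Uniformity, Norm entropy, Mode) are
    computed from it, everything else from the raw intensities.
    """
    v = roi.values
    if v.size == 0:
        raise EmptyMaskError("cannot compute first-order features of an empty ROI")
    if disc.voxel_count != roi.voxel_count:
        raise ValueError("discretization does not match ROI")
    n = v.size
    ng = disc.n_levels
    hist_p = disc.histogram() / n
    hist_entropy = _entropy_bits(hist_p)

    out = _base_stats(v, ng)
    out["Hist entropy"] = hist_entropy
    out["Uniformity"] = float((hist_p**2).sum())
    out["Entropy"] = _raw_entropy_bits(v)

    energy = out["Energy"]
    rng = out["Range"]
    out["NIenergy"] = energy / n
    out["Norm NIenergy"] = _safe_div(energy / n, rng**2)
    out["Norm entropy"] = hist_entropy / np.log2(ng)

    vmax = float(v.max())
    for t in VOLUME_FRACTION_THRESHOLDS:
        name = f"Volume fraction at {t:.2f} intensity"
        out[name] = float((v > t * vmax).mean()) if vmax > 0 else float("nan")

    # Gnorm: statistics of the gray levels rescaled to [0, 1].
    g = (disc.levels - 1) / (ng - 1) if ng > 1 else np.zeros(n)
    gs = _base_stats(g, ng)
    for src, dst in (
        ("Mean", "Gnorm mean"),
        ("Median", "Gnorm median"),
        ("Mode", "Gnorm mode"),
        ("Minimum", "Gnorm min"),
        ("Maximum", "Gnorm max"),
        ("Range", "Gnorm range"),
        ("Variance", "Gnorm variance"),
        ("Standard deviation", "Gnorm sd"),
        ("Energy", "Gnorm energy"),
        ("RMS", "Gnorm RMS"),
        ("MAD", "Gnorm MAD"),
        ("P10", "Gnorm P10"),
        ("P90", "Gnorm P90"),
        ("IQR", "Gnorm IQR"),
    ):
        out[dst] = gs[src]

    # Vnorm: statistic divided by the ROI volume in mm^3.
    vol = roi.volume_mm3
    for src, dst in (
        ("Mean", "Vnorm mean"),
        ("Median", "Vnorm median"),
        ("Minimum", "Vnorm min"),
        ("Maximum", "Vnorm max"),
        ("Range", "Vnorm range"),
        ("Variance", "Vnorm variance"),
        ("Standard deviation", "Vnorm sd"),
        ("Energy", "Vnorm energy"),
        ("RMS", "Vnorm RMS"),
        ("MAD", "Vnorm MAD"),
        ("P10", "Vnorm P10"),
        ("P90", "Vnorm P90"),
        ("IQR", "Vnorm IQR"),
        ("Entropy", "Vnorm entropy"),
    ):
        out[dst] = out[src] / vol

    ordered = {name: out[name] for name in FIRSTORDER_FEATURES}
    assert len(ordered) == 62
    return ordered


def filtered_panel(roi: ROIPatch, n_bins: int = 64) -> dict[str, float]:
    """The 22-statistic panel applied to (possibly signed) filtered ROIs.

    Identical names across all 41 filtered categories.  Discretization is
    FBN on the filtered values themselves (the min-shift inherent to FBN
    handles zero-sum filter outputs).  All-zero responses yield defined
    zeros for energy/entropy and NaN flags for scale-relative statistics.
    """
    v = roi.values
    if v.size == 0:
        raise EmptyMaskError("cannot compute the filtered panel of an empty ROI")
    disc = discretize_fbn(roi, n_bins=n_bins)
    hist_p = disc.histogram() / v.size
    hist_entropy = _entropy_bits(hist_p)
    base = _base_stats(v, n_bins)
    out = {
        "Mean": base["Mean"],
        "Median": base["Median"],
        "Min": base["Minimum"],
        "Max": base["Maximum"],
        "Range": base["Range"],
        "Variance": base["Variance"],
        "Standard deviation": base["Standard deviation"],
        "Coeff vari": base["Coeff vari"],
        "Skewness": base["Skewness"],
        "Kurtosis": base["Kurtosis"],
        "Energy": base["Energy"],
        "Norm energy": base["Energy"] / v.size,
        "RMS": base["RMS"],
        "MAD": base["MAD"],
        "P10": base["P10"],
        "P90": base["P90"],
        "IQR": base["IQR"],
        "Entropy": _raw_entropy_bits(v),
        "Hist entropy": hist_entropy,
        "Norm entropy": hist_entropy / np.log2(n_bins),
        "Uniformity": float((hist_p**2).sum()),
        "Mode": base["Mode"],
    }
    ordered = {name: out[name] for name in FILTERED_PANEL}
    assert len(ordered) == 22
    return ordered
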