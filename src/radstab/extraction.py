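"""Full-registry feature extraction for volumes, sessions and studies."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ImageVolume, ROIPatch, VOIMask, StudyDataset, extract_roi
from .filters import fractal_features, laws_bank, log_bank, wavelet_bank
from .firstorder import filtered_panel, firstorder_features
from .preprocessing import discretize_fbn, discretize_fbs, normalize_intensity
from .registry import enumerate_registry
from .shape import shape_features
from .texture import (
    DegenerateMatrixError,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "extract_features",
    "extract_session_features",
    "extract_study_features",
    "filtered_feature_sweep",
]

_NAN = float("nan")


def _discretize(roi: ROIPatch, config) -> "object":
    if config is not None and getattr(config, "discretization", "fbn") == "fbs":
        return discretize_fbs(roi, bin_width=getattr(config, "bin_width", 1.0))
    n_bins = getattr(config, "n_bins", 64) if config is not None else 64
    return discretize_fbn(roi, n_bins=n_bins)


def _roi_from_filtered(filtered: np.ndarray, roi: ROIPatch, slices) -> ROIPatch:
    crop = filtered[slices]
    values = crop.flatten(order="F")[roi.mask_crop.flatten(order="F")]
    return ROIPatch(
        values=values, mask_crop=roi.mask_crop, spacing=roi.spacing,
        intensity_crop=crop,
    )


def _mask_slices(mask: VOIMask):
    idx = np.nonzero(mask.mask)
    return tuple(slice(i.min(), i.max() + 1) for i in idx)


def filtered_feature_sweep(
    volume: ImageVolume,
    mask: VOIMask,
    config=None,
    filtered_volumes: dict[str, np.ndarray] | None = None,
) -> dict[tuple[str, str], float]:
    """All 908 filter-derived features for one (volume, VOI) pair.

    Each filter is applied to the whole volume; the 22-statistic panel is
    then computed on the filtered values inside the unmodified mask.  The
    fractal panel is computed once on the unfiltered ROI.  Precomputed
    ``filtered_volumes`` (from :func:`compute_filter_bank`) may be passed
    to share the filter cost across several VOIs of one session.
    """
    if filtered_volumes is None:
        filtered_volumes = compute_filter_bank(volume)
    roi = extract_roi(volume, mask)
    slices = _mask_slices(mask)
    n_bins = getattr(config, "n_bins", 64) if config is not None else 64
    out: dict[tuple[str, str], float] = {}
    for category, filt in filtered_volumes.items():
        froi = _roi_from_filtered(filt, roi, slices)
        for name, value in filtered_panel(froi, n_bins=n_bins).items():
            out[(category, name)] = value
    for name, value in fractal_features(roi).items():
        out[("Fractal dimension", name)] = value
    assert len(out) == 27 * 22 + 8 * 22 + 6 * 22 + 6
    return out


def compute_filter_bank(volume: ImageVolume) -> dict[str, np.ndarray]:
    """The 41 filtered volumes (27 Laws + 8 wavelet + 6 LoG), keyed by category."""
    out = {}
    out.update(laws_bank(volume))
    out.update(wavelet_bank(volume))
    out.update(log_bank(volume))
    return out


def extract_features(
    volume: ImageVolume,
    mask: VOIMask,
    config=None,
    filtered_volumes: dict[str, np.ndarray] | None = None,
    shape_cache: dict[int, dict[str, float]] | None = None,
) -> dict[tuple[str, str], float]:
    """The full 1085-feature panel as {(category, feature): value}.

    Texture matrices that cannot be built (degenerate ROIs) yield
    NaN-flagged panels rather than errors, so a study run never aborts on
    a pathological VOI.
    """
    if config is not None and getattr(config, "normalization", "none") != "none":
        volume = normalize_intensity(volume, config.normalization)
    out: dict[tuple[str, str], float] = {}

    if shape_cache is not None and id(mask) in shape_cache:
        shp = shape_cache[id(mask)]
    else:
        shp = shape_features(mask)
        if shape_cache is not None:
            shape_cache[id(mask)] = shp
    for name, value in shp.items():
        out[("Shape-based", name)] = value

    roi = extract_roi(volume, mask)
    disc = _discretize(roi, config)
    for name, value in firstorder_features(roi, disc).items():
        out[("First-order", name)] = value

    registry = enumerate_registry()
    texture_jobs = (
        ("Co-occurrence", build_glcm, glcm_features),
        ("Run-length", build_glrlm, glrlm_features),
        ("Gray-level size zone", build_glszm, glszm_features),
        ("Neighborhood gray tone diff.", build_ngtdm, ngtdm_features),
    )
    for category, builder, featurizer in texture_jobs:
        try:
            feats = featurizer(builder(disc))
        except DegenerateMatrixError:
            feats = {name: _NAN for name in registry.categories[category]}
        for name, value in feats.items():
            out[(category, name)] = value

    out.update(
        filtered_feature_sweep(
            volume, mask, config=config, filtered_volumes=filtered_volumes
        )
    )
    assert len(out) == registry.total
    return out


def extract_session_features(
    volume: ImageVolume,
    masks: dict[str, VOIMask],
    config=None,
    shape_cache: dict[int, dict[str, float]] | None = None,
) -> dict[str, dict[tuple[str, str], float]]:
    """Features for every VOI of one session, sharing one filter-bank pass."""
    filtered = compute_filter_bank(volume)
    return {
        voi: extract_features(
            volume, mask, config=config, filtered_volumes=filtered,
            shape_cache=shape_cache,
        )
        for voi, mask in masks.items()
    }


def extract_study_features(
    datasets: dict[str, StudyDataset], config=None
) -> pd.DataFrame:
    """Long-format feature table over a whole study.

    Columns: dataset, subject, session, voi, category, feature, value.
    """
    rows = []
    for ds_name, ds in datasets.items():
        shape_cache: dict[int, dict[str, float]] = {}
        for subject in ds.subjects:
            for session in ds.sessions:
                masks = {voi: ds.get(subject, session, voi)[1] for voi in ds.vois}
                volume = ds.get(subject, session, ds.vois[0])[0]
                per_voi = extract_session_features(
                    volume, masks, config=config, shape_cache=shape_cache
                )
                for voi, feats in per_voi.items():
                    for (category, feature), value in feats.items():
                        rows.append(
                            (ds_name, subject, session, voi, category, feature, value)
                        )
    return pd.DataFrame(
        rows,
        columns=["dataset", "subject", "session", "voi", "category", "feature", "value"],
    )
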