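"""The canonical feature registry.

The extraction engine computes a fixed panel of 1085 features per
(volume, VOI) pair, organized into categories:

* Shape-based (35) -- VOI geometry only, intensity-independent.
* First-order (62) -- intensity distribution statistics inside the VOI.
* Co-occurrence (40), Run-length (17), Gray-level size zone (12),
  Neighborhood gray tone diff. (11) -- 3D texture matrices built on
  26-connected neighborhoods of the discretized ROI.
* 27 Laws, 8 wavelet and 6 LoG filter banks, each followed by a fixed
  22-statistic panel on the filtered in-mask intensities (41 x 22 = 902).
* Fractal dimension (6) -- box counting and gliding-box lacunarity.

The name lists below ARE the contract: every feature module asserts that
it produced exactly its registry panel, and the robustness report is
keyed by (category, feature) pairs drawn from here.  Variant prefixes:
``Gnorm X`` = X computed on gray levels rescaled to [0, 1]; ``Vnorm X`` =
X divided by the ROI volume in mm^3; ``Vgnorm X`` = Gnorm X divided by
the ROI volume; ``NIenergy`` = energy / voxel count; ``Norm entropy`` =
histogram entropy / log2(Ng).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FeatureRegistry",
    "enumerate_registry",
    "SHAPE_FEATURES",
    "FIRSTORDER_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "NGTDM_FEATURES",
    "FILTERED_PANEL",
    "FRACTAL_FEATURES",
    "LAWS_CATEGORIES",
    "WAVELET_CATEGORIES",
    "LOG_CATEGORIES",
    "LOG_SIGMAS_MM",
    "FILTERED_TO_FIRSTORDER",
    "qualified_name",
]

SHAPE_FEATURES: tuple[str, ...] = (
    "V (voxels)",
    "Voxel volume (mm^3)",
    "Volume",
    "Surface area",
    "Voxel surface area",
    "Surface-to-volume ratio",
    "Compactness 1",
    "Compactness 2",
    "Sphericity",
    "Asphericity",
    "Spherical disproportion",
    "Maximum 3D diameter (mm)",
    "Major axis length (mm)",
    "Minor axis length (mm)",
    "Least axis length (mm)",
    "Elongation",
    "Flatness",
    "Long axis (mm, COM)",
    "Short axis (mm, COM)",
    "Least axis (mm, COM)",
    "Volume density (axis)",
    "Area density (axis)",
    "Volume density (AEE)",
    "Area density (AEE)",
    "Volume density (OMBB approx)",
    "Area density (OMBB approx)",
    "Volume density (convex)",
    "Area density (convex)",
    "Bounding box volume (mm^3)",
    "Convex hull volume (mm^3)",
    "Equivalent spherical diameter (mm)",
    "Equivalent spherical surface (mm^2)",
    "Axis ratio minor/major",
    "Axis ratio least/major",
    "Axis ratio least/minor",
)

_FO_BASE: tuple[str, ...] = (
    "Mean",
    "Median",
    "Mode",
    "Minimum",
    "Maximum",
    "Range",
    "Variance",
    "Standard deviation",
    "Coeff vari",
    "Skewness",
    "Kurtosis",
    "Energy",
    "RMS",
    "MAD",
    "Robust MAD",
    "Median MAD",
    "P10",
    "P90",
    "IQR",
    "Quartile dispersion",
    "Hist entropy",
    "Uniformity",
    "Entropy",
    "Min location fraction",
    "Max location fraction",
    "Interdecile range",
)

_FO_GNORM: tuple[str, ...] = (
    "Gnorm mean",
    "Gnorm median",
    "Gnorm mode",
    "Gnorm min",
    "Gnorm max",
    "Gnorm range",
    "Gnorm variance",
    "Gnorm sd",
    "Gnorm energy",
    "Gnorm RMS",
    "Gnorm MAD",
    "Gnorm P10",
    "Gnorm P90",
    "Gnorm IQR",
)

_FO_VNORM: tuple[str, ...] = (
    "Vnorm mean",
    "Vnorm median",
    "Vnorm min",
    "Vnorm max",
    "Vnorm range",
    "Vnorm variance",
    "Vnorm sd",
    "Vnorm energy",
    "Vnorm RMS",
    "Vnorm MAD",
    "Vnorm P10",
    "Vnorm P90",
    "Vnorm IQR",
    "Vnorm entropy",
)

VOLUME_FRACTION_THRESHOLDS: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75, 0.90)

FIRSTORDER_FEATURES: tuple[str, ...] = (
    _FO_BASE
    + ("NIenergy", "Norm NIenergy", "Norm entropy")
    + tuple(f"Volume fraction at {t:.2f} intensity" for t in VOLUME_FRACTION_THRESHOLDS)
    + _FO_GNORM
    + _FO_VNORM
)

GLCM_FEATURES: tuple[str, ...] = (
    "Energy",
    "Contrast",
    "Correlation",
    "Variance",
    "Inverse diff. moment",
    "Sum average",
    "Sum variance",
    "Sum entropy",
    "Entropy",
    "Difference average",
    "Difference variance",
    "Difference entropy",
    "IMC1",
    "IMC2",
    "Autocorrelation",
    "Cluster shade",
    "Cluster prominence",
    "Cluster tendency",
    "Maximum probability",
    "Mean",
    "Dissimilarity",
    "Inverse difference",
    "Inverse difference normalized",
    "Inverse diff. moment normalized",
    "Inverse variance",
    "Gnorm entropy",
    "Gnorm sum entropy",
    "Gnorm mean",
    "Gnorm variance",
    "Gnorm contrast",
    "Gnorm dissimilarity",
    "Vnorm mean",
    "Vnorm entropy",
    "Vnorm sum entropy",
    "Vnorm energy",
    "Vnorm variance",
    "Vgnorm Mean",
    "Vgnorm Entropy",
    "Vgnorm Sum entropy",
    "Vgnorm Variance",
)

GLRLM_FEATURES: tuple[str, ...] = (
    "Short-run emphasis",
    "Long-run emphasis",
    "Gray-level non-uniformity",
    "Gray-level non-uniformity normalized",
    "Run length non-uniformity",
    "Run length non-uniformity normalized",
    "Run percentage",
    "Low gray-level run emphasis",
    "High gray-level run emphasis",
    "Short-run low gray-level emphasis",
    "Short-run high gray-level emphasis",
    "Long-run low gray-level emphasis",
    "Long-run high gray-level emphasis",
    "Gray-level variance",
    "Run length variance",
    "Run entropy",
    "Number of runs",
)

GLSZM_FEATURES: tuple[str, ...] = (
    "Small zone emphasis",
    "Large zone emphasis",
    "Gray-level non-uniformity",
    "Zone size non-uniformity",
    "Zone percentage",
    "Low gray-level zone emphasis",
    "High gray-level zone emphasis",
    "Small zone low gray-level emphasis",
    "Small zone high gray-level emphasis",
    "Large zone low gray-level emphasis",
    "Large zone high gray-level emphasis",
    "Zone size entropy",
)

NGTDM_FEATURES: tuple[str, ...] = (
    "Coarseness",
    "Contrast",
    "Busyness",
    "Complexity",
    "Strength",
    "Gnorm coarseness",
    "Gnorm contrast",
    "Gnorm busyness",
    "Gnorm complexity",
    "Gnorm strength",
    "Vnorm coarseness",
)

FILTERED_PANEL: tuple[str, ...] = (
    "Mean",
    "Median",
    "Min",
    "Max",
    "Range",
    "Variance",
    "Standard deviation",
    "Coeff vari",
    "Skewness",
    "Kurtosis",
    "Energy",
    "Norm energy",
    "RMS",
    "MAD",
    "P10",
    "P90",
    "IQR",
    "Entropy",
    "Hist entropy",
    "Norm entropy",
    "Uniformity",
    "Mode",
)

# Maps each filtered-panel name to the first-order feature it must equal
# when the "filter" is the identity (consistency-by-construction check).
FILTERED_TO_FIRSTORDER: dict[str, str] = {
    "Mean": "Mean",
    "Median": "Median",
    "Min": "Minimum",
    "Max": "Maximum",
    "Range": "Range",
    "Variance": "Variance",
    "Standard deviation": "Standard deviation",
    "Coeff vari": "Coeff vari",
    "Skewness": "Skewness",
    "Kurtosis": "Kurtosis",
    "Energy": "Energy",
    "Norm energy": "NIenergy",
    "RMS": "RMS",
    "MAD": "MAD",
    "P10": "P10",
    "P90": "P90",
    "IQR": "IQR",
    "Entropy": "Entropy",
    "Hist entropy": "Hist entropy",
    "Norm entropy": "Norm entropy",
    "Uniformity": "Uniformity",
    "Mode": "Mode",
}

FRACTAL_FEATURES: tuple[str, ...] = (
    "FD boxcount",
    "FD differential",
    "MeanLac1",
    "MeanLac2",
    "MeanLac3",
    "Lac slope",
)

LAWS_KERNEL_NAMES: tuple[str, ...] = ("E", "L", "S")

LAWS_CATEGORIES: tuple[str, ...] = tuple(
    f"Laws {a}{b}{c}"
    for a in LAWS_KERNEL_NAMES
    for b in LAWS_KERNEL_NAMES
    for c in LAWS_KERNEL_NAMES
)

WAVELET_CATEGORIES: tuple[str, ...] = (
    "Wavelet HHH",
    "Wavelet HHL",
    "Wavelet HLH",
    "Wavelet HLL",
    "Wavelet LHH",
    "Wavelet LHL",
    "Wavelet LLH",
    "Wavelet LLL",
)

LOG_SIGMAS_MM: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

LOG_CATEGORIES: tuple[str, ...] = tuple(
    f"LoG sigma = {s:.1f} mm" for s in LOG_SIGMAS_MM
)


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered mapping of category name -> ordered feature-name tuple."""

    categories: dict[str, tuple[str, ...]]

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.categories.values())

    def qualified_names(self) -> list[str]:
        """All features as unique '<category>_<feature>' identifiers."""
        return [
            qualified_name(cat, feat)
            for cat, feats in self.categories.items()
            for feat in feats
        ]

    def count(self, category: str) -> int:
        return len(self.categories[category])


def qualified_name(category: str, feature: str) -> str:
    """Registry-unique feature identifier, e.g. 'Laws_EEL_Entropy'."""
    return f"{category.replace(' ', '_')}_{feature}"


def enumerate_registry() -> FeatureRegistry:
    """The full 1085-feature registry (category counts fixed by contract)."""
    categories: dict[str, tuple[str, ...]] = {
        "Shape-based": SHAPE_FEATURES,
        "First-order": FIRSTORDER_FEATURES,
        "Co-occurrence": GLCM_FEATURES,
        "Run-length": GLRLM_FEATURES,
        "Gray-level size zone": GLSZM_FEATURES,
        "Neighborhood gray tone diff.": NGTDM_FEATURES,
    }
    for cat in LAWS_CATEGORIES:
        categories[cat] = FILTERED_PANEL
    for cat in WAVELET_CATEGORIES:
        categories[cat] = FILTERED_PANEL
    for cat in LOG_CATEGORIES:
        categories[cat] = FILTERED_PANEL
    categories["Fractal dimension"] = FRACTAL_FEATURES
    return FeatureRegistry(categories=categories)
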