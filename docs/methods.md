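# Methods

This note records the models, conventions and parameter choices behind
`radstab`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, and what
the synthetic experiments do and do not establish.

## Geometry and image model

An `ImageVolume` is a 3D scalar array with voxel spacing in mm and an
origin; world position = origin + index × spacing, 0-based indices.
Direction matrices are deliberately unsupported: QA phantoms and the
synthetic study are axis-aligned, and orientation metadata in NIfTI/NRRD
headers beyond spacing is ignored with a logged warning. Masks use a
voxel-center inclusion rule — a voxel belongs to an analytic cylinder,
ball or ellipsoid iff its center lies inside — which is deterministic and
makes mask volumes converge to the analytic volume as spacing shrinks.
ROI values are listed in a fixed x-fastest scan order so ordered-value
tests are reproducible.

## Discretization

Texture and histogram features operate on integer gray levels 1..Ng.
The default is fixed bin number (FBN), Ng = 64 (config-exposed, 32/128
sensible alternatives), over the per-ROI min–max range:

    level = 1 + floor(Ng · (v − min) / (max − min)), clamped to Ng at v = max.

A constant ROI maps to level 1 everywhere. FBN is invariant under any
positive affine transform of the intensities — in particular under the
multiplicative session gain drift the study interrogates — which is the
conservative choice when the discretization dialect of a historical
in-house pipeline is unknown; results that depend on Ng are labeled with
the Ng used in the output provenance. A fixed-bin-size dialect is
available for sensitivity experiments. Intensity normalization defaults
to `none`: normalizing away session differences would mask exactly the
drift being quantified.

## The feature registry

The registry (1085 names) is the package's contract: every extraction
produces exactly these (category, feature) pairs, and each feature module
asserts its panel matches. Counts per category: 35 shape, 62 first-order,
40 GLCM, 17 GLRLM, 12 GLSZM, 11 NGTDM, 22 per filtered category
(27 Laws + 8 wavelet + 6 LoG), 6 fractal. (Parts of the literature quote
1087 for closely related taxonomies; the per-category counts above sum to
1085 and the registry follows them.)

Where a published report names only part of a panel, the remainder is a
declared reconstruction, frozen here:

- **Shape (35)**: IBSI-style morphology — voxel count, voxel and mesh
  volume, mesh and voxel-face surface area, surface-to-volume ratio,
  compactness 1/2, sphericity, asphericity, spherical disproportion,
  maximum 3D diameter, PCA axis lengths (4√λ), elongation, flatness,
  COM-aligned axis extents, volume/area densities for the axis-aligned
  bounding box, approximate enclosing ellipsoid, PCA-oriented bounding
  box and convex hull, bounding-box and hull volumes, equivalent-sphere
  diameter/surface, and three extent-based axis ratios. The
  intensity-weighted centre-of-mass shift is deliberately omitted: shape
  features here are strictly intensity-independent (permuting ROI
  intensities changes no shape value), and a COM shift would break that.
- **First-order (62)**: 26 base statistics (moments, percentiles,
  dispersion and location measures, histogram entropy/uniformity, raw
  256-bin histogram entropy), NIenergy = energy / N,
  Norm NIenergy = NIenergy / range², Norm entropy = Hist entropy / log₂ Ng,
  five "volume fraction above t × max" features (t = 0.10 … 0.90),
  14 `Gnorm` variants (statistics of gray levels rescaled to [0, 1]) and
  14 `Vnorm` variants (statistic / ROI volume in mm³).
- **Filtered panel (22)**: mean, median, min, max, range, variance, sd,
  coefficient of variation, skewness, kurtosis, energy, norm energy
  (energy/N), RMS, MAD, P10, P90, IQR, entropy, histogram entropy,
  normalized entropy, uniformity, mode — identical names across all 41
  filtered categories; on an unfiltered ROI the panel provably equals the
  matching first-order subset.
- **GLCM (40)**: the 25-feature Haralick panel plus Gnorm (6), Vnorm (5)
  and Vgnorm (4) variants. Gnorm rescales level coordinates to [0, 1]
  over the full 1..Ng range (entropy-type features are coordinate-free
  and unchanged by construction); Vnorm divides by ROI volume;
  Vgnorm = Gnorm / volume.
- **GLSZM (12)** and **GLRLM (17)**: the standard emphasis /
  non-uniformity / variance / entropy panels; the GLRLM panel adds the
  direction-averaged run count as its 17th entry.
- **NGTDM (11)**: coarseness, contrast, busyness, complexity, strength,
  their Gnorm variants, and volume-normalized coarseness.
- **Fractal (6)**: mask box-counting dimension over dyadic box sizes, a
  3D generalization of differential box counting on the masked intensity
  surface, gliding-box lacunarity Λ = 1 + var/mean² at box sizes 2/4/8 on
  the ROI binarized at its mean, and the log–log lacunarity slope.

Undefined values (vanishing denominators: CV of a zero-mean filtered ROI,
skewness of a constant ROI, correlation of a single-cell GLCM, …) are
returned as NaN flags, propagate as "excluded" in robustness tables, and
are never imputed or silently zeroed.

## Texture conventions

All four matrix families use the 26-neighborhood (13 unique directions)
in 3D, out-of-mask voxels ignored:

- **GLCM**: counts accumulated symmetrically over all 13 directions at
  Chebyshev distance 1 into a single matrix, normalized once, features
  computed once ("merge" aggregation). Distance 1 in grid steps;
  anisotropy is not distance-weighted. A per-direction averaging switch
  exists for sensitivity checks (`build_glcm`'s matrix is exposed, and
  `build_glrlm(directions=…)` shows the pattern).
- **GLRLM**: runs found per direction; the 17 features are computed per
  direction and averaged.
- **GLSZM**: zones are maximal 26-connected equal-level components
  (`scipy.ndimage.label` with a full 3×3×3 structure).
- **NGTDM**: per-voxel absolute deviation from the mean of its in-mask
  26-neighbors; neighborless voxels excluded. The coarseness denominator
  is floored at 1e−12 and the result capped at 1e12 — constant phantom
  ROIs are routine in this study and must yield a defined, stable value
  rather than an overflow.

All builders are verified against independent nested-loop brute-force
references (exact integer/probability equality) on randomized ROIs.

## Filter banks

Filters are applied to the **whole volume**, then masked — cropping
before filtering would put crop-boundary artifacts inside the VOI. A
config switch is not needed for the tested grids since masks never touch
the volume edge.

- **Laws**: classic unnormalized 5-tap kernels L5 = (1,4,6,4,1),
  E5 = (−1,−2,0,2,1), S5 = (−1,0,2,0,−1), applied separably in all 27
  orderings ("XYZ" = kernel X along x, …), mirror boundaries. Kernel
  normalization is off: the panel's scale-relative statistics
  (normalized entropies, CV) cancel the gain, and absolute-scale
  statistics are themselves informative about drift.
- **Wavelet**: single-level undecimated separable Haar with unit-sum low
  pass (0.5, 0.5) and zero-sum high pass (0.5, −0.5). This keeps every
  sub-band congruent with the input grid (so the unshifted VOI mask
  applies) and makes the eight sub-bands sum exactly back to the input —
  both properties are tested. The 2-tap transform is implemented directly
  rather than through a wavelet library whose Haar taps are 1/√2-
  normalized and whose stationary transform imposes length constraints.
- **LoG**: σ is physical (mm), converted per axis to voxel units through
  the spacing — required on the anisotropic 1.5×1.5×3.0 mm patient-like
  grids. The response is the sum of per-axis second-derivative-of-
  Gaussian filters scaled by 1/spacing² (a Laplacian in mm⁻²), truncation
  4σ, mirror boundaries. The discrete derivative kernel is zero-sum-
  corrected so a constant volume gives exactly zero. The canonical sweep
  is σ = 0.5 … 3.0 mm in 0.5 mm steps. σ below a tenth of the smallest
  spacing triggers a warning but is computed.
- **Fractal**: binarization threshold for lacunarity is the ROI mean
  (config-exposed); ROIs with a bounding box under 4 voxels on any axis
  yield flagged entries.

Mesh-based shape features use marching cubes at level 0.5 on the
zero-padded mask after a light Gaussian pre-smoothing (σ = 0.7 voxel).
Meshing the raw binary grid keeps the voxel staircase and overestimates
the area of smooth objects by ~10%, breaking the sphericity → 1 limit
for digitized balls; σ = 0.7 keeps ball sphericity above 0.98 while the
curvature shrinkage it introduces leaves the mesh volume within 10% of
the voxel-count volume for balls of radius ≥ 5 voxels (both bounds are
tested). The voxel-face surface area is retained as a named alternative
feature.

## Synthetic study and scanner model

The generator produces the study's invariant objects:

- **sphere_grid** (monthly-QA-like): a regular lattice of high-signal
  balls (radius 3 mm, pitch 10 mm, signal 100) in a low-signal
  background (10), on a 48³ grid at 1.5 mm isotropic; 4 cylindrical
  4.2 cm³ VOIs (r = 8.2 mm, h = 20 mm — the radius/height split is not
  dictated by the stated volume; these defaults hit it) placed in the
  four quadrants so each straddles balls and background.
- **uniform_cylinder** (daily-QA-like): a constant-signal water-like
  cylinder (r = 30 mm, h = 60 mm) with a central and four surrounding
  cavities; 2 cylindrical VOIs in homogeneous regions.
- **textured_organ** (kidney-/liver-like): Gaussian-smoothed seeded white
  noise (correlation length 6 mm, contrast 0.3, clipped positive) inside
  an ellipsoidal support, on a 48×48×24 grid at 1.5×1.5×3.0 mm; one
  ellipsoidal kidney-like VOI or one 14 cm³ spherical liver-like VOI per
  subject; each subject gets an independent texture realization.

Sessions follow a magnitude-MRI model: session t =
Rician(gain_t · bias_t(x) · shift_t(object), σ). Gains are drawn
uniformly in 1 ± drift; the bias field is a random polynomial (order 2)
rescaled to 1 ± amplitude, redrawn per session; shifts resample the
object trilinearly while masks stay fixed (emulating contours propagated
once by rigid registration and then held); Rician noise is the magnitude
of the signal plus two independent Gaussian channels. Everything derives
from one integer seed via spawned substreams; identical seeds give
bit-identical studies.

Default corruption magnitudes — ±2% gain drift, 2% bias amplitude,
SNR 50, no shift — are stand-ins for an unremarkable clinical scanner
(no public drift measurements exist for the systems of interest) and are
fully config-exposed. Signal physics (T1/T2, pulse sequences, k-space
artifacts, coils, deformable anatomy) is out of scope: the features
under study depend on intensity structure, not on how contrast arises.

Study layout defaults mirror a four-dataset design: 1 subject × 11
sessions × 4 VOIs (monthly phantom), 1 × 11 × 2 (daily phantom),
10 × 5 × 1 (kidney-like), 10 × 5 × 1 (liver-like). Grid extents (48³ and
48×48×24) were chosen as the package's own desk-scale default: they hold
every VOI with wide margins while a full four-dataset extraction of all
1085 features (166 ROI-sessions, 122 filter-bank passes) completes in
about 20 s on one CPU.

## Robustness workflow

CoV uses the sample (n−1) standard deviation by default
(config-switchable to population; the convention is recorded in report
metadata). A series of identical values short-circuits to CoV = 0
exactly — the float mean of n identical numbers is not exactly that
number, and the ~1e−14 residue would otherwise pollute the
corruption-free control. A series whose mean is within 1e−12·σ of zero
is flagged "unstable-mean" and excluded with a logged reason.

Aggregation: CoV per (subject, VOI) unit over sessions, then the
unweighted mean over units — each VOI separately for the phantom
datasets, each subject for the patient-like ones. A unit with fewer than
2 defined sessions is dropped with a reason; a feature is excluded from
a dataset when more than half its units are flagged; a feature missing
from any dataset is excluded from the final set ("incomplete coverage").
Kidney-like masks are one pooled VOI per subject. The robust set is the
intersection over all datasets of {aggregated CoV strictly < threshold},
threshold 5% by default; strictness at the boundary means an aggregated
CoV of exactly 5.0 is not robust.

## What the synthetic experiments show — and what they don't

With all corruptions disabled the generated object is session-invariant
by construction, so every defined feature must have CoV = 0 exactly;
this is a correctness control of the entire pipeline, not a statement
about scanners. With ±20% gain drift, FBN-discretized histogram and
texture features are exactly invariant while raw-intensity mean and
energy fail by an order of magnitude — a separation the workflow must
recover, and does. With Rician noise added (SNR 50), shape features
(computed from fixed masks) remain at CoV 0 and the intensity panels
spread out realistically.

None of this certifies feature robustness on real scanners: the
synthetic textures are stationary Gaussian fields, the bias fields are
low-order polynomials, masks carry no delineation variability, and
motion, ghosting and banding are absent. Passing tests establish that
the implementation computes what it claims and that the selection
workflow recovers known ground truth; robust-feature lists for a real
system must come from that system's own images.

## Known limitations

- No DICOM/RTSTRUCT ingestion, no oblique orientations, no registration.
- GLCM distance is fixed at 1 grid step by default; distance weighting
  and 2D per-slice variants are not implemented.
- The differential box-counting and lacunarity definitions for masked 3D
  intensity data are declared generalizations (the 2D originals do not
  transfer uniquely); they are frozen in the registry and tested against
  brute-force box sweeps.
- The 62-first-order / 22-filtered / 40-GLCM panel completions are
  reconstructions where published taxonomies name only part of the
  panel; the registry file is the authoritative contract.
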