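"""Domain types, image/mask I/O and VOI geometry.

The unit of computation throughout the package is an :class:`ImageVolume`
(a 3D scalar grid with physical voxel spacing in mm) together with a
:class:`VOIMask` delimiting one volume of interest.  Coordinates follow a
simple axis-aligned convention: 0-based voxel indices, world position =
``origin + index * spacing``.  Direction matrices are not supported; any
orientation metadata beyond spacing found in a file header is ignored with
a logged warning (synthetic and QA-phantom data are axis-aligned).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("radstab")

__all__ = [
    "ImageVolume",
    "VOIMask",
    "ROIPatch",
    "StudyDataset",
    "FormatError",
    "GeometryError",
    "CongruenceError",
    "EmptyMaskError",
    "read_volume",
    "write_volume",
    "make_cylinder_mask",
    "make_sphere_mask",
    "extract_roi",
]


class FormatError(ValueError):
    """Unreadable file or non-3D data."""


class GeometryError(ValueError):
    """Requested analytic shape does not fit the voxel grid."""


class CongruenceError(ValueError):
    """Volume and mask grids do not match."""


class EmptyMaskError(ValueError):
    """A mask with no foreground voxels was used for extraction."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities in arbitrary units.  Must be finite.
    spacing : tuple of float
        Voxel spacing ``(sx, sy, sz)`` in mm, all > 0.
    origin : tuple of float
        World position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise FormatError(f"volume must be 3D, got {data.ndim}D")
        if any(n < 1 for n in data.shape):
            raise FormatError("each axis must have at least 1 voxel")
        if not np.all(np.isfinite(data)):
            raise FormatError("volume intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise FormatError(f"spacing must be 3 positive numbers, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis (mm)."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]


@dataclass(frozen=True)
class VOIMask:
    """A binary volume of interest on an :class:`ImageVolume` grid."""

    mask: np.ndarray
    label: str = "voi"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise FormatError(f"mask must be 3D, got {mask.ndim}D")
        mask = mask.astype(bool)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class ROIPatch:
    """Masked intensities plus the bounding-box-cropped mask.

    ``values`` holds the intensities of foreground voxels in a fixed,
    deterministic scan order: x varies fastest, then y, then z (i.e. the
    Fortran-order traversal of the (nx, ny, nz) array).
    """

    values: np.ndarray
    mask_crop: np.ndarray
    spacing: tuple[float, float, float]
    intensity_crop: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask_crop = np.asarray(self.mask_crop, dtype=bool)
        if values.size != int(mask_crop.sum()):
            raise CongruenceError(
                "ROI value count must equal foreground count of cropped mask"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask_crop", mask_crop)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.values.size)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        """ROI volume from voxel counting, in mm^3."""
        return self.voxel_count * self.voxel_volume


@dataclass
class StudyDataset:
    """One dataset of a repeatability study: subjects x sessions x VOIs.

    ``get(subject, session, voi)`` must resolve to exactly one
    (ImageVolume, VOIMask) pair; here the pairs are held in a dict keyed
    by the triple.
    """

    name: str
    subjects: list[str]
    sessions: list[str]
    vois: list[str]
    items: dict[tuple[str, str, str], tuple[ImageVolume, VOIMask]] = field(
        default_factory=dict
    )

    def get(self, subject: str, session: str, voi: str) -> tuple[ImageVolume, VOIMask]:
        return self.items[(subject, session, voi)]

    def triples(self):
        for subject in self.subjects:
            for session in self.sessions:
                for voi in self.vois:
                    yield subject, session, voi


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) file as an ImageVolume.

    Spacing and origin are taken from the header; intensities are returned
    unmodified.  Oblique direction cosines are not supported: any rotation
    component in the header is dropped with a warning.
    """
    path = os.fspath(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(path)
        except Exception as exc:  # pragma: no cover - nibabel error paths
            raise FormatError(f"cannot read NIfTI file {path!r}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"expected 3D data, got {data.ndim}D in {path!r}")
        zooms = img.header.get_zooms()[:3]
        affine = img.affine
        rot = affine[:3, :3]
        if not _is_axis_aligned(rot):
            logger.warning(
                "%s: non-axis-aligned affine; orientation ignored, spacing kept", path
            )
        origin = tuple(float(v) for v in affine[:3, 3])
        return ImageVolume(np.asarray(data, dtype=np.float64), tuple(zooms), origin)
    if lower.endswith(".nrrd"):
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(path)
        except Exception as exc:
            raise FormatError(f"cannot read NRRD file {path!r}: {exc}") from exc
        if img.GetDimension() != 3:
            raise FormatError(
                f"expected 3D data, got {img.GetDimension()}D in {path!r}"
            )
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        if not _is_axis_aligned(direction):
            logger.warning(
                "%s: non-identity direction matrix ignored; spacing kept", path
            )
        # SimpleITK arrays are (z, y, x); transpose to our (x, y, z) layout.
        data = sitk.GetArrayFromImage(img).T
        return ImageVolume(
            np.asarray(data, dtype=np.float64),
            tuple(img.GetSpacing()),
            tuple(img.GetOrigin()),
        )
    raise FormatError(f"unsupported file format: {path!r} (use .nii/.nii.gz/.nrrd)")


def write_volume(volume: ImageVolume | VOIMask, path: str | os.PathLike) -> None:
    """Write a volume or mask to NIfTI or NRRD (chosen by extension).

    Masks are stored as 8-bit 0/1 volumes.
    """
    path = os.fspath(path)
    if isinstance(volume, VOIMask):
        data = volume.mask.astype(np.uint8)
        spacing, origin = volume.spacing, volume.origin
    else:
        data = np.asarray(volume.data)
        spacing, origin = volume.spacing, volume.origin
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(data, affine), path)
    elif lower.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetOrigin(tuple(float(o) for o in origin))
        sitk.WriteImage(img, path)
    else:
        raise FormatError(f"unsupported file format: {path!r}")


def _is_axis_aligned(rot: np.ndarray, tol: float = 1e-6) -> bool:
    """True if a 3x3 header matrix is diagonal up to sign (no rotation)."""
    off = rot - np.diag(np.diag(rot))
    return bool(np.all(np.abs(off) <= tol * max(1.0, np.abs(rot).max())))


# ---------------------------------------------------------------------------
# VOI geometry
# ---------------------------------------------------------------------------

def _center_grids(volume: ImageVolume):
    cx = volume.voxel_centers(0)
    cy = volume.voxel_centers(1)
    cz = volume.voxel_centers(2)
    return np.meshgrid(cx, cy, cz, indexing="ij")


def make_cylinder_mask(
    volume: ImageVolume,
    center: tuple[float, float, float],
    radius: float,
    height: float,
    axis: str = "z",
    label: str = "cylinder",
) -> VOIMask:
    """Analytic cylinder VOI: a voxel is included iff its center is inside.

    ``center`` is in world mm; ``radius``/``height`` in mm; ``axis`` the
    cylinder axis.  The voxel-count volume approximates pi r^2 h.
    """
    if radius <= 0 or height <= 0:
        raise GeometryError("cylinder radius and height must be positive")
    ax = {"x": 0, "y": 1, "z": 2}.get(axis)
    if ax is None:
        raise GeometryError(f"axis must be one of x, y, z, got {axis!r}")
    _check_inside(volume, center, radius, height, ax)
    gx, gy, gz = _center_grids(volume)
    coords = [gx - center[0], gy - center[1], gz - center[2]]
    along = coords.pop(ax)
    inside = (coords[0] ** 2 + coords[1] ** 2 <= radius**2) & (
        np.abs(along) <= height / 2.0
    )
    if not inside.any():
        raise GeometryError("cylinder contains no voxel centers (too small)")
    return VOIMask(inside, label=label, spacing=volume.spacing, origin=volume.origin)


def make_sphere_mask(
    volume: ImageVolume,
    center: tuple[float, float, float],
    radius: float,
    label: str = "sphere",
) -> VOIMask:
    """Analytic ball VOI: voxel centers within ``radius`` mm of ``center``."""
    if radius <= 0:
        raise GeometryError("sphere radius must be positive")
    _check_inside(volume, center, radius, 2 * radius, None)
    gx, gy, gz = _center_grids(volume)
    inside = (
        (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
        <= radius**2
    )
    if not inside.any():
        raise GeometryError("sphere contains no voxel centers (too small)")
    return VOIMask(inside, label=label, spacing=volume.spacing, origin=volume.origin)


def _check_inside(volume, center, radius, height, ax) -> None:
    """Require the analytic shape to lie within the volume's physical bounds."""
    for axis in range(3):
        lo = volume.origin[axis] - volume.spacing[axis] / 2.0
        hi = lo + volume.shape[axis] * volume.spacing[axis]
        extent = height / 2.0 if axis == ax else radius
        if center[axis] - extent < lo - 1e-9 or center[axis] + extent > hi + 1e-9:
            raise GeometryError(
                f"shape exceeds volume bounds on axis {axis}: "
                f"[{center[axis] - extent:.2f}, {center[axis] + extent:.2f}] mm "
                f"outside [{lo:.2f}, {hi:.2f}] mm"
            )


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi(volume: ImageVolume, mask: VOIMask) -> ROIPatch:
    """Crop to the mask bounding box and list foreground intensities.

    Values come out in x-fastest scan order (x varies fastest, then y,
    then z), fixed so ordered-value tests are reproducible.
    """
    if volume.shape != mask.shape:
        raise CongruenceError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    m = mask.mask
    if not m.any():
        raise EmptyMaskError(f"mask {mask.label!r} has no foreground voxels")
    slices = tuple(
        slice(idx.min(), idx.max() + 1) for idx in np.nonzero(m)
    )
    mask_crop = m[slices]
    intensity_crop = volume.data[slices].astype(float)
    # Fortran-order flattening makes axis 0 (x) the fastest-varying index.
    flat_mask = mask_crop.flatten(order="F")
    values = intensity_crop.flatten(order="F")[flat_mask]
    return ROIPatch(
        values=values,
        mask_crop=mask_crop,
        spacing=volume.spacing,
        intensity_crop=intensity_crop,
    )
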