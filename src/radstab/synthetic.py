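"""Synthetic phantoms, organ-like volumes, and a seeded scanner model.

The generators emulate the invariant objects of a longitudinal MRI-Linac
QA study: a sphere-grid QA phantom (a lattice of high-signal balls in a
low-signal background, Magphan-flavored), a uniform water cylinder with
ionization-chamber cavities (Daily-QA-flavored), and textured organ-like
volumes (smoothed random fields inside an ellipsoidal support, standing
in for the heterogeneity of kidney/liver tissue).

Repeat sessions are produced by a magnitude-MRI scanner model: each
session applies a multiplicative gain, a smooth polynomial bias field,
an optional rigid sub-voxel translation of the object (masks are NOT
shifted, emulating contours propagated once and held fixed), and Rician
noise.  Everything is driven by one integer seed; identical seeds give
bit-identical series.

Pulse-sequence physics (T1/T2, TRUFI signal equations) is deliberately
not modeled: the features under study depend on intensity structure,
not on how the contrast was generated, so signal levels are abstract
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import GeometryError, ImageVolume, VOIMask

__all__ = [
    "PhantomSpec",
    "ScannerParams",
    "SessionSeries",
    "ConfigError",
    "generate_phantom",
    "simulate_session_series",
    "make_ellipsoid_mask",
]


class ConfigError(ValueError):
    """Inconsistent synthetic-study configuration."""


@dataclass
class PhantomSpec:
    """Geometry and signal description of one ground-truth object.

    ``kind`` is one of ``sphere_grid``, ``uniform_cylinder`` or
    ``textured_organ``.  Lengths in mm, signals in abstract intensity
    units (>= 0).  ``texture_correlation_mm`` is the Gaussian smoothing
    scale of the organ texture; ``texture_contrast`` its relative
    standard deviation (0 gives a constant organ).
    """

    kind: str
    foreground: float = 100.0
    background: float = 0.0
    # sphere_grid
    ball_radius_mm: float = 3.0
    ball_pitch_mm: float = 10.0
    # uniform_cylinder
    cylinder_radius_mm: float = 30.0
    cylinder_height_mm: float = 60.0
    cavity_radius_mm: float = 4.0
    cavity_centers_mm: tuple = ((0.0, 0.0), (17.0, 17.0), (-17.0, 17.0),
                                (17.0, -17.0), (-17.0, -17.0))
    # textured_organ
    organ_semiaxes_mm: tuple = (30.0, 32.0, 30.0)
    texture_correlation_mm: float = 6.0
    texture_contrast: float = 0.3
    texture_seed: int = 0

    def __post_init__(self) -> None:
        if self.foreground < 0 or self.background < 0:
            raise ConfigError("signal levels must be >= 0")
        if self.kind not in ("sphere_grid", "uniform_cylinder", "textured_organ"):
            raise ConfigError(f"unknown phantom kind {self.kind!r}")


@dataclass
class ScannerParams:
    """Per-session acquisition corruptions.

    ``gain_per_session`` and ``shift_mm_per_session`` must have one entry
    per session; ``noise_sigma`` is the Rician scale in intensity units.
    """

    gain_per_session: tuple[float, ...]
    noise_sigma: float = 0.0
    bias_field_amplitude: float = 0.0
    bias_field_order: int = 2
    shift_mm_per_session: tuple[tuple[float, float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.gain_per_session = tuple(float(g) for g in self.gain_per_session)
        if any(g <= 0 for g in self.gain_per_session):
            raise ConfigError("gain factors must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise sigma must be >= 0")
        if not 0 <= self.bias_field_amplitude < 1:
            raise ConfigError("bias amplitude must be in [0, 1)")
        if self.shift_mm_per_session is not None:
            self.shift_mm_per_session = tuple(
                tuple(float(c) for c in s) for s in self.shift_mm_per_session
            )

    @classmethod
    def identity(cls, n_sessions: int) -> "ScannerParams":
        """All corruptions disabled: every session equals the object."""
        return cls(gain_per_session=(1.0,) * n_sessions)

    @classmethod
    def drifting(
        cls,
        n_sessions: int,
        gain_drift: float = 0.02,
        noise_sigma: float = 0.0,
        bias_amplitude: float = 0.0,
        bias_order: int = 2,
        shift_mm: float = 0.0,
        seed: int = 0,
    ) -> "ScannerParams":
        """Draw per-session gains uniformly in 1 +/- gain_drift (seeded)."""
        rng = np.random.default_rng(seed)
        gains = 1.0 + rng.uniform(-gain_drift, gain_drift, size=n_sessions)
        shifts = None
        if shift_mm > 0:
            shifts = tuple(
                tuple(rng.uniform(-shift_mm, shift_mm, size=3)) for _ in range(n_sessions)
            )
        return cls(
            gain_per_session=tuple(gains),
            noise_sigma=noise_sigma,
            bias_field_amplitude=bias_amplitude,
            bias_field_order=bias_order,
            shift_mm_per_session=shifts,
            seed=seed,
        )


@dataclass
class SessionSeries:
    """Ordered repeat acquisitions of one subject plus its VOI masks."""

    subject: str
    volumes: list[ImageVolume]
    masks: dict[str, VOIMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            raise ConfigError("all session volumes must share one grid")
        for mask in self.masks.values():
            if mask.shape not in shapes:
                raise ConfigError("masks must be congruent with the session grid")


def _centered_grid(shape, spacing):
    """World coordinates with the origin at the volume center."""
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    return origin, np.meshgrid(*axes, indexing="ij")


def generate_phantom(
    spec: PhantomSpec,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> ImageVolume:
    """Noiseless deterministic ground-truth object on a centered grid."""
    origin, (gx, gy, gz) = _centered_grid(shape, spacing)
    extent = [shape[a] * spacing[a] for a in range(3)]

    if spec.kind == "sphere_grid":
        r, pitch = spec.ball_radius_mm, spec.ball_pitch_mm
        data = np.full(shape, spec.background, dtype=float)
        half = [e / 2.0 for e in extent]
        n_balls = []
        for a in range(3):
            k = int(np.floor((half[a] - r) / pitch))
            n_balls.append(2 * k + 1)
        if min(n_balls) < 1:
            raise GeometryError("ball lattice does not fit the grid")
        for cx in np.arange(-(n_balls[0] // 2), n_balls[0] // 2 + 1) * pitch:
            for cy in np.arange(-(n_balls[1] // 2), n_balls[1] // 2 + 1) * pitch:
                for cz in np.arange(-(n_balls[2] // 2), n_balls[2] // 2 + 1) * pitch:
                    ball = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2 <= r**2
                    data[ball] = spec.foreground
        return ImageVolume(data, spacing, origin)

    if spec.kind == "uniform_cylinder":
        R, H = spec.cylinder_radius_mm, spec.cylinder_height_mm
        if 2 * R > min(extent[0], extent[1]) or H > extent[2]:
            raise GeometryError("cylinder does not fit the grid")
        data = np.full(shape, spec.background, dtype=float)
        body = (gx**2 + gy**2 <= R**2) & (np.abs(gz) <= H / 2.0)
        data[body] = spec.foreground
        for cx, cy in spec.cavity_centers_mm:
            cavity = ((gx - cx) ** 2 + (gy - cy) ** 2 <= spec.cavity_radius_mm**2) & (
                np.abs(gz) <= H / 2.0
            )
            data[cavity] = 0.0
        return ImageVolume(data, spacing, origin)

    # textured_organ
    a, b, c = spec.organ_semiaxes_mm
    if 2 * a > extent[0] or 2 * b > extent[1] or 2 * c > extent[2]:
        raise GeometryError("organ ellipsoid does not fit the grid")
    support = (gx / a) ** 2 + (gy / b) ** 2 + (gz / c) ** 2 <= 1.0
    data = np.full(shape, spec.background, dtype=float)
    if spec.texture_contrast > 0:
        rng = np.random.default_rng(spec.texture_seed)
        white = rng.standard_normal(shape)
        sigma_vox = [max(spec.texture_correlation_mm / s, 1e-6) for s in spacing]
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="mirror")
        sd = smooth.std()
        field_ = smooth / sd if sd > 0 else smooth
        texture = spec.foreground * np.clip(
            1.0 + spec.texture_contrast * field_, 0.0, None
        )
    else:
        texture = np.full(shape, float(spec.foreground))
    data[support] = texture[support]
    return ImageVolume(data, spacing, origin)


def make_ellipsoid_mask(
    volume: ImageVolume,
    center: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
    label: str = "organ",
) -> VOIMask:
    """Axis-aligned ellipsoid VOI (voxel-center inclusion rule)."""
    if min(semiaxes) <= 0:
        raise GeometryError("semi-axes must be positive")
    gx = volume.voxel_centers(0)[:, None, None] - center[0]
    gy = volume.voxel_centers(1)[None, :, None] - center[1]
    gz = volume.voxel_centers(2)[None, None, :] - center[2]
    inside = (gx / semiaxes[0]) ** 2 + (gy / semiaxes[1]) ** 2 + (
        gz / semiaxes[2]
    ) ** 2 <= 1.0
    if not inside.any():
        raise GeometryError("ellipsoid contains no voxel centers")
    return VOIMask(inside, label=label, spacing=volume.spacing, origin=volume.origin)


def _bias_field(shape, amplitude: float, order: int, rng) -> np.ndarray:
    """Smooth multiplicative field in [1 - a, 1 + a] from a random polynomial."""
    if amplitude == 0:
        return np.ones(shape)
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    raw = np.zeros(shape)
    for px in range(order + 1):
        for py in range(order + 1 - px):
            for pz in range(order + 1 - px - py):
                if px == py == pz == 0:
                    continue
                raw += rng.standard_normal() * gx**px * gy**py * gz**pz
    peak = np.abs(raw).max()
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * raw / peak


def simulate_session_series(
    obj: ImageVolume,
    params: ScannerParams,
    n_sessions: int,
    subject: str = "subject",
    masks: dict[str, VOIMask] | None = None,
) -> SessionSeries:
    """Repeat acquisitions: Rician(gain_t * bias_t(x) * shift_t(object), sigma).

    Noise draws and bias fields are independent across sessions but fully
    determined by ``params.seed``; masks are passed through unshifted.
    """
    if n_sessions < 2:
        raise ConfigError("a session series needs at least 2 sessions")
    if len(params.gain_per_session) != n_sessions:
        raise ConfigError(
            f"gain sequence length {len(params.gain_per_session)} != "
            f"session count {n_sessions}"
        )
    shifts = params.shift_mm_per_session
    if shifts is not None and len(shifts) != n_sessions:
        raise ConfigError("shift sequence length must equal session count")
    rng = np.random.default_rng(params.seed)
    volumes = []
    for t in range(n_sessions):
        data = obj.data
        if shifts is not None and any(abs(c) > 0 for c in shifts[t]):
            shift_vox = [shifts[t][a] / obj.spacing[a] for a in range(3)]
            data = ndimage.shift(data, shift_vox, order=1, mode="nearest")
        bias = _bias_field(
            obj.shape, params.bias_field_amplitude, params.bias_field_order, rng
        )
        signal = params.gain_per_session[t] * bias * data
        if params.noise_sigma > 0:
            n1 = rng.normal(0.0, params.noise_sigma, obj.shape)
            n2 = rng.normal(0.0, params.noise_sigma, obj.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        volumes.append(ImageVolume(signal, obj.spacing, obj.origin))
    return SessionSeries(subject=subject, volumes=volumes, masks=masks or {})
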