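"""Study configuration and the synthetic four-dataset study builder.

The default configuration mirrors the layout of a longitudinal MRI-Linac
repeatability study: a sphere-grid QA phantom imaged over 11 monthly
sessions with 4 cylindrical 4.2 cm^3 VOIs; a uniform cylinder phantom
with cavities over 11 daily sessions with 2 such VOIs; and two
patient-like datasets of 10 textured subjects x 5 sessions each, one
with a kidney-like ellipsoidal VOI and one with a 14 cm^3 spherical
liver-like VOI.  Phantom grids are 1.5 mm isotropic; patient-like grids
are 1.5 x 1.5 x 3.0 mm.  Grid extents (48^3 voxels for phantoms,
48 x 48 x 24 for patients) keep a full study desk-scale while leaving
comfortable margins around every VOI.

Default corruption magnitudes are deliberately modest stand-ins for an
unremarkable clinical scanner -- +/-2% session gain drift, 2% bias-field
amplitude, signal-to-noise ratio 50 -- and are fully config-exposed.
"""

from __future__ import annotations

import csv
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .core import (
    ImageVolume,
    StudyDataset,
    VOIMask,
    make_cylinder_mask,
    make_sphere_mask,
    write_volume,
)
from .synthetic import (
    ConfigError,
    PhantomSpec,
    ScannerParams,
    generate_phantom,
    make_ellipsoid_mask,
    simulate_session_series,
)

__all__ = [
    "ScannerSettings",
    "DatasetSettings",
    "StudyConfig",
    "build_study",
    "write_study",
]

# 4.2 cm^3 cylindrical VOI (r=8.2 mm, h=20 mm -> pi r^2 h = 4223 mm^3)
CYL_RADIUS_MM = 8.2
CYL_HEIGHT_MM = 20.0
# 14 cm^3 spherical VOI (r=14.95 mm -> 4/3 pi r^3 = 13995 mm^3)
SPHERE_RADIUS_MM = 14.95


@dataclass
class ScannerSettings:
    """Config-level scanner corruption magnitudes (all disabled at 0)."""

    gain_drift: float = 0.02
    bias_amplitude: float = 0.02
    bias_order: int = 2
    noise_snr: float = 50.0
    shift_mm: float = 0.0

    @classmethod
    def disabled(cls) -> "ScannerSettings":
        return cls(gain_drift=0.0, bias_amplitude=0.0, noise_snr=0.0, shift_mm=0.0)


@dataclass
class DatasetSettings:
    name: str
    kind: str  # sphere_grid | uniform_cylinder | textured_organ
    n_subjects: int
    n_sessions: int
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    voi: str  # cylinders4 | cylinders2 | kidney | sphere
    scanner: ScannerSettings = field(default_factory=ScannerSettings)

    def __post_init__(self) -> None:
        if self.n_sessions < 2:
            raise ConfigError("each dataset needs at least 2 sessions")
        if self.n_subjects < 1:
            raise ConfigError("each dataset needs at least 1 subject")
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if isinstance(self.scanner, dict):
            self.scanner = ScannerSettings(**self.scanner)


@dataclass
class StudyConfig:
    """Top-level study description; YAML round-trippable."""

    seed: int = 0
    threshold_percent: float = 5.0
    n_bins: int = 64
    discretization: str = "fbn"
    normalization: str = "none"
    sd_convention: str = "sample"  # sample (n-1) or population (n)
    datasets: list[DatasetSettings] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.datasets = [
            d if isinstance(d, DatasetSettings) else DatasetSettings(**d)
            for d in self.datasets
        ]

    @classmethod
    def default(cls, seed: int = 0, scanner: ScannerSettings | None = None) -> "StudyConfig":
        """The four-dataset study layout with shared scanner settings."""
        sc = scanner if scanner is not None else ScannerSettings()
        return cls(
            seed=seed,
            datasets=[
                DatasetSettings(
                    name="monthly_phantom",
                    kind="sphere_grid",
                    n_subjects=1,
                    n_sessions=11,
                    shape=(48, 48, 48),
                    spacing=(1.5, 1.5, 1.5),
                    voi="cylinders4",
                    scanner=sc,
                ),
                DatasetSettings(
                    name="daily_phantom",
                    kind="uniform_cylinder",
                    n_subjects=1,
                    n_sessions=11,
                    shape=(48, 48, 48),
                    spacing=(1.5, 1.5, 1.5),
                    voi="cylinders2",
                    scanner=sc,
                ),
                DatasetSettings(
                    name="kidney",
                    kind="textured_organ",
                    n_subjects=10,
                    n_sessions=5,
                    shape=(48, 48, 24),
                    spacing=(1.5, 1.5, 3.0),
                    voi="kidney",
                    scanner=sc,
                ),
                DatasetSettings(
                    name="liver",
                    kind="textured_organ",
                    n_subjects=10,
                    n_sessions=5,
                    shape=(48, 48, 24),
                    spacing=(1.5, 1.5, 3.0),
                    voi="sphere",
                    scanner=sc,
                ),
            ],
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"invalid config: {exc}") from exc

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _make_vois(volume: ImageVolume, kind: str) -> dict[str, VOIMask]:
    if kind == "cylinders4":
        return {
            f"voi{i + 1}": make_cylinder_mask(
                volume, (sx * 15.0, sy * 15.0, 0.0), CYL_RADIUS_MM, CYL_HEIGHT_MM,
                axis="z", label=f"voi{i + 1}",
            )
            for i, (sx, sy) in enumerate([(1, 1), (1, -1), (-1, 1), (-1, -1)])
        }
    if kind == "cylinders2":
        return {
            f"voi{i + 1}": make_cylinder_mask(
                volume, (0.0, sy * 16.0, 0.0), CYL_RADIUS_MM, CYL_HEIGHT_MM,
                axis="z", label=f"voi{i + 1}",
            )
            for i, sy in enumerate([1, -1])
        }
    if kind == "kidney":
        return {
            "kidney": make_ellipsoid_mask(
                volume, (0.0, 0.0, 0.0), (12.0, 16.0, 18.0), label="kidney"
            )
        }
    if kind == "sphere":
        return {
            "liver": make_sphere_mask(
                volume, (0.0, 0.0, 0.0), SPHERE_RADIUS_MM, label="liver"
            )
        }
    raise ConfigError(f"unknown VOI layout {kind!r}")


def _object_for(ds: DatasetSettings, subject_index: int, texture_seed: int) -> ImageVolume:
    if ds.kind == "sphere_grid":
        spec = PhantomSpec(kind="sphere_grid", foreground=100.0, background=10.0)
    elif ds.kind == "uniform_cylinder":
        spec = PhantomSpec(kind="uniform_cylinder", foreground=100.0, background=0.0)
    elif ds.kind == "textured_organ":
        spec = PhantomSpec(
            kind="textured_organ",
            foreground=100.0,
            background=0.0,
            texture_seed=texture_seed,
        )
    else:
        raise ConfigError(f"unknown phantom kind {ds.kind!r}")
    return generate_phantom(spec, ds.shape, ds.spacing)


def build_study(config: StudyConfig) -> dict[str, StudyDataset]:
    """Generate all datasets of the study, deterministically from the seed."""
    if not config.datasets:
        raise ConfigError("study config lists no datasets")
    root_ss = np.random.SeedSequence(config.seed)
    dataset_seeds = root_ss.spawn(len(config.datasets))
    out: dict[str, StudyDataset] = {}
    for ds, ds_ss in zip(config.datasets, dataset_seeds):
        subject_seeds = ds_ss.spawn(ds.n_subjects)
        subjects = [f"sub{j + 1:02d}" for j in range(ds.n_subjects)]
        sessions = [f"ses{t + 1:02d}" for t in range(ds.n_sessions)]
        items: dict[tuple[str, str, str], tuple[ImageVolume, VOIMask]] = {}
        voi_names: list[str] | None = None
        for j, (subject, sub_ss) in enumerate(zip(subjects, subject_seeds)):
            tex_seed, scan_seed = (int(s) for s in sub_ss.generate_state(2) % (2**31))
            obj = _object_for(ds, j, tex_seed)
            masks = _make_vois(obj, ds.voi)
            if voi_names is None:
                voi_names = list(masks)
            sc = ds.scanner
            fg = obj.data[obj.data > 0]
            sigma = float(fg.mean() / sc.noise_snr) if sc.noise_snr > 0 else 0.0
            params = ScannerParams.drifting(
                ds.n_sessions,
                gain_drift=sc.gain_drift,
                noise_sigma=sigma,
                bias_amplitude=sc.bias_amplitude,
                bias_order=sc.bias_order,
                shift_mm=sc.shift_mm,
                seed=scan_seed,
            )
            series = simulate_session_series(
                obj, params, ds.n_sessions, subject=subject, masks=masks
            )
            for session, vol in zip(sessions, series.volumes):
                for voi, mask in masks.items():
                    items[(subject, session, voi)] = (vol, mask)
        out[ds.name] = StudyDataset(
            name=ds.name,
            subjects=subjects,
            sessions=sessions,
            vois=voi_names or [],
            items=items,
        )
    return out


def write_study(datasets: dict[str, StudyDataset], outdir: str | os.PathLike) -> str:
    """Write volumes/masks as NIfTI plus a manifest CSV; returns manifest path."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    manifest = os.path.join(outdir, "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dataset", "subject", "session", "voi", "volume_path", "mask_path"])
        for name, ds in datasets.items():
            written_masks: dict[tuple[str, str], str] = {}
            written_vols: dict[tuple[str, str], str] = {}
            for subject, session, voi in ds.triples():
                vol, mask = ds.get(subject, session, voi)
                vkey = (subject, session)
                if vkey not in written_vols:
                    vpath = os.path.join(outdir, f"{name}_{subject}_{session}.nii.gz")
                    write_volume(vol, vpath)
                    written_vols[vkey] = vpath
                mkey = (subject, voi)
                if mkey not in written_masks:
                    mpath = os.path.join(outdir, f"{name}_{subject}_{voi}_mask.nii.gz")
                    write_volume(mask, mpath)
                    written_masks[mkey] = mpath
                writer.writerow(
                    [name, subject, session, voi, written_vols[vkey], written_masks[mkey]]
                )
    return manifest
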