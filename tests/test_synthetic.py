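"""Phantom generators, the scanner model, and the study builder."""

import numpy as np
import pytest
from scipy import ndimage

from radstab import (
    PhantomSpec,
    ScannerParams,
    StudyConfig,
    ScannerSettings,
    build_study,
    generate_phantom,
    simulate_session_series,
)
from radstab.synthetic import ConfigError


class TestGeneratePhantom:
    def test_uniform_cylinder_is_binary(self):
        spec = PhantomSpec(kind="uniform_cylinder", foreground=100.0, background=0.0)
        vol = generate_phantom(spec, (48, 48, 48), (1.5, 1.5, 1.5))
        inside = vol.data[vol.data > 0]
        assert set(np.unique(inside)) == {100.0}

    def test_sphere_grid_ball_count(self):
        spec = PhantomSpec(kind="sphere_grid", ball_radius_mm=3.0, ball_pitch_mm=15.0,
                           foreground=100.0, background=0.0)
        vol = generate_phantom(spec, (48, 48, 48), (1.5, 1.5, 1.5))
        labeled, n = ndimage.label(vol.data > 50)
        half = 48 * 1.5 / 2
        per_axis = 2 * int(np.floor((half - 3.0) / 15.0)) + 1
        assert n == per_axis**3

    def test_textured_organ_zero_contrast_is_constant(self):
        spec = PhantomSpec(kind="textured_organ", texture_contrast=0.0,
                           organ_semiaxes_mm=(12.0, 14.0, 12.0))
        vol = generate_phantom(spec, (32, 32, 24), (1.5, 1.5, 3.0))
        inside = vol.data[vol.data > 0]
        assert np.allclose(inside, inside[0])

    def test_textured_organ_seeded(self):
        spec = PhantomSpec(kind="textured_organ", texture_seed=7,
                           organ_semiaxes_mm=(12.0, 14.0, 12.0))
        a = generate_phantom(spec, (24, 24, 16), (1.5, 1.5, 3.0))
        b = generate_phantom(spec, (24, 24, 16), (1.5, 1.5, 3.0))
        np.testing.assert_array_equal(a.data, b.data)

    def test_geometry_overflow(self):
        from radstab import GeometryError

        spec = PhantomSpec(kind="uniform_cylinder", cylinder_radius_mm=100.0)
        with pytest.raises(GeometryError):
            generate_phantom(spec, (16, 16, 16), (1.0, 1.0, 1.0))


class TestSessionSeries:
    def _object(self):
        spec = PhantomSpec(kind="uniform_cylinder", cylinder_radius_mm=8.0,
                           cylinder_height_mm=16.0)
        return generate_phantom(spec, (24, 24, 24), (1.5, 1.5, 1.5))

    def test_identity_when_disabled(self):
        obj = self._object()
        series = simulate_session_series(obj, ScannerParams.identity(3), 3)
        for vol in series.volumes:
            np.testing.assert_array_equal(vol.data, obj.data)

    def test_same_seed_bit_identical(self):
        obj = self._object()
        params = ScannerParams.drifting(3, gain_drift=0.1, noise_sigma=2.0,
                                        bias_amplitude=0.05, seed=11)
        a = simulate_session_series(obj, params, 3)
        b = simulate_session_series(obj, params, 3)
        for va, vb in zip(a.volumes, b.volumes):
            np.testing.assert_array_equal(va.data, vb.data)

    def test_gain_scales_mean(self):
        obj = self._object()
        params = ScannerParams(gain_per_session=(1.0, 1.2))
        series = simulate_session_series(obj, params, 2)
        m1, m2 = (v.data.mean() for v in series.volumes)
        assert m2 == pytest.approx(1.2 * m1, rel=1e-12)

    def test_mismatched_sequence_length(self):
        obj = self._object()
        with pytest.raises(ConfigError):
            simulate_session_series(obj, ScannerParams(gain_per_session=(1.0,)), 3)

    def test_rician_mean_at_high_snr(self):
        """For signal A >> sigma the Rician sample mean recovers A."""
        obj = generate_phantom(
            PhantomSpec(kind="uniform_cylinder", cylinder_radius_mm=14.0,
                        cylinder_height_mm=28.0, cavity_centers_mm=()),
            (32, 32, 32), (1.0, 1.0, 1.0),
        )
        sigma = 2.0  # A = 100 -> SNR 50
        params = ScannerParams(gain_per_session=(1.0, 1.0), noise_sigma=sigma, seed=3)
        series = simulate_session_series(obj, params, 2)
        inside = obj.data == 100.0
        n = int(inside.sum())
        assert n >= 10_000
        sample_mean = series.volumes[0].data[inside].mean()
        # Rician bias at A >> sigma is sigma^2/(2A); allow 3 standard errors.
        se = sigma / np.sqrt(n)
        assert abs(sample_mean - (100.0 + sigma**2 / 200.0)) < 3 * se

    def test_bias_field_bound(self):
        obj = self._object()
        amp = 0.07
        params = ScannerParams(gain_per_session=(1.0, 1.0),
                               bias_field_amplitude=amp, seed=5)
        series = simulate_session_series(obj, params, 2)
        inside = obj.data > 0
        ratio = series.volumes[0].data[inside] / obj.data[inside]
        assert ratio.min() >= 1 - amp - 1e-12
        assert ratio.max() <= 1 + amp + 1e-12

    def test_noise_independent_across_sessions(self):
        obj = self._object()
        params = ScannerParams(gain_per_session=(1.0, 1.0), noise_sigma=2.0, seed=9)
        series = simulate_session_series(obj, params, 2)
        assert not np.array_equal(series.volumes[0].data, series.volumes[1].data)


class TestBuildStudy:
    def test_default_layout(self):
        datasets = build_study(StudyConfig.default(seed=0, scanner=ScannerSettings.disabled()))
        sizes = {
            name: (len(d.subjects), len(d.sessions), len(d.vois))
            for name, d in datasets.items()
        }
        assert sizes == {
            "monthly_phantom": (1, 11, 4),
            "daily_phantom": (1, 11, 2),
            "kidney": (10, 5, 1),
            "liver": (10, 5, 1),
        }

    def test_minimal_study(self):
        cfg = StudyConfig.default(seed=0)
        for ds in cfg.datasets:
            ds.n_subjects = 1
            ds.n_sessions = 2
        datasets = build_study(cfg)
        assert all(len(d.sessions) == 2 for d in datasets.values())

    def test_session_count_below_two_rejected(self):
        from radstab.study import DatasetSettings

        with pytest.raises(ConfigError):
            DatasetSettings(
                name="x", kind="sphere_grid", n_subjects=1, n_sessions=1,
                shape=(16, 16, 16), spacing=(1.5, 1.5, 1.5), voi="cylinders2",
            )

    def test_seeded_determinism(self):
        cfg = StudyConfig.default(seed=42)
        for ds in cfg.datasets:
            ds.n_subjects = 1
            ds.n_sessions = 2
        a = build_study(cfg)
        b = build_study(cfg)
        for name in a:
            for triple in a[name].items:
                va, _ = a[name].items[triple]
                vb, _ = b[name].items[triple]
                np.testing.assert_array_equal(va.data, vb.data)

    def test_yaml_round_trip(self, tmp_path):
        cfg = StudyConfig.default(seed=5)
        cfg.to_yaml(tmp_path / "study.yaml")
        back = StudyConfig.from_yaml(tmp_path / "study.yaml")
        assert back.seed == 5
        assert [d.name for d in back.datasets] == [d.name for d in cfg.datasets]
        assert back.datasets[0].scanner.noise_snr == cfg.datasets[0].scanner.noise_snr
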