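"""CoV statistic, dataset aggregation, and robust-feature selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radstab import cov, dataset_cov, select_robust
from radstab.robustness import CoVTable


class TestCov:
    def test_constant_series_zero(self):
        assert cov([5, 5, 5, 5]) == 0.0

    def test_sample_sd_examples(self):
        assert cov([1, 2, 3]) == pytest.approx(50.0)
        assert cov([2, 4]) == pytest.approx(47.14, abs=0.01)

    def test_population_convention(self):
        # population sd of (1,2,3) = sqrt(2/3), mean 2
        assert cov([1, 2, 3], ddof=0) == pytest.approx(100 * np.sqrt(2 / 3) / 2)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            cov([1.0])

    def test_unstable_mean_flagged(self):
        assert np.isnan(cov([-1.0, 1.0]))

    @settings(deadline=None, max_examples=50)
    @given(
        seed=st.integers(0, 10_000),
        k=st.floats(0.01, 1000.0),
    )
    def test_scale_invariance(self, seed, k):
        rng = np.random.default_rng(seed)
        v = rng.normal(50, 5, 6)
        assert cov(k * v) == pytest.approx(cov(v), rel=1e-9)


def _long_table(rows):
    return pd.DataFrame(
        rows, columns=["dataset", "subject", "session", "voi", "category", "feature", "value"]
    )


class TestDatasetCov:
    def test_mean_over_vois(self):
        rows = []
        # voi1 values (1,2,3) -> CoV 50; voi2 values (2,4) padded to 3 sessions
        for s, v in zip(["s1", "s2", "s3"], [1.0, 2.0, 3.0]):
            rows.append(("d", "sub1", s, "voi1", "C", "f", v))
        for s, v in zip(["s1", "s2", "s3"], [10.0, 10.0, 10.0]):
            rows.append(("d", "sub1", s, "voi2", "C", "f", v))
        table = dataset_cov("d", _long_table(rows))
        agg = table.aggregated
        assert agg.loc[0, "mean_cov"] == pytest.approx(25.0)  # mean(50, 0)

    def test_single_unit_passthrough(self):
        rows = [("d", "sub1", s, "voi1", "C", "f", v)
                for s, v in zip(["s1", "s2", "s3"], [1.0, 2.0, 3.0])]
        table = dataset_cov("d", _long_table(rows))
        assert table.aggregated.loc[0, "mean_cov"] == pytest.approx(50.0)

    def test_patientwise_mean_matches_hand_computation(self, rng):
        rows = []
        expected = []
        for j in range(10):
            vals = rng.normal(100, 3, 5)
            expected.append(100 * vals.std(ddof=1) / abs(vals.mean()))
            for t, v in enumerate(vals):
                rows.append(("pat", f"sub{j}", f"s{t}", "organ", "C", "f", v))
        table = dataset_cov("pat", _long_table(rows))
        assert table.aggregated.loc[0, "mean_cov"] == pytest.approx(np.mean(expected))

    def test_flagged_majority_excluded(self):
        rows = []
        for s in ["s1", "s2"]:
            rows.append(("d", "sub1", s, "voi1", "C", "f", np.nan))
            rows.append(("d", "sub1", s, "voi2", "C", "f", np.nan))
            rows.append(("d", "sub1", s, "voi3", "C", "f", 5.0))
        table = dataset_cov("d", _long_table(rows))
        assert bool(table.aggregated.loc[0, "excluded"])


def _agg_table(name, feature_covs):
    agg = pd.DataFrame(
        [
            (cat, feat, mc, 1, not np.isfinite(mc), "" if np.isfinite(mc) else "flagged")
            for (cat, feat), mc in feature_covs.items()
        ],
        columns=["category", "feature", "mean_cov", "n_units", "excluded", "reason"],
    )
    return CoVTable(dataset=name, per_unit=pd.DataFrame(), aggregated=agg)


class TestSelectRobust:
    def test_intersection_and_boundary(self):
        f1, f2, f3 = ("C", "f1"), ("C", "f2"), ("C", "f3")
        covs = [
            {f1: 2.0, f2: 4.0, f3: 4.0},
            {f1: 3.0, f2: 6.0, f3: 5.0},  # f3 exactly 5.0 -> excluded (strict)
            {f1: 1.0, f2: 1.0, f3: 1.0},
            {f1: 4.0, f2: 1.0, f3: 1.0},
        ]
        tables = [_agg_table(f"d{i}", c) for i, c in enumerate(covs)]
        report = select_robust(tables, threshold=5.0)
        assert f1 in report.robust
        assert f2 not in report.robust
        assert f3 not in report.robust

    def test_incomplete_coverage_excluded(self):
        f = ("C", "f")
        tables = [
            _agg_table("d0", {f: 1.0}),
            _agg_table("d1", {}),
            _agg_table("d2", {f: 1.0}),
            _agg_table("d3", {f: 1.0}),
        ]
        report = select_robust(tables)
        assert f not in report.robust
        assert "incomplete coverage" in report.exclusions[f]

    def test_threshold_monotonicity(self, rng):
        feats = {("C", f"f{i}"): float(rng.uniform(0, 12)) for i in range(30)}
        tables = [_agg_table(f"d{i}", feats) for i in range(4)]
        sizes = [
            select_robust(tables, threshold=t).n_robust for t in (1.0, 3.0, 5.0, 10.0)
        ]
        assert sizes == sorted(sizes)


class TestRecoveryDirections:
    def test_gain_drift_spares_discretized_features(self):
        """Pure multiplicative drift: FBN-discretized histogram and texture
        features stay exactly invariant while raw mean/energy drift away."""
        from radstab import (
            ScannerSettings,
            StudyConfig,
            build_study,
            extract_study_features,
        )

        cfg = StudyConfig.default(
            seed=3,
            scanner=ScannerSettings(
                gain_drift=0.2, bias_amplitude=0.0, noise_snr=0.0, shift_mm=0.0
            ),
        )
        cfg.datasets = [d for d in cfg.datasets if d.name == "liver"]
        cfg.datasets[0].n_subjects = 2
        cfg.datasets[0].n_sessions = 3
        feats = extract_study_features(build_study(cfg), config=cfg)
        agg = dataset_cov("liver", feats).aggregated.set_index(["category", "feature"])
        for key in [
            ("First-order", "Hist entropy"),
            ("First-order", "Norm entropy"),
            ("First-order", "Uniformity"),
            ("Co-occurrence", "Entropy"),
            ("Run-length", "Short-run emphasis"),
        ]:
            assert agg.loc[key, "mean_cov"] == 0.0, key
        for key in [("First-order", "Mean"), ("First-order", "Energy")]:
            assert agg.loc[key, "mean_cov"] > 5.0, key
        # Shape features never see the intensities at all.
        shape_covs = agg.loc["Shape-based"]["mean_cov"].dropna()
        assert (shape_covs == 0.0).all()


class TestRunStudyMinimal:
    def test_determinism_and_outputs(self, tmp_path):
        """A down-scaled clean study runs end to end and is reproducible."""
        from radstab import ScannerSettings, StudyConfig, run_study

        cfg = StudyConfig.default(seed=7, scanner=ScannerSettings.disabled())
        for ds in cfg.datasets:
            ds.n_subjects = 1
            ds.n_sessions = 2
        rep1, feats1, _ = run_study(cfg, outdir=tmp_path / "run1")
        rep2, feats2, _ = run_study(cfg, outdir=tmp_path / "run2")
        assert rep1.to_dict() == rep2.to_dict()
        pd.testing.assert_frame_equal(feats1, feats2)
        assert (tmp_path / "run1" / "report.json").exists()
        assert (tmp_path / "run1" / "features.csv").exists()
        # identical sessions -> every finite aggregated CoV is exactly 0
        cov_df = pd.read_csv(tmp_path / "run1" / "cov_table.csv")
        finite = cov_df["mean_cov"].dropna()
        assert (finite == 0.0).all()
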