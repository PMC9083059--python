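"""Repeatability/reproducibility workflow: CoV, aggregation, selection.

The figure of merit is the coefficient of variation of a feature across
repeat sessions, CoV = 100 * sigma / |mu| (sample standard deviation by
default).  Per dataset, CoV is first computed per aggregation unit --
each VOI separately for phantom datasets, each subject for patient-like
datasets; in general each (subject, VOI) series -- and then averaged
(unweighted) over units.  A feature is robust in a dataset when its
aggregated CoV is strictly below the threshold (default 5%), and enters
the final robust set only when robust in every dataset.

Undefined (NaN-flagged) feature values are excluded with a recorded
reason and never imputed; a feature is dropped from a dataset when more
than half of its units are flagged, and a feature missing from any
dataset is excluded from the final set as "incomplete coverage".
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import StudyDataset
from .registry import enumerate_registry

logger = logging.getLogger("radstab")

__all__ = [
    "UnstableMeanError",
    "CoVTable",
    "RobustnessReport",
    "cov",
    "dataset_cov",
    "select_robust",
    "run_study",
]

_EPS = 1e-12


class UnstableMeanError(ValueError):
    """CoV requested for a series whose mean is unstably close to zero."""


def cov(values, ddof: int = 1) -> float:
    """Coefficient of variation in percent: 100 * sd / |mean|.

    ``ddof=1`` gives the sample (n-1) standard deviation convention.
    Returns NaN (the flagged-undefined value) when the mean is within
    1e-12 * sd of zero, where the ratio is numerically meaningless.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("CoV needs at least 2 finite values")
    if v.max() == v.min():
        # Identical values have zero dispersion by definition; computing
        # sd via the float mean would leave ~1e-14 rounding residue.
        return 0.0
    sd = float(v.std(ddof=ddof))
    mean = float(v.mean())
    if abs(mean) < _EPS * max(sd, 1e-300):
        return float("nan")
    return 100.0 * sd / abs(mean)


@dataclass
class CoVTable:
    """Per-unit and aggregated CoV for one dataset."""

    dataset: str
    per_unit: pd.DataFrame  # unit, category, feature, cov, n, flag
    aggregated: pd.DataFrame  # category, feature, mean_cov, n_units, excluded, reason


def dataset_cov(
    dataset_name: str,
    features: pd.DataFrame,
    ddof: int = 1,
    min_sessions: int = 2,
) -> CoVTable:
    """Per-unit CoV over sessions, then the unweighted mean over units.

    ``features`` is the long-format table produced by
    :func:`radstab.extraction.extract_study_features` (already restricted
    or restrictable by its ``dataset`` column).  The aggregation unit is
    the (subject, voi) pair: for the single-subject phantom datasets this
    reduces to "each VOI separately", for the single-VOI patient datasets
    to "each subject separately".
    """
    df = features
    if "dataset" in df.columns:
        df = df[df["dataset"] == dataset_name]
    if df.empty:
        raise ValueError(f"no feature rows for dataset {dataset_name!r}")

    unit = df["subject"].astype(str) + "/" + df["voi"].astype(str)
    df = df.assign(unit=unit)
    records = []
    grouped = df.groupby(["unit", "category", "feature"], sort=False)["value"]
    for (u, category, feature), series in grouped:
        vals = series.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        n_dropped = vals.size - finite.size
        if finite.size < min_sessions:
            records.append((u, category, feature, np.nan, finite.size, "too-few-sessions"))
            continue
        c = cov(finite, ddof=ddof)
        if np.isnan(c):
            records.append((u, category, feature, np.nan, finite.size, "unstable-mean"))
        elif n_dropped > 0:
            records.append((u, category, feature, c, finite.size, "partial-undefined"))
        else:
            records.append((u, category, feature, c, finite.size, ""))
    per_unit = pd.DataFrame(
        records, columns=["unit", "category", "feature", "cov", "n", "flag"]
    )

    agg_records = []
    n_units_total = per_unit["unit"].nunique()
    for (category, feature), sub in per_unit.groupby(["category", "feature"], sort=False):
        ok = sub[np.isfinite(sub["cov"])]
        n_flagged = len(sub) - len(ok)
        if n_flagged * 2 > n_units_total or ok.empty:
            reasons = ", ".join(sorted(set(sub.loc[~np.isfinite(sub["cov"]), "flag"])))
            agg_records.append(
                (category, feature, np.nan, len(ok), True, f"flagged-majority: {reasons}")
            )
            continue
        agg_records.append(
            (category, feature, float(ok["cov"].mean()), len(ok), False, "")
        )
    aggregated = pd.DataFrame(
        agg_records,
        columns=["category", "feature", "mean_cov", "n_units", "excluded", "reason"],
    )
    n_excl = int(aggregated["excluded"].sum())
    if n_excl:
        logger.info(
            "%s: %d features excluded from aggregation (flagged units)",
            dataset_name,
            n_excl,
        )
    return CoVTable(dataset=dataset_name, per_unit=per_unit, aggregated=aggregated)


@dataclass
class RobustnessReport:
    """Per-dataset robust sets, the final intersection, and bookkeeping."""

    threshold_percent: float
    per_dataset_robust: dict[str, set]
    robust: set = field(default_factory=set)
    exclusions: dict = field(default_factory=dict)
    per_category_counts: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def n_robust(self) -> int:
        return len(self.robust)

    def to_dict(self) -> dict:
        registry = enumerate_registry()
        order = {
            (cat, feat): k
            for k, (cat, feat) in enumerate(
                (c, f) for c, feats in registry.categories.items() for f in feats
            )
        }
        robust_sorted = sorted(self.robust, key=lambda cf: order.get(tuple(cf), 1 << 30))
        return {
            "threshold_percent": self.threshold_percent,
            "n_robust": self.n_robust,
            "n_total": registry.total,
            "per_category_counts": self.per_category_counts,
            "robust_features": [list(cf) for cf in robust_sorted],
            "per_dataset_robust_counts": {
                name: len(s) for name, s in self.per_dataset_robust.items()
            },
            "n_excluded": len(self.exclusions),
            "exclusions": {f"{c}|{f}": r for (c, f), r in sorted(self.exclusions.items())},
            "metadata": self.metadata,
        }


def select_robust(
    tables: list[CoVTable] | dict[str, CoVTable],
    threshold: float = 5.0,
) -> RobustnessReport:
    """Intersect per-dataset robust sets under strict CoV < threshold."""
    if isinstance(tables, dict):
        tables = list(tables.values())
    if not tables:
        raise ValueError("no CoV tables given")
    per_dataset: dict[str, set] = {}
    excluded: dict[tuple[str, str], str] = {}
    coverage: dict[tuple[str, str], int] = {}
    for table in tables:
        robust = set()
        for row in table.aggregated.itertuples(index=False):
            key = (row.category, row.feature)
            coverage[key] = coverage.get(key, 0) + 1
            if row.excluded or not np.isfinite(row.mean_cov):
                excluded.setdefault(key, f"excluded in {table.dataset}: {row.reason}")
            elif row.mean_cov < threshold:  # strict inequality at the boundary
                robust.add(key)
        per_dataset[table.dataset] = robust

    final = set.intersection(*per_dataset.values()) if per_dataset else set()
    n_datasets = len(tables)
    for key, n_seen in coverage.items():
        if n_seen < n_datasets:
            excluded.setdefault(key, "incomplete coverage")
    final -= set(excluded)

    registry = enumerate_registry()
    counts = {
        category: sum(1 for c, _ in final if c == category)
        for category in registry.categories
    }
    return RobustnessReport(
        threshold_percent=threshold,
        per_dataset_robust=per_dataset,
        robust=final,
        exclusions=excluded,
        per_category_counts=counts,
        metadata={"n_datasets": n_datasets},
    )


def run_study(
    config, outdir: str | os.PathLike | None = None
) -> tuple[RobustnessReport, pd.DataFrame, dict[str, CoVTable]]:
    """End-to-end pipeline: simulate, extract, CoV, select; optionally write.

    Returns (report, features long-table, CoV tables).  With ``outdir``
    set, writes ``features.csv``, ``cov_table.csv``, ``robust_features.csv``
    and ``report.json``.
    """
    from .extraction import extract_study_features
    from .study import StudyConfig, build_study

    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    ddof = 1 if config.sd_convention == "sample" else 0
    datasets = build_study(config)
    features = extract_study_features(datasets, config=config)
    tables = {
        name: dataset_cov(name, features, ddof=ddof) for name in datasets
    }
    report = select_robust(tables, threshold=config.threshold_percent)
    report.metadata.update(
        {
            "seed": config.seed,
            "sd_convention": config.sd_convention,
            "n_bins": config.n_bins,
            "discretization": config.discretization,
            "normalization": config.normalization,
            "datasets": [d.name for d in config.datasets],
        }
    )
    if outdir is not None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        features.to_csv(os.path.join(outdir, "features.csv"), index=False)
        pd.concat(
            [t.aggregated.assign(dataset=t.dataset) for t in tables.values()]
        ).to_csv(os.path.join(outdir, "cov_table.csv"), index=False)
        pd.DataFrame(
            sorted(report.robust), columns=["category", "feature"]
        ).to_csv(os.path.join(outdir, "robust_features.csv"), index=False)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return report, features, tables
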