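"""ROI summaries and cohort statistics for quantitative cord maps.

Implements the study-level statistical machinery: per-region means and
SDs, inter-subject coefficients of variation (CoV = 100 SD/mean), the
odd/even-echo intra-subject robustness measure, paired t-tests between
regions, and intra-class correlation coefficients for the two half-data
measurements.  Sample (n-1) standard deviations are used throughout.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ParameterMaps, Volume3D

__all__ = [
    "ROISet",
    "roi_summary",
    "cohort_summary",
    "cov_percent",
    "robustness_percent",
    "paired_ttest",
    "icc",
    "ICCResult",
]


@dataclass
class ROISet:
    """Named regions over a label volume (regions are disjoint by label)."""

    labels: Volume3D
    regions: dict            # name -> label value or sequence of label values

    def mask(self, name: str) -> np.ndarray:
        spec = self.regions[name]
        values = [spec] if np.isscalar(spec) else list(spec)
        return np.isin(self.labels.data, values)


def roi_summary(
    maps: ParameterMaps,
    rois: ROISet,
    subject: str | None = None,
) -> pd.DataFrame:
    """Per region x parameter: mean, sample SD and voxel count.

    Only voxels valid under the map's own mask contribute.  An empty
    region after validity masking raises, naming the region.
    """
    if rois.labels.shape != maps.apd.shape:
        raise ValueError("ROI labels must share the map grid")
    rows = []
    for region in rois.regions:
        region_mask = rois.mask(region)
        for name, arr in maps.items():
            m = region_mask & maps.mask(name) & np.isfinite(arr)
            values = arr[m]
            if values.size == 0:
                raise ValueError(f"region {region!r} is empty after masking "
                                 f"for {name}")
            rows.append({
                "subject": subject, "region": region, "parameter": name,
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                "n_voxels": int(values.size),
            })
    return pd.DataFrame(rows)


def cov_percent(values) -> float:
    """Inter-subject coefficient of variation, 100 SD/mean (sample SD)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CoV needs at least two values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CoV undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / mean)


def robustness_percent(value_odd: float, value_even: float) -> float:
    """Intra-subject robustness: 100 SD/mean of the odd/even pair.

    The sample SD of two values is |a - b| / sqrt(2).
    """
    pair = np.array([value_odd, value_even], dtype=float)
    mean = pair.mean()
    if mean <= 0:
        raise ValueError("robustness undefined for non-positive mean")
    return float(100.0 * (abs(value_odd - value_even) / np.sqrt(2.0)) / mean)


def paired_ttest(a, b) -> tuple[float, int, float]:
    """Classical paired t-test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length samples, n >= 2")
    d = a - b
    if d.std(ddof=1) == 0.0:
        raise ValueError("paired t-test undefined: zero-variance differences")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


@dataclass
class ICCResult:
    value: float
    model: str
    defined: bool = True


def icc(pairs, model: str = "one_way") -> ICCResult:
    """Intra-class correlation of two measurements per subject.

    ``one_way`` is ICC(1,1) from one-way random-effects mean squares,
    (MSB - MSW)/(MSB + (k-1) MSW) with k = 2 — appropriate when the two
    half-data measurements are not distinguishable "raters".  ``two_way``
    is the absolute-agreement single-measure form ICC(A,1).
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least three subjects")
    row_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * row_means.var(ddof=1)
    msw = ((x - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    if model == "one_way":
        denom = msb + (k - 1) * msw
        if denom <= 0:
            warnings.warn("ICC undefined: degenerate variance")
            return ICCResult(float("nan"), model, defined=False)
        return ICCResult(float((msb - msw) / denom), model)
    if model == "two_way":
        col_means = x.mean(axis=0)
        msc = n * col_means.var(ddof=1)
        sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        denom = msb + (k - 1) * mse + k / n * (msc - mse)
        if denom <= 0:
            warnings.warn("ICC undefined: degenerate variance")
            return ICCResult(float("nan"), model, defined=False)
        return ICCResult(float((msb - mse) / denom), model)
    raise ValueError(f"unknown ICC model {model!r}")


def cohort_summary(subject_stats: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-subject ROI means into cohort mean, SD and CoV."""
    required = {"subject", "region", "parameter", "mean"}
    if not required.issubset(subject_stats.columns):
        raise ValueError(f"subject stats must have columns {sorted(required)}")
    rows = []
    for (region, parameter), grp in subject_stats.groupby(["region", "parameter"]):
        values = grp["mean"].to_numpy(dtype=float)
        rows.append({
            "region": region,
            "parameter": parameter,
            "n_subjects": len(values),
            "cohort_mean": float(values.mean()),
            "cohort_sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            "cov_percent": cov_percent(values) if len(values) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
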