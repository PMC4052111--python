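"""ROI CBF statistics, variability metrics and paired method comparison.

Conventions: the coefficient of variance is 100 * sample SD / mean with the
n-1 denominator throughout; the grey-to-white ratio is computed per subject
and then averaged; report tables round CBF to 2 decimals and C.V. to 1,
keeping full precision internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_fitting import trimmed_mean


@dataclass
class GroupStats:
    mean: float
    sd: float
    cv_pct: float
    n: int


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def roi_cbf(cbf_map: np.ndarray, mask: np.ndarray, trim_frac: float = 0.0) -> float:
    """(Optionally trimmed) mean CBF over mask voxels, mL/100 g/min."""
    mask = np.asarray(mask, dtype=bool)
    if cbf_map.shape != mask.shape:
        raise ValueError("CBF map and mask must share a grid")
    vals = np.asarray(cbf_map, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("mask selects no finite CBF voxels")
    return trimmed_mean(vals, trim_frac)


def gm_wm_ratio(cbf_gm: float, cbf_wm: float) -> float:
    """Grey-to-white perfusion ratio (dimensionless)."""
    if cbf_wm <= 0:
        raise ValueError(f"WM CBF must be positive for a ratio, got {cbf_wm}")
    return cbf_gm / cbf_wm


def cv_percent(values) -> float:
    """Coefficient of variance: 100 * sample SD (n-1) / mean, percent."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("coefficient of variance needs >= 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("coefficient of variance undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def interslice_cv(cbf_map: np.ndarray, mask: np.ndarray,
                  slice_axis: int = 2) -> float:
    """C.V. of per-slice masked mean CBF across slices intersecting the mask."""
    mask = np.asarray(mask, dtype=bool)
    if cbf_map.shape != mask.shape:
        raise ValueError("CBF map and mask must share a grid")
    slice_means = []
    for k in range(cbf_map.shape[slice_axis]):
        sl_mask = np.take(mask, k, axis=slice_axis)
        if not sl_mask.any():
            continue
        sl_vals = np.take(cbf_map, k, axis=slice_axis)[sl_mask]
        sl_vals = sl_vals[np.isfinite(sl_vals)]
        if sl_vals.size:
            slice_means.append(sl_vals.mean())
    if len(slice_means) < 2:
        raise ValueError("need >= 2 slices intersecting the mask")
    return cv_percent(slice_means)


def spatial_cv(cbf_map: np.ndarray, mask: np.ndarray) -> float:
    """C.V. over all masked voxel values."""
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(cbf_map, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need >= 2 masked voxels")
    return cv_percent(vals)


def temporal_cv(pwi_series: np.ndarray, slice_set, mask: np.ndarray,
                slice_axis: int = 2) -> float:
    """C.V. over time of the mean perfusion signal in chosen slices.

    Per time point, the signal is averaged over the intersection of ``mask``
    with the listed slices (on real data: the four slices near the
    transverse sinuses), then the C.V. is taken across time points.
    """
    pwi_series = np.asarray(pwi_series, dtype=float)
    if pwi_series.ndim != 4:
        raise ValueError("need a 4D perfusion-weighted series")
    if pwi_series.shape[3] < 2:
        raise ValueError("temporal C.V. needs >= 2 time points")
    region = np.zeros(pwi_series.shape[:3], dtype=bool)
    for k in slice_set:
        idx = [slice(None)] * 3
        idx[slice_axis] = k
        region[tuple(idx)] = True
    region &= np.asarray(mask, dtype=bool)
    if not region.any():
        raise ValueError("slice set and mask do not intersect")
    means = [pwi_series[..., tpt][region].mean()
             for tpt in range(pwi_series.shape[3])]
    return cv_percent(means)


def group_stats(per_subject_values) -> GroupStats:
    """Across-subject mean, sample SD and C.V.% of an ROI statistic."""
    vals = np.asarray(per_subject_values, dtype=float).ravel()
    if vals.size < 2:
        raise ValueError("group statistics need >= 2 subjects")
    return GroupStats(mean=float(vals.mean()), sd=float(vals.std(ddof=1)),
                      cv_pct=cv_percent(vals), n=int(vals.size))


def paired_ttest(values_a, values_b) -> TTestResult:
    """Two-tailed paired t-test (df = n-1) on matched per-subject values."""
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired t-test needs equal-length samples")
    if a.size < 2:
        raise ValueError("paired t-test needs >= 2 pairs")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        return TTestResult(t=np.nan, p=np.nan, df=a.size - 1, degenerate=True)
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       df=int(a.size - 1))


def perfusion_report(per_subject: pd.DataFrame,
                     round_output: bool = True) -> pd.DataFrame:
    """Group report table from per-subject rows.

    ``per_subject`` needs columns ``subject, method, cbf_gm, cbf_wm``.  The
    result stacks, per method, one row per subject with the GM/WM ratio plus
    Mean / S.D. / C.V.(%) summary rows, mirroring the conventional layout of
    multi-method perfusion comparisons.
    """
    required = {"subject", "method", "cbf_gm", "cbf_wm"}
    if not required <= set(per_subject.columns):
        raise ValueError(f"per-subject table needs columns {sorted(required)}")
    rows = []
    for method, grp in per_subject.groupby("method", sort=False):
        grp = grp.sort_values("subject")
        ratios = [gm_wm_ratio(g, w) for g, w in zip(grp.cbf_gm, grp.cbf_wm)]
        for (_, r), ratio in zip(grp.iterrows(), ratios):
            rows.append({"method": method, "row": str(r.subject),
                         "cbf_gm": r.cbf_gm, "cbf_wm": r.cbf_wm,
                         "ratio": ratio})
        for name, stat in (("Mean", np.mean), ("S.D.", lambda v: np.std(v, ddof=1)),
                           ("C.V.(%)", cv_percent)):
            rows.append({"method": method, "row": name,
                         "cbf_gm": float(stat(grp.cbf_gm.to_numpy())),
                         "cbf_wm": float(stat(grp.cbf_wm.to_numpy())),
                         "ratio": float(stat(np.asarray(ratios)))})
    report = pd.DataFrame(rows)
    if round_output:
        is_cv = report["row"] == "C.V.(%)"
        for col in ("cbf_gm", "cbf_wm", "ratio"):
            report[col] = np.where(is_cv, report[col].round(1),
                                   report[col].round(2))
    return report
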