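"""Susceptibility / partial-volume quality control.

Signal dropout near tissue boundaries shows up as low proton-density (M0)
voxels whose CBF estimates are unreliable.  The screen: correlate CBF with
M0 intensity within a tissue mask, flag voxels under an intensity cut, and
summarize the M0 intensity distribution (histogram + skewness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CorrelationResult:
    r2: float
    r: float
    n: int
    degenerate: bool = False


@dataclass
class FilterResult:
    mask: np.ndarray
    flagged_fraction: float
    n_flagged: int


@dataclass
class HistogramResult:
    counts: np.ndarray
    bin_edges: np.ndarray
    skewness: float
    n: int


def cbf_m0_correlation(cbf_map, m0_map, mask) -> CorrelationResult:
    """Squared Pearson correlation of CBF vs M0 intensity over masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(m0_map, dtype=float)[mask]
    y = np.asarray(cbf_map, dtype=float)[mask]
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("correlation needs >= 3 masked voxels")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(r2=np.nan, r=np.nan, n=int(x.size),
                                 degenerate=True)
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r2=r * r, r=r, n=int(x.size))


def low_intensity_filter(mask, m0_map, cut: float = 800.0) -> FilterResult:
    """Drop masked voxels with M0 below ``cut``; report the removed fraction."""
    if cut < 0:
        raise ValueError(f"intensity cut must be non-negative, got {cut}")
    mask = np.asarray(mask, dtype=bool)
    m0 = np.asarray(m0_map, dtype=float)
    n_total = int(mask.sum())
    if n_total == 0:
        return FilterResult(mask=mask.copy(), flagged_fraction=0.0, n_flagged=0)
    kept = mask & (m0 >= cut)
    n_flagged = n_total - int(kept.sum())
    return FilterResult(mask=kept, flagged_fraction=n_flagged / n_total,
                        n_flagged=n_flagged)


def intensity_histogram(m0_map, mask, bins: int = 50) -> HistogramResult:
    """Histogram + adjusted Fisher-Pearson sample skewness of masked M0 values."""
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(m0_map, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("histogram needs >= 1 masked voxel")
    counts, edges = np.histogram(vals, bins=bins)
    skew = float(stats.skew(vals, bias=False)) if vals.size >= 3 else np.nan
    return HistogramResult(counts=counts, bin_edges=edges, skewness=skew,
                           n=int(vals.size))


def qc_report(cbf_map, m0_map, gm_mask, wm_mask, cut: float = 800.0,
              bins: int = 50) -> dict:
    """Full QC summary for a subject: correlations before/after the cut,
    flagged fractions, and per-tissue intensity histograms."""
    out = {}
    for tissue, mask in (("gm", gm_mask), ("wm", wm_mask)):
        corr = cbf_m0_correlation(cbf_map, m0_map, mask)
        filt = low_intensity_filter(mask, m0_map, cut)
        corr_after = (cbf_m0_correlation(cbf_map, m0_map, filt.mask)
                      if filt.mask.sum() >= 3 else None)
        hist = intensity_histogram(m0_map, mask, bins)
        out[tissue] = {
            "r2": corr.r2,
            "r2_after_cut": corr_after.r2 if corr_after else None,
            "flagged_fraction": filt.flagged_fraction,
            "n_flagged": filt.n_flagged,
            "skewness": hist.skewness,
            "n_voxels": int(np.asarray(mask, dtype=bool).sum()),
        }
    out["intensity_cut"] = cut
    return out
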