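"""ROI kinetic-parameter estimation from multi-TI2 difference signals.

The multi-inversion-time experiment samples the ASL difference signal at a
ladder of total inversion times.  ROI signals are robustified with a
two-sided trimmed mean, compensated for the per-slice acquisition delay, and
optionally averaged across adjacent slice pairs for SNR before a bounded
nonlinear least-squares fit of the three-phase kinetic model.

Free parameters of :func:`fit_kinetic` are cbf, arterial transit time,
bolus duration, and an additive baseline offset.  A free multiplicative
amplitude would be exactly collinear with cbf (both scale the model
linearly), so the calibration amplitude 2*alpha*M0b is held at its measured
value and residual subtraction-error DC leakage is absorbed by the offset
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetic_model import (AcquisitionParams, KineticParams, delta_m,
                            slice_effective_ti2)

__all__ = [
    "RoiSignalCurve", "FitResult", "trimmed_mean", "slice_effective_ti2",
    "average_adjacent_slices", "fit_kinetic",
]

#: default optimizer bounds: cbf mL/100g/min, att ms, tau ms, offset signal units
DEFAULT_BOUNDS = {
    "cbf": (0.0, 300.0),
    "att": (0.0, 3000.0),
    "tau": (100.0, 3000.0),
    "offset": (-np.inf, np.inf),
}


@dataclass
class RoiSignalCurve:
    """Trimmed-mean difference signal sampled over effective inversion times."""

    ti2: np.ndarray          # effective TI2 per point, ms, strictly increasing
    dm: np.ndarray           # trimmed-mean difference signal per point
    n_voxels: np.ndarray     # voxel count behind each point
    roi_id: str = "roi"
    slices: tuple = ()

    def __post_init__(self) -> None:
        self.ti2 = np.asarray(self.ti2, dtype=float)
        self.dm = np.asarray(self.dm, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        if not (self.ti2.shape == self.dm.shape == self.n_voxels.shape):
            raise ValueError("ti2, dm and n_voxels must have equal length")
        if np.any(np.diff(self.ti2) <= 0):
            raise ValueError("TI2 values must be strictly increasing")
        if np.any(self.n_voxels <= 0):
            raise ValueError("every curve point needs > 0 contributing voxels")

    def __len__(self) -> int:
        return self.ti2.size


@dataclass
class FitResult:
    params: KineticParams
    offset: float
    rss: float
    residuals: np.ndarray
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    degenerate: bool = False
    n_iter: int = 0


def trimmed_mean(values, trim_frac: float = 0.05) -> float:
    """Two-sided trimmed mean: drop floor(trim_frac*n) values from each tail.

    With the floor rule small samples are never emptied; ``trim_frac=0``
    reduces to the arithmetic mean.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot take a trimmed mean of an empty sequence")
    if not 0.0 <= trim_frac < 0.5:
        raise ValueError(f"trim_frac must be in [0, 0.5), got {trim_frac}")
    k = int(np.floor(trim_frac * values.size))
    if k == 0:
        return float(values.mean())
    srt = np.sort(values)
    core = srt[k:values.size - k]
    if core.size == 0:  # unreachable under the floor rule; guarded anyway
        raise ValueError("trimming removed all values")
    return float(core.mean())


def average_adjacent_slices(ti2_per_slice, dm_per_slice, n_per_slice=None):
    """Average signals of non-overlapping adjacent slice pairs (0,1), (2,3), ...

    The pair's effective TI2 is the mean of the two slice TI2s; an odd
    trailing slice is kept unpaired.  Returns ``(ti2_pairs, dm_pairs,
    n_pairs, slice_groups)``.
    """
    ti2 = np.asarray(ti2_per_slice, dtype=float)
    dm = np.asarray(dm_per_slice, dtype=float)
    if ti2.size != dm.size:
        raise ValueError("per-slice TI2 and signal lengths differ")
    if ti2.size < 2:
        raise ValueError("need at least two slices to pair")
    n = (np.ones_like(ti2, dtype=int) if n_per_slice is None
         else np.asarray(n_per_slice, dtype=int))
    out_t, out_d, out_n, groups = [], [], [], []
    i = 0
    while i < ti2.size:
        j = min(i + 2, ti2.size)
        out_t.append(ti2[i:j].mean())
        out_d.append(dm[i:j].mean())
        out_n.append(int(n[i:j].sum()))
        groups.append(tuple(range(i, j)))
        i = j
    return np.array(out_t), np.array(out_d), np.array(out_n), groups


def fit_kinetic(curve: RoiSignalCurve, acq: AcquisitionParams,
                init: KineticParams | None = None,
                bounds: dict | None = None,
                fit_offset: bool = True) -> FitResult:
    """Bounded trust-region least-squares fit of the three-phase model.

    Minimizes sum((dm_obs - delta_m(t; cbf, att, tau) - offset)^2) over the
    curve's effective TI2 points.  ``init.m0b`` supplies the measured
    calibration amplitude (held fixed).  Deterministic given data and init;
    non-convergence and all-zero (degenerate) curves are flagged, not raised.
    """
    if len(curve) < 5:
        raise ValueError("need >= 5 distinct TI2 points (more than parameters)")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    if init is None:
        init = KineticParams(cbf=50.0, att=700.0,
                             tau=max(acq.ti1, bounds["tau"][0]), m0b=1.0)
    m0b = init.m0b
    t, y = curve.ti2, curve.dm

    if np.allclose(y, 0.0):
        lo_att, lo_tau = bounds["att"][0], bounds["tau"][0]
        kp = KineticParams(cbf=0.0, att=lo_att, tau=lo_tau, m0b=m0b)
        return FitResult(params=kp, offset=0.0, rss=0.0,
                         residuals=np.zeros_like(y), converged=True,
                         degenerate=True)

    names = ["cbf", "att", "tau"] + (["offset"] if fit_offset else [])

    def model(x):
        cbf, att, tau = x[0], x[1], x[2]
        off = x[3] if fit_offset else 0.0
        kp = KineticParams(cbf=max(cbf, 0.0), att=max(att, 0.0),
                           tau=max(tau, 1e-9), m0b=m0b)
        return delta_m(t, kp, acq) + off

    def resid(x):
        return model(x) - y

    x0 = [np.clip(init.cbf, *bounds["cbf"]),
          np.clip(init.att, *bounds["att"]),
          np.clip(init.tau, *bounds["tau"])]
    lo = [bounds["cbf"][0], bounds["att"][0], bounds["tau"][0]]
    hi = [bounds["cbf"][1], bounds["att"][1], bounds["tau"][1]]
    if fit_offset:
        x0.append(0.0)
        lo.append(bounds["offset"][0])
        hi.append(bounds["offset"][1])

    res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=2000)

    stderr: dict = {}
    dof = len(curve) - len(names)
    if dof > 0 and res.jac is not None:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * (2.0 * res.cost) / dof
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            stderr = dict(zip(names, se))
        except np.linalg.LinAlgError:
            stderr = {}

    kp = KineticParams(cbf=float(res.x[0]), att=float(res.x[1]),
                       tau=float(res.x[2]), m0b=m0b)
    return FitResult(
        params=kp,
        offset=float(res.x[3]) if fit_offset else 0.0,
        rss=float(2.0 * res.cost),
        residuals=res.fun.copy(),
        stderr=stderr,
        converged=bool(res.success),
        degenerate=False,
        n_iter=int(res.nfev),
    )
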