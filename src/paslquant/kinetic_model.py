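"""Single blood-compartment kinetic model for pulsed ASL and single-subtraction CBF.

The difference signal between control and label images, :math:`\\Delta M(t)`,
follows a three-phase piecewise model: zero before the labeled bolus arrives
(arterial transit time :math:`\\Delta t`), a linear inflow ramp weighted by
blood T1 decay while the bolus enters (duration :math:`\\tau`), and a decaying
plateau once the whole bolus has arrived.  With a temporally defined bolus
(Q2TIPS, width TI1) and an acquisition at total inversion time TI2 on the
plateau, perfusion follows from a single subtraction:

.. math::

    \\mathrm{CBF} = \\frac{\\lambda\\,\\Delta M}
                        {2\\,\\alpha\\,M_0\\,TI_1\\,e^{-TI_2/T_{1b}}}

All times are milliseconds internally.  CBF crosses the API boundary in
mL/100 g/min; internally it is mL/g/ms (conversion factor 6e6).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: mL/100 g/min per (mL/g/ms): 100 g/g * 60000 ms/min = 6e6
CBF_UNIT_FACTOR = 6.0e6


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulsed-ASL acquisition and quantification constants.

    Parameters
    ----------
    ti1 : float
        Temporal bolus width (Q2TIPS saturation time), ms.
    ti2_base : float
        Total inversion time of the first (most inferior) slice, ms.
    slice_dt : float
        Per-slice acquisition increment for ascending EPI readout, ms.
    tr : float
        Repetition time, ms.
    alpha : float
        Labeling (inversion) efficiency, in (0, 1].
    t1b : float
        Longitudinal relaxation time of arterial blood, ms.
    lambda_ : float
        Blood/tissue water partition coefficient, mL/g.
    """

    ti1: float = 800.0
    ti2_base: float = 1800.0
    slice_dt: float = 30.0
    tr: float = 2500.0
    alpha: float = 0.95
    t1b: float = 1664.0
    lambda_: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.t1b <= 0:
            raise ValueError(f"t1b must be positive, got {self.t1b}")
        if self.ti1 <= 0:
            raise ValueError(f"ti1 must be positive, got {self.ti1}")
        if self.ti2_base < self.ti1:
            raise ValueError(
                f"ti2_base ({self.ti2_base}) must be >= ti1 ({self.ti1})"
            )
        if self.lambda_ <= 0:
            raise ValueError(f"lambda_ must be positive, got {self.lambda_}")

    @property
    def postlabeling_delay(self) -> float:
        """TI2 − TI1 of the first slice, ms."""
        return self.ti2_base - self.ti1

    def with_ti2(self, ti2_base: float) -> "AcquisitionParams":
        return replace(self, ti2_base=ti2_base)


@dataclass(frozen=True)
class KineticParams:
    """Per-voxel or per-ROI kinetic state.

    cbf in mL/100 g/min, arterial transit time ``att`` and bolus duration
    ``tau`` in ms, ``m0b`` the fully relaxed arterial-blood magnetization in
    scanner signal units.
    """

    cbf: float
    att: float
    tau: float
    m0b: float

    def __post_init__(self) -> None:
        if self.cbf < 0:
            raise ValueError(f"cbf must be >= 0, got {self.cbf}")
        if self.att < 0:
            raise ValueError(f"att must be >= 0, got {self.att}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.m0b <= 0:
            raise ValueError(f"m0b must be positive, got {self.m0b}")


def delta_m(t, kp: KineticParams, acq: AcquisitionParams):
    """Three-phase single-compartment ASL difference signal at time ``t`` (ms).

    Phase 1 (t < att): no labeled blood has arrived, signal 0.
    Phase 2 (att <= t < att + tau): linear inflow, ``2 a M0b f (t-att) e^{-t/T1b}``.
    Phase 3 (t >= att + tau): full bolus, ``2 a M0b f tau e^{-t/T1b}``.

    ``f`` is cbf converted to mL/g/ms.  Continuous at both breakpoints;
    vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be non-negative")
    f = kp.cbf / CBF_UNIT_FACTOR
    amp = 2.0 * acq.alpha * kp.m0b * f
    decay = np.exp(-t / acq.t1b)
    inflow = np.clip(t - kp.att, 0.0, kp.tau)
    out = amp * inflow * decay
    return out if out.ndim else float(out)


def m0_blood(m0_tissue, lambda_: float):
    """Arterial blood equilibrium magnetization from tissue proton density.

    M0b = M0 / lambda, with lambda the blood/tissue partition coefficient.
    """
    if lambda_ <= 0:
        raise ValueError(f"lambda_ must be positive, got {lambda_}")
    return m0_tissue / lambda_


def cbf_single_subtraction(dm, m0, acq: AcquisitionParams, ti2=None):
    """Quantify CBF (mL/100 g/min) from a mean difference signal and tissue M0.

    Implements the single-subtraction plateau inversion

        CBF = lambda * dm / (2 * alpha * m0 * TI1 * exp(-TI2/T1b)) * 6e6.

    ``ti2`` defaults to ``acq.ti2_base``; pass a per-voxel array for
    slice-timing compensation.  The sign of the output follows the sign of
    ``dm`` (negative values are preserved for subtraction-error QC).  When
    ``m0`` is an array, voxels with ``m0 <= 0`` quantify to NaN; a scalar
    ``m0 <= 0`` raises.
    """
    if ti2 is None:
        ti2 = acq.ti2_base
    denom = 2.0 * acq.alpha * np.asarray(m0, dtype=float) * acq.ti1 * np.exp(
        -np.asarray(ti2, dtype=float) / acq.t1b
    )
    dm = np.asarray(dm, dtype=float)
    if denom.ndim == 0:
        if denom <= 0:
            raise ValueError("m0 must be positive for scalar quantification")
        out = acq.lambda_ * dm / denom * CBF_UNIT_FACTOR
        return out if out.ndim else float(out)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = acq.lambda_ * dm / denom * CBF_UNIT_FACTOR
    return np.where(np.asarray(m0) > 0, out, np.nan)


def slice_effective_ti2(slice_index, acq: AcquisitionParams):
    """Effective TI2 of a slice under ascending acquisition: ti2_base + k*slice_dt."""
    idx = np.asarray(slice_index)
    if np.any(idx < 0):
        raise ValueError("slice_index must be non-negative")
    out = acq.ti2_base + idx * acq.slice_dt
    return out if out.ndim else float(out)


def cbf_map(mean_pwi: np.ndarray, mean_m0: np.ndarray, acq: AcquisitionParams,
            slice_axis: int = 2) -> np.ndarray:
    """Voxelwise single-subtraction CBF map with per-slice TI2 compensation.

    Voxels in slice ``k`` (along ``slice_axis``) use TI2 = ti2_base +
    k*slice_dt.  Voxels with non-positive M0 map to NaN.
    """
    if mean_pwi.shape != mean_m0.shape:
        raise ValueError(
            f"PWI shape {mean_pwi.shape} != M0 shape {mean_m0.shape}"
        )
    n_slices = mean_pwi.shape[slice_axis]
    shape = [1] * mean_pwi.ndim
    shape[slice_axis] = n_slices
    ti2 = slice_effective_ti2(np.arange(n_slices), acq).reshape(shape)
    return cbf_single_subtraction(mean_pwi, mean_m0, acq, ti2=ti2)
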