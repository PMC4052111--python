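"""Digital two-tissue perfusion phantom and pulsed-ASL series simulator.

The phantom is a nested pair of ellipsoids on a small EPI-like grid: a
grey-matter shell around a white-matter core, each carrying its own ground
truth (CBF, arterial transit time, bolus duration, proton density).  The
simulator generates alternating label/control volumes from the three-phase
kinetic model with per-slice acquisition delays, additive Gaussian thermal
noise, optional short-delay intravascular hyperintensities, optional rigid
motion (recorded in a ground-truth trace), and the pair of proton-density
calibration images.

What it emulates: thermal noise, slice-timing, bolus truncation by the
saturation train (Q2TIPS), vascular artifacts that decay with post-labeling
delay, boundary M0 attenuation (partial-volume rim).  What it does not:
physiological noise, B0/susceptibility distortion, realistic anatomy.

All randomness flows from the single spec seed via independent child
streams, so identical specs reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .kinetic_model import (CBF_UNIT_FACTOR, AcquisitionParams, KineticParams)
from .model_fitting import RoiSignalCurve
from .preprocessing import CONTROL, LABEL, AslSeries, MotionTrace, \
    apply_rigid_motion


@dataclass(frozen=True)
class TissueTruth:
    """Ground-truth kinetic state of one tissue class."""

    cbf: float      # mL/100 g/min
    att: float      # ms
    tau: float      # ms
    m0: float       # signal units

    def __post_init__(self) -> None:
        if min(self.cbf, self.att) < 0 or min(self.tau, self.m0) <= 0:
            raise ValueError("tissue truth values must be positive")


@dataclass(frozen=True)
class VesselArtifactSpec:
    """Compact bright clusters in inferior slices emulating intravascular signal.

    The difference-signal hyperintensity decays exponentially with
    post-labeling delay and vanishes entirely at the extinction delay,
    reproducing the disappearance of arterial artifacts once labeled blood
    has washed into tissue.
    """

    n_clusters: int = 6
    amplitude: float = 200.0       # difference-signal units at zero delay
    decay_ms: float = 700.0
    extinction_ms: float = 1000.0
    slices: tuple = (0, 1, 2)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, truth values, noise and artifact description of the phantom."""

    shape: tuple = (32, 32, 12)
    voxel_mm: tuple = (3.0, 3.0, 6.0)
    outer_semiaxes: tuple = (13.0, 13.0, 5.2)   # voxels; GM shell outer surface
    inner_semiaxes: tuple = (7.5, 7.5, 3.0)     # voxels; WM core
    gm: TissueTruth = TissueTruth(cbf=45.0, att=700.0, tau=900.0, m0=1100.0)
    wm: TissueTruth = TissueTruth(cbf=27.0, att=800.0, tau=1000.0, m0=1000.0)
    noise_sd: float = 10.0                      # per-voxel, label and control
    rim_attenuation: float = 0.65               # M0 factor on the surface shell
    prob_smooth_sigma: float = 0.6              # voxels, for probability maps
    artifact: VesselArtifactSpec = field(default_factory=VesselArtifactSpec)
    seed: int = 0

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=seed)


@dataclass
class Phantom:
    """Built phantom: truth volumes, ROI mask and tissue probability maps."""

    labels: np.ndarray        # 0 background, 1 GM, 2 WM
    cbf: np.ndarray
    att: np.ndarray
    tau: np.ndarray
    m0: np.ndarray            # with boundary attenuation applied
    roi: np.ndarray           # "cerebellum" extent (GM ∪ WM support)
    gm_prob: np.ndarray
    wm_prob: np.ndarray
    spec: PhantomSpec

    @property
    def gm_mask(self) -> np.ndarray:
        return self.labels == 1

    @property
    def wm_mask(self) -> np.ndarray:
        return self.labels == 2


def _ellipsoid(shape, semiaxes) -> np.ndarray:
    center = (np.array(shape) - 1) / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2
             for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministically construct truth volumes and probability maps."""
    outer = _ellipsoid(spec.shape, spec.outer_semiaxes)
    inner = _ellipsoid(spec.shape, spec.inner_semiaxes)
    if not inner.any() or not (outer & ~inner).any():
        raise ValueError("degenerate phantom geometry: empty tissue class")
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[outer & ~inner] = 1   # GM shell
    labels[inner] = 2            # WM core

    def paint(attr: str) -> np.ndarray:
        vol = np.zeros(spec.shape, dtype=float)
        vol[labels == 1] = getattr(spec.gm, attr)
        vol[labels == 2] = getattr(spec.wm, attr)
        return vol

    m0 = paint("m0")
    # partial-volume rim: attenuate M0 on the outermost tissue shell
    interior = ndimage.binary_erosion(outer)
    rim = outer & ~interior
    m0[rim] *= spec.rim_attenuation

    gm_prob = ndimage.gaussian_filter((labels == 1).astype(float),
                                      spec.prob_smooth_sigma)
    wm_prob = ndimage.gaussian_filter((labels == 2).astype(float),
                                      spec.prob_smooth_sigma)
    np.clip(gm_prob, 0.0, 1.0, out=gm_prob)
    np.clip(wm_prob, 0.0, 1.0, out=wm_prob)

    return Phantom(labels=labels, cbf=paint("cbf"), att=paint("att"),
                   tau=paint("tau"), m0=m0, roi=outer, gm_prob=gm_prob,
                   wm_prob=wm_prob, spec=spec)


def delta_m_map(phantom: Phantom, acq: AcquisitionParams,
                q2tips: bool = True) -> np.ndarray:
    """Noise-free difference-signal map at each slice's effective TI2.

    With ``q2tips`` the saturation train truncates the labeled bolus at TI1,
    so the effective bolus duration is min(tau, TI1); the multi-TI2 ladder
    experiment runs with the train off (``q2tips=False``).
    """
    n_slices = phantom.labels.shape[2]
    t = (acq.ti2_base + np.arange(n_slices) * acq.slice_dt).reshape(1, 1, -1)
    tau_eff = np.minimum(phantom.tau, acq.ti1) if q2tips else phantom.tau
    f = phantom.cbf / CBF_UNIT_FACTOR
    m0b = phantom.m0 / acq.lambda_
    inflow = np.clip(t - phantom.att, 0.0, None)
    inflow = np.minimum(inflow, np.where(tau_eff > 0, tau_eff, np.inf))
    dm = 2.0 * acq.alpha * m0b * f * inflow * np.exp(-t / acq.t1b)
    dm[phantom.labels == 0] = 0.0
    return dm


def _artifact_support(phantom: Phantom, rng: np.random.Generator) -> np.ndarray:
    """Indicator map of vessel-cluster voxels (unit amplitude) in inferior slices."""
    art = phantom.spec.artifact
    support = np.zeros(phantom.labels.shape, dtype=float)
    cand = np.argwhere((phantom.labels > 0)
                       & np.isin(np.indices(phantom.labels.shape)[2],
                                 art.slices))
    if cand.size == 0 or art.n_clusters == 0:
        return support
    centers = cand[rng.choice(cand.shape[0], size=min(art.n_clusters,
                                                      cand.shape[0]),
                              replace=False)]
    for cx, cy, cz in centers:
        for dx, dy, dz in ((0, 0, 0), (1, 0, 0), (-1, 0, 0),
                           (0, 1, 0), (0, -1, 0)):
            x, y, z = cx + dx, cy + dy, cz + dz
            if (0 <= x < support.shape[0] and 0 <= y < support.shape[1]
                    and 0 <= z < support.shape[2]
                    and phantom.labels[x, y, z] > 0):
                support[x, y, z] = 1.0
    return support


def artifact_amplitude(spec: VesselArtifactSpec, delay_ms: float) -> float:
    """Hyperintensity amplitude at a post-labeling delay; zero at/after extinction."""
    if delay_ms >= spec.extinction_ms:
        return 0.0
    return spec.amplitude * float(np.exp(-delay_ms / spec.decay_ms))


def simulate_series(phantom: Phantom, acq: AcquisitionParams,
                    n_pairs: int = 90, noise_sd: float | None = None,
                    artifacts: bool = True, motion: dict | None = None,
                    q2tips: bool = True, order: str = "label-first",
                    ) -> tuple[AslSeries, MotionTrace, tuple]:
    """Simulate an alternating label/control series plus M0 images and trace.

    Control volumes are the proton-density baseline plus noise; label
    volumes subtract the kinetic-model difference signal (and any vascular
    hyperintensity at short post-labeling delay).  ``motion`` maps volume
    index -> 6 rigid parameters (tx, ty, tz mm, rx, ry, rz deg), applied to
    that volume and recorded in the returned ground-truth trace.
    """
    if order not in ("label-first", "control-first"):
        raise ValueError(f"unknown pair ordering {order!r}")
    if acq.ti2_base < acq.ti1:
        raise ValueError("schedule inconsistent: TI2 < TI1")
    spec = phantom.spec
    sd = spec.noise_sd if noise_sd is None else noise_sd
    ss = np.random.SeedSequence(spec.seed)
    rng_noise, rng_art, rng_m0 = (np.random.default_rng(c)
                                  for c in ss.spawn(3))

    dm = delta_m_map(phantom, acq, q2tips=q2tips)
    art_map = 0.0
    if artifacts and spec.artifact.n_clusters > 0:
        amp = artifact_amplitude(spec.artifact, acq.postlabeling_delay)
        if amp > 0.0:
            art_map = amp * _artifact_support(phantom, rng_art)

    control_clean = phantom.m0
    label_clean = control_clean - dm - art_map

    n_vol = 2 * n_pairs
    shape = phantom.labels.shape
    data = np.empty(shape + (n_vol,), dtype=float)
    tags = []
    for p in range(n_pairs):
        lab = label_clean + (rng_noise.normal(0.0, sd, shape) if sd else 0.0)
        con = control_clean + (rng_noise.normal(0.0, sd, shape) if sd else 0.0)
        i = 2 * p
        if order == "label-first":
            data[..., i], data[..., i + 1] = lab, con
            tags += [LABEL, CONTROL]
        else:
            data[..., i], data[..., i + 1] = con, lab
            tags += [CONTROL, LABEL]

    trace = np.zeros((n_vol, 6))
    if motion:
        for vi, params in motion.items():
            if not 0 <= vi < n_vol:
                raise ValueError(f"motion volume index {vi} out of range")
            trace[vi] = np.asarray(params, dtype=float)
            data[..., vi] = apply_rigid_motion(data[..., vi], trace[vi],
                                               spec.voxel_mm)

    m0_pre = phantom.m0 + (rng_m0.normal(0.0, sd, shape) if sd else 0.0)
    m0_post = phantom.m0 + (rng_m0.normal(0.0, sd, shape) if sd else 0.0)

    series = AslSeries(data, tags, acq, voxel_mm=spec.voxel_mm)
    return series, MotionTrace(trace), (m0_pre, m0_post)


def emulate_delay_sweep(phantom: Phantom, acq: AcquisitionParams,
                        delays, n_pairs: int = 30) -> dict:
    """One simulated series per post-labeling delay (TI2 = TI1 + delay).

    Vessel hyperintensity decays with delay and vanishes for delays at or
    beyond the artifact extinction delay, reproducing the short-delay
    intravascular contamination pattern used to select the operating delay.
    """
    out = {}
    for d in delays:
        if d <= 0:
            raise ValueError(f"post-labeling delays must be positive, got {d}")
        acq_d = acq.with_ti2(acq.ti1 + float(d))
        out[float(d)] = simulate_series(phantom, acq_d, n_pairs=n_pairs,
                                        artifacts=True)
    return out


def simulate_ladder_curves(truth: KineticParams, acq: AcquisitionParams,
                           ti2_values=None, n_curves: int = 1,
                           n_pairs: int = 30, n_voxels: int = 250,
                           voxel_noise_sd: float = 10.0,
                           seed: int = 0) -> list[RoiSignalCurve]:
    """ROI-level multi-TI2 curves with noise propagated from voxel level.

    Each curve samples the three-phase model at the TI2 ladder (default
    50..3300 ms in 300 ms steps, bolus untruncated — saturation train off)
    and adds Gaussian noise with the standard deviation of a mean over
    ``n_pairs`` pair-subtracted averages of ``n_voxels`` voxels:
    sigma_curve = voxel_noise_sd * sqrt(2) / sqrt(n_pairs * n_voxels).
    The default ``n_voxels`` matches the default phantom's grey-matter
    extent per imaging slice (~250 voxels; a two-slice pooled curve would
    double it).
    """
    if ti2_values is None:
        # 12-point ladder: 50 ms then 300..3300 ms in 300 ms steps
        ti2_values = np.r_[50.0, np.arange(300.0, 3301.0, 300.0)]
    ti2_values = np.asarray(ti2_values, dtype=float)
    rng = np.random.default_rng(seed)
    f = truth.cbf / CBF_UNIT_FACTOR
    inflow = np.clip(ti2_values - truth.att, 0.0, truth.tau)
    clean = 2.0 * acq.alpha * truth.m0b * f * inflow * np.exp(
        -ti2_values / acq.t1b)
    sigma = voxel_noise_sd * np.sqrt(2.0) / np.sqrt(n_pairs * n_voxels)
    curves = []
    for c in range(n_curves):
        noisy = clean + (rng.normal(0.0, sigma, clean.shape)
                         if sigma > 0 else 0.0)
        curves.append(RoiSignalCurve(ti2=ti2_values, dm=noisy,
                                     n_voxels=np.full(ti2_values.shape,
                                                      n_voxels),
                                     roi_id=f"sim-{c}"))
    return curves
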