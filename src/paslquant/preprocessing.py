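"""Label/control series screening, motion bookkeeping, and pairwise subtraction.

Motion *estimation* (rigid registration) is out of scope: a per-volume motion
trace (3 translations in mm, 3 rotations in degrees) is an input, produced by
an external registration tool on real data and by the simulator's ground
truth on synthetic data.  The rules applied here: volumes moving more than
1 mm / 1 deg are motion-corrected (trilinear resampling by the known inverse
transform), and label/control *pairs* containing a volume beyond 2 mm / 2 deg
are excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import ndimage

from .kinetic_model import AcquisitionParams

LABEL = "label"
CONTROL = "control"


class Decision(str, Enum):
    KEEP = "keep"
    CORRECT = "correct"
    EXCLUDE = "exclude"


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion: translations (mm) and rotations (deg).

    ``params`` has shape (n_volumes, 6) ordered (tx, ty, tz, rx, ry, rz).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must have shape (n_volumes, 6)")

    def __len__(self) -> int:
        return self.params.shape[0]


@dataclass
class AslSeries:
    """4D alternating label/control series with geometry and timing metadata."""

    data: np.ndarray                      # (x, y, slice, volume)
    volume_labels: Sequence[str]          # 'label' / 'control' per volume
    acq: AcquisitionParams
    voxel_mm: tuple = (3.0, 3.0, 6.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("series data must be 4D (x, y, slice, volume)")
        if len(self.volume_labels) != self.data.shape[3]:
            raise ValueError("one volume label per volume required")
        tags = set(self.volume_labels)
        if not tags <= {LABEL, CONTROL}:
            raise ValueError(f"unknown volume tags: {tags - {LABEL, CONTROL}}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def pairs(self) -> list[tuple[int, int]]:
        """Consecutive (label_index, control_index) pairs, any within-pair order."""
        if self.n_volumes % 2:
            raise ValueError("series must contain an even number of volumes")
        out = []
        for i in range(0, self.n_volumes, 2):
            a, b = self.volume_labels[i], self.volume_labels[i + 1]
            if {a, b} != {LABEL, CONTROL}:
                raise ValueError(f"volumes {i},{i+1} do not form a label/control pair")
            out.append((i, i + 1) if a == LABEL else (i + 1, i))
        return out


def screen_motion(trace: MotionTrace,
                  correct_mm: float = 1.0, correct_deg: float = 1.0,
                  exclude_mm: float = 2.0, exclude_deg: float = 2.0,
                  n_volumes: int | None = None) -> list[Decision]:
    """Per-volume keep/correct/exclude decision from motion magnitudes.

    Any axis translation beyond ``correct_mm`` or rotation beyond
    ``correct_deg`` triggers correction; beyond ``exclude_mm``/``exclude_deg``
    the volume is excluded.  Pair-level propagation is separate
    (:func:`pair_decisions`).
    """
    if n_volumes is not None and len(trace) != n_volumes:
        raise ValueError(
            f"motion trace has {len(trace)} records for {n_volumes} volumes"
        )
    trans = np.abs(trace.params[:, :3])
    rot = np.abs(trace.params[:, 3:])
    out = []
    for i in range(len(trace)):
        if trans[i].max() > exclude_mm or rot[i].max() > exclude_deg:
            out.append(Decision.EXCLUDE)
        elif trans[i].max() > correct_mm or rot[i].max() > correct_deg:
            out.append(Decision.CORRECT)
        else:
            out.append(Decision.KEEP)
    return out


def pair_decisions(decisions: Sequence[Decision],
                   pairs: Sequence[tuple[int, int]]) -> list[Decision]:
    """Promote per-volume decisions to pair level: exclusion removes the partner."""
    out = []
    for li, ci in pairs:
        d = {decisions[li], decisions[ci]}
        if Decision.EXCLUDE in d:
            out.append(Decision.EXCLUDE)
        elif Decision.CORRECT in d:
            out.append(Decision.CORRECT)
        else:
            out.append(Decision.KEEP)
    return out


def _rigid_matrix(params: np.ndarray, voxel_mm) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix (xyz Euler, degrees) and translation in voxel units."""
    tx, ty, tz, rx, ry, rz = params
    rx, ry, rz = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    t_vox = np.array([tx, ty, tz]) / np.asarray(voxel_mm, dtype=float)
    return R, t_vox


def apply_rigid_motion(volume: np.ndarray, params, voxel_mm=(3.0, 3.0, 6.0),
                       inverse: bool = False) -> np.ndarray:
    """Resample a 3D volume under a rigid transform (trilinear interpolation).

    Rotations are about the volume center.  ``inverse=True`` applies the
    inverse transform — used to *correct* a volume whose forward motion
    parameters are known.
    """
    params = np.asarray(params, dtype=float)
    if np.allclose(params, 0.0):
        return volume.copy()
    R, t_vox = _rigid_matrix(params, voxel_mm)
    center = (np.array(volume.shape) - 1) / 2.0
    if inverse:
        # output voxel x maps to input R x + t (undoing x -> R^-1 (x - t))
        matrix, offset = R, center - R @ center + t_vox
    else:
        Rinv = R.T
        matrix, offset = Rinv, center - Rinv @ center - Rinv @ t_vox
    return ndimage.affine_transform(volume, matrix, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def correct_motion(series: AslSeries, decisions: Sequence[Decision],
                   trace: MotionTrace) -> AslSeries:
    """Undo recorded motion on volumes flagged 'correct' (trilinear resampling)."""
    if len(trace) != series.n_volumes:
        raise ValueError("motion trace / series length mismatch")
    data = series.data.copy()
    for i, d in enumerate(decisions):
        if d is Decision.CORRECT:
            data[..., i] = apply_rigid_motion(
                series.data[..., i], trace.params[i], series.voxel_mm,
                inverse=True)
    return AslSeries(data, list(series.volume_labels), series.acq,
                     series.voxel_mm)


def pairwise_subtract(series: AslSeries,
                      decisions: Sequence[Decision] | None = None) -> np.ndarray:
    """Control − label difference series over surviving pairs.

    Returns a 4D array (x, y, slice, pair).  ``decisions`` are *pair-level*
    (see :func:`pair_decisions`); excluded pairs contribute no volume.
    """
    pairs = series.pairs()
    if decisions is None:
        decisions = [Decision.KEEP] * len(pairs)
    if len(decisions) != len(pairs):
        raise ValueError("one pair-level decision per pair required")
    kept = [(li, ci) for (li, ci), d in zip(pairs, decisions)
            if d is not Decision.EXCLUDE]
    if not kept:
        raise ValueError("no label/control pairs survive motion screening")
    diffs = [series.data[..., ci] - series.data[..., li] for li, ci in kept]
    return np.stack(diffs, axis=-1)


def mean_pwi(pwi_series: np.ndarray) -> np.ndarray:
    """Voxelwise mean of a perfusion-weighted (difference) series."""
    pwi_series = np.asarray(pwi_series, dtype=float)
    if pwi_series.ndim != 4 or pwi_series.shape[3] < 1:
        raise ValueError("need a 4D difference series with >= 1 volume")
    return pwi_series.mean(axis=3)


def mean_m0(m0_pre: np.ndarray, m0_post: np.ndarray) -> np.ndarray:
    """Average of the proton-density images acquired before and after the series."""
    m0_pre = np.asarray(m0_pre, dtype=float)
    m0_post = np.asarray(m0_post, dtype=float)
    if m0_pre.shape != m0_post.shape:
        raise ValueError(
            f"M0 geometry mismatch: {m0_pre.shape} vs {m0_post.shape}"
        )
    return 0.5 * (m0_pre + m0_post)
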