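"""Tissue-mask construction: probability thresholding, ROI constraint, rebinarization.

Tissue segmentation itself (probability-map estimation) is upstream; this
module turns grey- and white-matter probability maps plus an anatomical ROI
into disjoint binary masks on the ASL grid by the cascade: threshold at a
high probability (default 0.75), AND with the ROI, and — when interpolation
has left fractional values — conservatively rebinarize at a second cut
(default 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TissueMasks:
    """Disjoint binary GM/WM masks plus the thresholds that produced them."""

    gm: np.ndarray
    wm: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        self.gm = np.asarray(self.gm, dtype=bool)
        self.wm = np.asarray(self.wm, dtype=bool)
        if self.gm.shape != self.wm.shape:
            raise ValueError("GM and WM masks must share a grid")
        if np.any(self.gm & self.wm):
            raise ValueError("GM and WM masks must be disjoint")


def threshold_probability(prob_map: np.ndarray, p_thresh: float = 0.75) -> np.ndarray:
    """Binary mask of voxels whose tissue probability is >= ``p_thresh``."""
    if not 0.0 < p_thresh <= 1.0:
        raise ValueError(f"p_thresh must be in (0, 1], got {p_thresh}")
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.min() < 0.0 or prob_map.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    return prob_map >= p_thresh


def constrain_to_roi(mask: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Voxelwise AND of a tissue mask with an anatomical ROI mask."""
    mask = np.asarray(mask, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != roi_mask.shape:
        raise ValueError(
            f"grid mismatch: mask {mask.shape} vs ROI {roi_mask.shape}"
        )
    return mask & roi_mask


def rebinarize(values: np.ndarray, cut: float = 0.9) -> np.ndarray:
    """Conservatively rebinarize an interpolated (fractional) mask at ``cut``.

    Keeps voxels with value >= cut; the result is a subset of the input's
    support.  A mask that is already binary passes through unchanged for any
    cut in (0, 1].
    """
    if not 0.0 < cut <= 1.0:
        raise ValueError(f"cut must be in (0, 1], got {cut}")
    values = np.asarray(values, dtype=float)
    if values.min() < 0.0 or values.max() > 1.0:
        raise ValueError("mask values must lie in [0, 1]")
    return values >= cut


def build_tissue_masks(gm_prob: np.ndarray, wm_prob: np.ndarray,
                       roi_mask: np.ndarray, p_thresh: float = 0.75,
                       rebin_cut: float = 0.9) -> TissueMasks:
    """Full cascade to disjoint GM/WM masks constrained to the ROI.

    Voxels passing the probability threshold for *both* tissues are assigned
    to the tissue with the higher probability (tie -> GM), preserving
    disjointness.  Idempotent and antitone in both thresholds.
    """
    gm = constrain_to_roi(threshold_probability(gm_prob, p_thresh), roi_mask)
    wm = constrain_to_roi(threshold_probability(wm_prob, p_thresh), roi_mask)
    overlap = gm & wm
    if np.any(overlap):
        gm_wins = np.asarray(gm_prob) >= np.asarray(wm_prob)  # tie -> GM
        gm = gm & (~overlap | gm_wins)
        wm = wm & (~overlap | ~gm_wins)
    return TissueMasks(gm=gm, wm=wm,
                       provenance={"p_thresh": p_thresh,
                                   "rebin_cut": rebin_cut})
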