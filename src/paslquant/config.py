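"""Run configuration: acquisition constants, screening thresholds, paths, seed.

A single YAML/JSON file drives every CLI stage; the config hash is embedded
in output manifests so reruns are attributable.  Validation errors name the
offending field path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .kinetic_model import AcquisitionParams


@dataclass(frozen=True)
class Thresholds:
    """Screening and masking thresholds with their documented ranges."""

    motion_correct_mm: float = 1.0
    motion_correct_deg: float = 1.0
    motion_exclude_mm: float = 2.0
    motion_exclude_deg: float = 2.0
    prob_thresh: float = 0.75
    rebin_cut: float = 0.9
    trim_frac: float = 0.05
    m0_intensity_cut: float = 800.0

    def __post_init__(self) -> None:
        checks = [
            ("thresholds.motion_correct_mm", 0 < self.motion_correct_mm),
            ("thresholds.motion_correct_deg", 0 < self.motion_correct_deg),
            ("thresholds.motion_exclude_mm",
             self.motion_exclude_mm >= self.motion_correct_mm),
            ("thresholds.motion_exclude_deg",
             self.motion_exclude_deg >= self.motion_correct_deg),
            ("thresholds.prob_thresh", 0 < self.prob_thresh <= 1),
            ("thresholds.rebin_cut", 0 < self.rebin_cut <= 1),
            ("thresholds.trim_frac", 0 <= self.trim_frac < 0.5),
            ("thresholds.m0_intensity_cut", self.m0_intensity_cut >= 0),
        ]
        for path, ok in checks:
            if not ok:
                raise ValueError(f"invalid config value at {path}")


@dataclass(frozen=True)
class RunConfig:
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    paths: dict = field(default_factory=dict)
    seed: int = 0
    pair_order: str = "label-first"
    n_pairs: int = 90

    def __post_init__(self) -> None:
        if self.pair_order not in ("label-first", "control-first"):
            raise ValueError("invalid config value at pair_order")
        if self.n_pairs < 1:
            raise ValueError("invalid config value at n_pairs")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        acq = d.pop("acquisition", {})
        thr = d.pop("thresholds", {})
        try:
            return cls(acquisition=AcquisitionParams(**acq),
                       thresholds=Thresholds(**thr), **d)
        except TypeError as e:
            raise ValueError(f"invalid config structure: {e}") from None

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
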