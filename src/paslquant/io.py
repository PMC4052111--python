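"""NIfTI, motion-trace TSV and config file I/O."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preprocessing import MotionTrace

MOTION_COLUMNS = ["volume", "tx", "ty", "tz", "rx", "ry", "rz"]


def save_nifti(path, data: np.ndarray, voxel_mm=(3.0, 3.0, 6.0)) -> None:
    affine = np.diag(list(voxel_mm[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(voxel_mm[:3]) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    voxel_mm = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_mm


def save_mask(path, mask: np.ndarray, voxel_mm=(3.0, 3.0, 6.0)) -> None:
    save_nifti(path, np.asarray(mask, dtype=np.uint8), voxel_mm)


def save_motion_trace(path, trace: MotionTrace) -> None:
    df = pd.DataFrame(trace.params, columns=MOTION_COLUMNS[1:])
    df.insert(0, "volume", np.arange(len(trace)))
    df.to_csv(path, sep="\t", index=False)


def load_motion_trace(path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = set(MOTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"motion trace TSV missing columns: {sorted(missing)}")
    df = df.sort_values("volume")
    return MotionTrace(df[MOTION_COLUMNS[1:]].to_numpy(dtype=float))


def save_curve_tsv(path, curve) -> None:
    df = pd.DataFrame({"ti2_ms": curve.ti2, "dm": curve.dm,
                       "n_voxels": curve.n_voxels,
                       "roi": curve.roi_id,
                       "slice": [";".join(map(str, curve.slices))] * len(curve)})
    df.to_csv(path, sep="\t", index=False)


def load_curve_tsv(path):
    from .model_fitting import RoiSignalCurve
    df = pd.read_csv(path, sep="\t").sort_values("ti2_ms")
    roi_id = str(df["roi"].iloc[0]) if "roi" in df else "roi"
    return RoiSignalCurve(ti2=df["ti2_ms"].to_numpy(),
                          dm=df["dm"].to_numpy(),
                          n_voxels=df["n_voxels"].to_numpy(),
                          roi_id=roi_id)


def load_config_file(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
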