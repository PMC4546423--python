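"""NIfTI-1 and tabular I/O with JSON sidecars for units and timing."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

from .core import DiffusionPair, DynamicSeries, ParameterMap
from .errors import InputError


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _write_sidecar(path: Path, meta: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_sidecar(path: Path) -> dict:
    with open(_sidecar_path(path)) as fh:
        return json.load(fh)


def save_map(pmap: ParameterMap, path) -> None:
    """Write a parameter map (and its nil mask) as NIfTI plus sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(pmap.values.astype(np.float32), np.eye(4)), path)
    _write_sidecar(path, {"kind": pmap.kind, "units": pmap.units})
    nil_path = path.with_name(path.name.replace(".nii", "_nil.nii", 1))
    nib.save(nib.Nifti1Image(pmap.nil_mask.astype(np.uint8), np.eye(4)),
             nil_path)


def load_map(path) -> ParameterMap:
    path = Path(path)
    meta = _read_sidecar(path)
    values = np.asanyarray(nib.load(path).dataobj, dtype=float)
    nil_path = path.with_name(path.name.replace(".nii", "_nil.nii", 1))
    nil = (np.asanyarray(nib.load(nil_path).dataobj) > 0
           if nil_path.exists() else None)
    return ParameterMap(values, kind=meta["kind"], nil_mask=nil)


def save_series(series: DynamicSeries, path) -> None:
    """Write a 4D dynamic series as NIfTI plus timing sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(series.si.astype(np.float32), np.eye(4)), path)
    _write_sidecar(path, {"dt": series.dt, "n_baseline": series.n_baseline,
                          "te": series.te})


def load_series(path) -> DynamicSeries:
    path = Path(path)
    meta = _read_sidecar(path)
    si = np.asanyarray(nib.load(path).dataobj, dtype=float)
    return DynamicSeries(si, dt=meta["dt"], n_baseline=meta["n_baseline"],
                         te=meta.get("te"))


def save_dwi_pair(pair: DiffusionPair, path_s0, path_sb) -> None:
    for vol, path in ((pair.s0, Path(path_s0)), (pair.sb, Path(path_sb))):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)), path)
    _write_sidecar(Path(path_sb), {"b": pair.b})


def load_dwi_pair(path_s0, path_sb) -> DiffusionPair:
    meta = _read_sidecar(Path(path_sb))
    s0 = np.asanyarray(nib.load(path_s0).dataobj, dtype=float)
    sb = np.asanyarray(nib.load(path_sb).dataobj, dtype=float)
    return DiffusionPair(s0, sb, b=meta["b"])


def save_mask(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise InputError("masks must be binary")
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), Path(path))


def load_mask(path) -> np.ndarray:
    return np.asanyarray(nib.load(path).dataobj) > 0


def save_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
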