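"""NIfTI, YAML and JSON plumbing shared by the pipeline stages."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml


def affine_for(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_nifti(volume: np.ndarray, path: Path | str,
               voxel_size_mm: float = 1.0) -> Path:
    """Write a volume as NIfTI-1; 4D inputs keep their leading index last.

    Stacked series (echo or direction index on axis 0) are moved to the 4th
    NIfTI dimension.  Boolean masks are stored as uint8.
    """
    path = Path(path)
    arr = np.asarray(volume)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.float32)
    if arr.ndim == 4:
        arr = np.moveaxis(arr, 0, -1)
    img = nib.Nifti1Image(arr, affine_for(voxel_size_mm))
    path.parent.mkdir(parents=True, exist_ok=True)
    img.to_filename(str(path))
    return path


def load_nifti(path: Path | str, series: bool = False) -> np.ndarray:
    """Read a NIfTI volume; with ``series`` move the 4th dim back to axis 0."""
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if series:
        if arr.ndim != 4:
            raise ValueError(f"{path}: expected a 4D series")
        arr = np.moveaxis(arr, -1, 0)
    return arr


def sha256_of(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default)
                    + "\n")
    return path


def read_json(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_yaml(path: Path | str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path
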