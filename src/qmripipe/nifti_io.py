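"""NIfTI, TSV and YAML/JSON input-output with geometry checks.

Volumes are stored as NIfTI-1 float32 (labels as uint8/int16) with the voxel
size on the affine diagonal and the units recorded in the header description
field.  Volumes intended for voxel-wise combination must agree in shape and
affine; a mismatch is a hard error, never a silent resample.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "save_volume",
    "load_volume",
    "check_same_geometry",
    "save_table",
    "load_table",
    "save_yaml",
    "load_yaml",
    "save_json",
]


def _affine(voxel_size_mm) -> np.ndarray:
    voxel = np.broadcast_to(np.asarray(voxel_size_mm, dtype=np.float64), (3,))
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = voxel
    return affine


def save_volume(
    path: str | Path,
    data: np.ndarray,
    voxel_size_mm,
    units: str = "",
    dtype=np.float32,
) -> Path:
    """Write a 3D/4D volume as NIfTI-1; units go into the header description."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), _affine(voxel_size_mm))
    img.header["descrip"] = units.encode()[:79]
    for axis, size in enumerate(np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))):
        img.header["pixdim"][axis + 1] = size
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, str]:
    """Read a NIfTI volume; returns (data, voxel_size_mm, units)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    voxel = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    units = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="replace")
    return data, voxel, units


def check_same_geometry(path_a: str | Path, path_b: str | Path) -> None:
    """Raise if two volumes differ in grid shape or affine (voxel-wise ops)."""
    a, b = nib.load(str(path_a)), nib.load(str(path_b))
    if a.shape[:3] != b.shape[:3]:
        raise ValueError(f"grid mismatch: {a.shape[:3]} vs {b.shape[:3]} ({path_a} vs {path_b})")
    if not np.allclose(a.affine, b.affine, atol=1e-5):
        raise ValueError(f"affine mismatch between {path_a} and {path_b}")


def save_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_yaml(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
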