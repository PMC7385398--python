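"""NIfTI / TSV / JSON readers and writers for the pipeline's artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BoldRun, FCMatrix, VolumeMap

__all__ = [
    "write_volume",
    "read_volume",
    "write_bold",
    "read_bold",
    "write_table",
    "read_table",
    "write_fc_matrix",
    "read_fc_matrix",
    "write_json",
    "read_json",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_volume(path: str | Path, vmap: VolumeMap, dtype=np.float64) -> Path:
    """Write the values grid as NIfTI-1; the mask is a separate volume."""
    path = Path(path)
    img = nib.Nifti1Image(vmap.values.astype(dtype), _affine(vmap.voxel_size_mm))
    nib.save(img, str(path))
    return path


def read_volume(
    path: str | Path, mask: np.ndarray | None = None
) -> VolumeMap:
    """Load a 3D NIfTI as a VolumeMap; default mask is nonzero voxels."""
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    if values.ndim == 4 and values.shape[-1] == 1:
        values = values[..., 0]
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {values.shape}")
    voxel_size = float(img.header.get_zooms()[0])
    if mask is None:
        mask = values != 0
        if not mask.any():
            mask = np.ones(values.shape, dtype=bool)
    elif mask.shape != values.shape:
        raise ValueError(f"{path}: mask shape mismatch")
    return VolumeMap(values, mask, voxel_size)


def write_bold(path: str | Path, run: BoldRun, voxel_size_mm: float = 3.0) -> Path:
    """Write a 4D run; the repetition time is stored in the time zoom."""
    path = Path(path)
    img = nib.Nifti1Image(run.values.astype(np.float32), _affine(voxel_size_mm))
    img.header.set_zooms((voxel_size_mm,) * 3 + (run.tr_seconds,))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    return path


def read_bold(path: str | Path) -> BoldRun:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    if values.ndim != 4:
        raise ValueError(f"{path}: expected a 4D run, got shape {values.shape}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldRun(values, tr)


def write_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fc_matrix(path: str | Path, fc: FCMatrix) -> Path:
    """TSV with region labels as header and index."""
    df = pd.DataFrame(fc.z_values, index=fc.region_labels, columns=fc.region_labels)
    df.to_csv(path, sep="\t")
    return Path(path)


def read_fc_matrix(path: str | Path) -> FCMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [int(c) if str(c).lstrip("-").isdigit() else c for c in df.columns]
    return FCMatrix(df.to_numpy(dtype=float), labels)


def write_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
    return path


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
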