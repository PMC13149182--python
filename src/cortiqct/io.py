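"""NIfTI-1 and sidecar I/O.

Volumes are written as signed 16-bit HU with unit scale slope; masks as
unsigned 8-bit.  Every generated artifact gets a JSON sidecar echoing the
generation parameters.  Axis order inside the package is (slice, row, col);
on disk the array is stored as-is with the voxel spacing in the affine
diagonal, which round-trips through :func:`read_volume`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import VoxelVolume

__all__ = ["write_volume", "read_volume", "write_mask", "read_mask",
           "write_sidecar", "read_sidecar"]


def _affine(spacing) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dz, dy, dx, 1.0])


def write_volume(volume: VoxelVolume, path) -> Path:
    path = Path(path)
    data = np.round(volume.hu_grid).astype(np.int16)
    img = nib.Nifti1Image(data, _affine(volume.voxel_spacing))
    img.header.set_slope_inter(1.0, 0.0)
    nib.save(img, path)
    return path


def read_volume(path) -> VoxelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(data, spacing)


def write_mask(mask: np.ndarray, spacing, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing))
    nib.save(img, path)
    return path


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(bool)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_sidecar(params, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(params), indent=2, sort_keys=True) + "\n")
    return path


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
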