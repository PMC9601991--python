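"""Mask and configuration I/O.

Masks travel as NIfTI (spacing in the header, mm); tables as CSV; run
summaries as JSON; run configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import ConfigError, DataError
from .mask import VoxelMask

__all__ = ["read_mask", "write_mask", "read_config", "write_json"]


def write_mask(mask: VoxelMask, path: str | Path) -> Path:
    """Write a binary mask as NIfTI with voxel spacing in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*mask.spacing_mm, 1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> VoxelMask:
    """Read a NIfTI mask; nonzero voxels are foreground."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"mask file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # nibabel raises several format error types
        raise DataError(f"cannot read NIfTI mask {path}: {exc}") from exc
    if data.ndim != 3:
        raise DataError(f"mask {path} is {data.ndim}D; expected a 3D volume")
    return VoxelMask(data > 0, tuple(float(z) for z in zooms))


def read_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse YAML config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return path


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
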