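"""Voxel mask container.

A :class:`VoxelMask` is a 3D binary occupancy grid with anisotropic voxel
spacing in millimetres. Axis convention throughout the package:

* axis 0 (``x``): medial -> lateral
* axis 1 (``y``): anterior -> posterior (paracoronal slice-stack axis)
* axis 2 (``z``): inferior -> superior
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class VoxelMask:
    """Binary 3D segmentation mask with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        """Voxel-count volume in cm^3 (count x voxel volume)."""
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0

    def is_subset_of(self, other: "VoxelMask") -> bool:
        return bool(np.all(other.data[self.data]))

    def copy(self) -> "VoxelMask":
        return VoxelMask(self.data.copy(), self.spacing_mm, dict(self.meta))
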