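"""Voxel-grid containers shared across the pipeline.

A :class:`VoxelImage` is a 3-D scalar grid with isotropic-or-not voxel spacing
in millimetres, a role tag saying what the scalars mean (counts, activity,
density, dose-rate) and, where applicable, the acquisition time in hours post
administration. A :class:`VOIMask` is a binary grid on the same geometry with
an organ label. Masks must share the exact grid of the image they index; no
resampling is performed anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

ROLES = ("counts", "activity", "density", "dose-rate")

#: roles whose voxel values must be non-negative
_NONNEG_ROLES = ("counts", "activity", "density")


def _as_spacing(spacing) -> Tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(spacing, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3 or np.any(arr <= 0):
        raise ValueError(f"voxel spacing must be 1 or 3 positive values (mm), got {spacing!r}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class VoxelImage:
    """3-D scalar grid with voxel spacing (mm) and a role tag."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    role: str
    time_h: Optional[float] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        self.spacing = _as_spacing(self.spacing)
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role in _NONNEG_ROLES and np.any(self.data < 0):
            raise ValueError(f"{self.role} image contains negative voxels")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (spacing is in mm; 1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def with_data(self, data: np.ndarray, role: Optional[str] = None) -> "VoxelImage":
        return replace(self, data=data, role=role if role is not None else self.role)


@dataclass
class VOIMask:
    """Binary volume-of-interest mask aligned to a voxel grid."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    label: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.data.ndim}")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_ml

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def require_same_grid(mask: VOIMask, image: VoxelImage, what: str = "image") -> None:
    if not mask.same_grid(image):
        raise ValueError(
            f"grid mismatch between mask {mask.label!r} "
            f"(shape {mask.shape}, spacing {mask.spacing}) and {what} "
            f"(shape {image.shape}, spacing {image.spacing})"
        )
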