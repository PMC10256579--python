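"""Image quantification: counts-to-activity conversion, threshold
segmentation, and per-organ time-activity extraction by voxel summation.

All operations are pure reductions over aligned voxel grids; images and
masks must share the exact grid (no resampling). Externally produced organ
masks (e.g. outlines copied from CT) are accepted as-is; the fixed-fraction
threshold segmenter covers the SPECT-only sites where anatomical imaging is
unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .calibration import CalibrationFactor, RecoveryCurve, apply_recovery_correction
from .image import VoxelImage, VOIMask, require_same_grid

# re-exported container types live with their geometry logic
__all__ = [
    "VoxelImage",
    "VOIMask",
    "TimeActivitySeries",
    "counts_to_activity",
    "segment_threshold",
    "extract_time_activity",
]

#: 6-connectivity structure (faces only) for connected components
_STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class TimeActivitySeries:
    """Per-organ samples of (time, activity, VOI volume, VOI mass) plus the
    administered activity, the input to kinetic fitting."""

    organ: str
    times_h: np.ndarray
    activities_mbq: np.ndarray
    volumes_ml: np.ndarray
    masses_g: np.ndarray
    a0_mbq: float

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.activities_mbq = np.asarray(self.activities_mbq, dtype=float)
        self.volumes_ml = np.asarray(self.volumes_ml, dtype=float)
        self.masses_g = np.asarray(self.masses_g, dtype=float)
        n = self.times_h.size
        if not (self.activities_mbq.size == self.volumes_ml.size == self.masses_g.size == n):
            raise ValueError("all sample arrays must have equal length")
        if n and np.any(np.diff(self.times_h) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.activities_mbq < 0):
            raise ValueError("activities must be >= 0")
        if self.a0_mbq <= 0:
            raise ValueError("administered activity must be > 0")

    def __len__(self) -> int:
        return self.times_h.size


def counts_to_activity(image: VoxelImage, cf: CalibrationFactor) -> VoxelImage:
    """Convert a count-rate image (cps) to activity (MBq) with the system
    calibration factor; geometry and time tag are unchanged."""
    if image.role != "counts":
        raise ValueError(f"expected a counts image, got role {image.role!r}")
    return VoxelImage(
        image.data / cf.value, image.spacing, "activity", time_h=image.time_h
    )


def segment_threshold(
    image: VoxelImage,
    region: VOIMask,
    fraction: float = 0.35,
    label: str = "",
) -> VOIMask:
    """Fixed-fraction threshold segmentation within a search region.

    Keeps voxels >= fraction x (max value in region), then retains the
    largest 6-connected component; ties on component size break on the
    highest total intensity. The 0.35 default is the fixed 35% threshold
    used for SPECT-only salivary outlining in the multi-centre protocol.
    """
    if not (0 < fraction < 1):
        raise ValueError("threshold fraction must lie in (0, 1)")
    require_same_grid(region, image, what="image to segment")
    if region.voxel_count == 0:
        raise ValueError("search region is empty")
    vals = np.where(region.data, image.data, -np.inf)
    vmax = float(np.max(vals))
    if vmax <= 0:
        raise ValueError("nothing to segment: search region maximum is not positive")
    above = region.data & (image.data >= fraction * vmax)
    labeled, ncomp = ndimage.label(above, structure=_STRUCTURE_6)
    if ncomp == 0:
        raise ValueError("nothing to segment: no voxels above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, ncomp + 1))
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if best.size > 1:
        intensities = ndimage.sum_labels(image.data, labeled, index=best)
        best = best[np.argmax(intensities)]
    else:
        best = best[0]
    return VOIMask(labeled == best, image.spacing, label=label or region.label)


def extract_time_activity(
    images: Sequence[VoxelImage],
    mask: VOIMask,
    a0_mbq: float,
    density: Union[VoxelImage, float] = 1.0,
    recovery: Optional[RecoveryCurve] = None,
) -> TimeActivitySeries:
    """Sum the activity in a VOI at each time-point.

    Per time-point: activity = sum of voxel values inside the mask (optionally
    recovery-corrected using the VOI volume), volume = voxel count x voxel
    volume, mass = sum of density x voxel volume over the mask. ``density``
    may be a density image on the same grid or a uniform value in g/mL.
    """
    if len(images) < 1:
        raise ValueError("at least one activity image is required")
    for i, img in enumerate(images):
        if img.role != "activity":
            raise ValueError(f"image {i} (t={img.time_h}) has role {img.role!r}, expected 'activity'")
        require_same_grid(mask, img, what=f"activity image {i} (t={img.time_h} h)")
    if mask.voxel_count == 0:
        raise ValueError(f"mask {mask.label!r} is empty")

    vox_ml = mask.voxel_volume_ml
    volume_ml = mask.voxel_count * vox_ml
    if isinstance(density, VoxelImage):
        require_same_grid(mask, density, what="density image")
        mass_g = float(density.data[mask.data].sum() * vox_ml)
    else:
        mass_g = float(density) * volume_ml

    times, acts = [], []
    for img in images:
        a = float(img.data[mask.data].sum())
        if recovery is not None:
            a = apply_recovery_correction(a, volume_ml, recovery)
        times.append(img.time_h if img.time_h is not None else 0.0)
        acts.append(a)

    order = np.argsort(times)
    times = np.asarray(times)[order]
    acts = np.asarray(acts)[order]
    n = len(times)
    return TimeActivitySeries(
        organ=mask.label,
        times_h=times,
        activities_mbq=acts,
        volumes_ml=np.full(n, volume_ml),
        masses_g=np.full(n, mass_g),
        a0_mbq=a0_mbq,
    )
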