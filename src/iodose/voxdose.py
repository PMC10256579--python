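"""Voxel-level absorbed dose: S-value kernel convolution, mass-averaged VOI
dose rates, and their time integral.

The dose engine is charged-particle-only kernel convolution: the dose rate
at a target voxel is the activity map convolved with a voxel S-value kernel
(Gy per MBq·h for a source at a given offset, tabulated in water), scaled
per target voxel by reference/local density as a first-order heterogeneity
correction. The 1x1x1 local-deposition kernel — all charged-particle energy
absorbed in the source voxel — is the default for organs large relative to
the I-131 beta range, and is exact in the charged-particle-equilibrium
limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .config import REFERENCE_DENSITY_G_PER_ML, charged_particle_delta
from .image import VoxelImage, VOIMask, require_same_grid
from .kinetics import KineticFit, _fit_monoexp_points, LN2

_SPACING_RTOL = 0.01  # kernels are never resampled; spacing must match to 1%


@dataclass
class VoxelKernel:
    """Odd-sided 3-D array of voxel S-values (Gy per MBq·h), water medium.

    ``delta`` is the total energy emitted per unit cumulated activity in
    Gy·g/(MBq·h); energy closure requires sum(S) x reference voxel mass =
    delta, i.e. the kernel deposits exactly the emitted energy.
    """

    svalues: np.ndarray
    spacing_mm: Tuple[float, float, float]
    delta_gy_g_per_mbq_h: float
    medium: str = "water"
    reference_density_g_per_ml: float = REFERENCE_DENSITY_G_PER_ML

    def __post_init__(self):
        self.svalues = np.asarray(self.svalues, dtype=float)
        s = np.atleast_1d(np.asarray(self.spacing_mm, dtype=float))
        if s.size == 1:
            s = np.repeat(s, 3)
        self.spacing_mm = tuple(float(x) for x in s)
        if self.svalues.ndim != 3 or any(n % 2 == 0 for n in self.svalues.shape):
            raise ValueError("kernel must be a 3-D array with odd side lengths")
        if np.any(self.svalues < 0):
            raise ValueError("S-values must be >= 0")
        c = tuple(n // 2 for n in self.svalues.shape)
        if self.svalues[c] <= 0:
            raise ValueError("central S-value must be > 0")
        closure = self.svalues.sum() * self.reference_voxel_mass_g
        if not np.isclose(closure, self.delta_gy_g_per_mbq_h, rtol=1e-6):
            raise ValueError(
                f"energy closure violated: sum(S) x voxel mass = {closure:.6e} "
                f"but delta = {self.delta_gy_g_per_mbq_h:.6e} Gy·g/(MBq·h)"
            )

    @property
    def reference_voxel_mass_g(self) -> float:
        vol_ml = float(np.prod(self.spacing_mm)) / 1000.0
        return vol_ml * self.reference_density_g_per_ml


def local_deposition_kernel(
    spacing_mm: Union[float, Sequence[float]],
    delta_gy_g_per_mbq_h: Optional[float] = None,
) -> VoxelKernel:
    """1x1x1 kernel absorbing all charged-particle energy in the source
    voxel: S_000 = delta / (reference voxel mass)."""
    if delta_gy_g_per_mbq_h is None:
        delta_gy_g_per_mbq_h = charged_particle_delta()
    s = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if s.size == 1:
        s = np.repeat(s, 3)
    vox_mass = float(np.prod(s)) / 1000.0 * REFERENCE_DENSITY_G_PER_ML
    sval = np.full((1, 1, 1), delta_gy_g_per_mbq_h / vox_mass)
    return VoxelKernel(sval, tuple(s), delta_gy_g_per_mbq_h)


@dataclass
class DoseRecord:
    """Per-patient per-organ absorbed dose, the unit of cohort reporting."""

    patient_id: str
    centre: str
    organ: str
    dose_gy: float
    a0_mbq: float
    method: str  # kernel | local-deposition | whole-body
    flags: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.dose_gy < 0:
            raise ValueError("absorbed dose must be >= 0")
        if self.a0_mbq <= 0:
            raise ValueError("administered activity must be > 0")

    @property
    def dose_per_admin_mgy_per_mbq(self) -> float:
        """Dose per administered activity, mGy/MBq."""
        return self.dose_gy / self.a0_mbq * 1000.0


def dose_rate_map(
    activity: VoxelImage,
    density: VoxelImage,
    kernel: VoxelKernel,
) -> VoxelImage:
    """Dose-rate map (Gy/h) by S-value kernel convolution of the activity
    map, with per-target-voxel density scaling reference/local.

    Boundary handling is zero padding (activity outside the grid is zero).
    The kernel's declared spacing must match the image grid within 1%;
    kernels are never resampled.
    """
    if activity.role != "activity":
        raise ValueError(f"expected an activity image, got role {activity.role!r}")
    if density.role != "density":
        raise ValueError(f"expected a density image, got role {density.role!r}")
    if not activity.same_grid(density):
        raise ValueError("activity and density images are not on the same grid")
    rel = np.abs(np.asarray(kernel.spacing_mm) - np.asarray(activity.spacing)) / np.asarray(
        activity.spacing
    )
    if np.any(rel > _SPACING_RTOL):
        raise ValueError(
            f"kernel spacing {kernel.spacing_mm} mm does not match image spacing "
            f"{activity.spacing} mm within 1%; kernels are not resampled"
        )
    if np.any((activity.data > 0) & (density.data <= 0)):
        raise ValueError("density must be > 0 wherever activity is > 0")

    if kernel.svalues.shape == (1, 1, 1):
        rate = activity.data * float(kernel.svalues[0, 0, 0])
    else:
        rate = ndimage.convolve(activity.data, kernel.svalues, mode="constant", cval=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(
            density.data > 0, kernel.reference_density_g_per_ml / density.data, 0.0
        )
    return VoxelImage(rate * scale, activity.spacing, "dose-rate", time_h=activity.time_h)


def mass_averaged_dose_rate(
    rate: VoxelImage, density: VoxelImage, mask: VOIMask
) -> float:
    """Energy-deposition-weighted mean dose rate over a VOI: total deposited
    power divided by the VOI mass, Gy/h."""
    if rate.role != "dose-rate":
        raise ValueError(f"expected a dose-rate image, got role {rate.role!r}")
    require_same_grid(mask, rate, what="dose-rate image")
    require_same_grid(mask, density, what="density image")
    m = mask.data
    masses = density.data[m] * mask.voxel_volume_ml  # g per voxel
    total_mass = float(masses.sum())
    if total_mass <= 0:
        raise ValueError(f"VOI {mask.label!r} has zero mass")
    return float((rate.data[m] * masses).sum() / total_mass)


def integrate_dose_rate(
    samples: Sequence[Tuple[float, float]],
    half_life_h: Optional[float] = None,
) -> float:
    """Absorbed dose (Gy) by mono-exponential time-integration of
    mass-averaged dose-rate samples, 0 to infinity.

    With a single sample an effective half-life must be supplied (the
    single-time-point rule); with two or more the mono-exponential fitter is
    reused with dose-rate in place of activity. All-zero samples integrate
    to zero dose.
    """
    if len(samples) < 1:
        raise ValueError("at least one (time, dose-rate) sample is required")
    arr = np.asarray(samples, dtype=float)
    t, y = arr[:, 0], arr[:, 1]
    if np.any(y < 0):
        raise ValueError("dose rates must be >= 0")
    if np.all(y == 0):
        return 0.0
    pos = y > 0
    if pos.sum() == 1:
        if half_life_h is None:
            raise ValueError(
                "a single positive sample needs an assumed effective half-life"
            )
        lam = LN2 / half_life_h
        i = int(np.argmax(pos))
        return float(y[i] * np.exp(lam * t[i]) / lam)
    flags: List[str] = []
    d0, lam, _ = _fit_monoexp_points(t[pos], y[pos], flags)
    return float(d0 / lam)
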