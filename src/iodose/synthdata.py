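"""Synthetic data generation: digital phantoms, SPECT-like time series,
whole-body retention curves and calibration acquisitions.

The study's patient images are not public, so every pipeline input is
emulated here with known ground truth. The generator encodes the study
conditions the pipeline was designed for:

* organ kinetics are mono-exponential washout with organ-specific effective
  half-lives (instantaneous uptake at t=0), matching the fitting assumption
  of the dosimetry pipeline; a bi-exponential uptake-washout variant is
  available to probe model misfit;
* whole-body retention is a 1- or 2-component exponential normalised to the
  administered activity at t=0;
* imaging degradation is first-order: isotropic Gaussian blur stands in for
  system resolution (the mechanism behind the partial-volume effect) and
  Poisson noise for counting statistics;
* centres differ in imaging schedule (1-6 time-points between 6 and 168 h),
  retention-measurement window, and field of view (full vs head/neck-only).

Every generated dataset carries machine-readable ground truth (true t=0
activities, effective half-lives, TIAs, and local-deposition organ doses) so
downstream tests never re-derive truth by hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import (
    I131_PHYSICAL_HALF_LIFE_H,
    REFERENCE_DENSITY_G_PER_ML,
    charged_particle_delta,
)
from .image import VoxelImage, VOIMask

LN2 = float(np.log(2))

#: Segmentation vocabulary of the multi-centre protocol.
ORGAN_VOCABULARY = (
    "neck_uptake",
    "lung_left",
    "lung_right",
    "salivary_glands",
    "parotid",
    "submandibular",
    "bones",
    "liver",
    "kidney_left",
    "kidney_right",
    "spleen",
    "urinary_bladder",
    "l2_l4",
)

#: Organs outside a head/neck-only field of view (single-FOV centres cannot
#: quantify the abdomen).
ABDOMINAL_ORGANS = frozenset(
    {"liver", "kidney_left", "kidney_right", "spleen", "urinary_bladder", "l2_l4"}
)

FOV_PRESETS = ("full", "head-neck-only")


# ---------------------------------------------------------------------------
# specs


@dataclass
class OrganSpec:
    """One organ: a geometric primitive with uniform activity and density."""

    name: str
    primitive: str  # sphere | ellipsoid | box
    center_mm: Tuple[float, float, float]
    radii_mm: Tuple[float, float, float]  # half-extents for box
    concentration_mbq_per_ml: float
    half_life_h: float
    density_g_per_ml: float = 1.0
    #: optional uptake half-life; when set the organ follows
    #: A(t) ~ 2^(-t/T_eff) - 2^(-t/T_up) (uptake-washout misfit variant)
    uptake_half_life_h: Optional[float] = None

    def __post_init__(self):
        self.center_mm = tuple(float(c) for c in np.atleast_1d(self.center_mm))
        r = np.atleast_1d(np.asarray(self.radii_mm, dtype=float))
        if r.size == 1:
            r = np.repeat(r, 3)
        self.radii_mm = tuple(float(x) for x in r)
        if self.primitive not in ("sphere", "ellipsoid", "box"):
            raise ValueError(f"unknown primitive {self.primitive!r}")
        if any(x <= 0 for x in self.radii_mm):
            raise ValueError(f"organ {self.name!r}: all radii must be > 0")
        if self.concentration_mbq_per_ml < 0:
            raise ValueError(f"organ {self.name!r}: concentration must be >= 0")
        if not (0 < self.half_life_h <= I131_PHYSICAL_HALF_LIFE_H):
            raise ValueError(
                f"organ {self.name!r}: effective half-life must lie in "
                f"(0, {I131_PHYSICAL_HALF_LIFE_H}] h"
            )
        if self.density_g_per_ml <= 0:
            raise ValueError(f"organ {self.name!r}: density must be > 0")


@dataclass
class PhantomSpec:
    shape: Tuple[int, int, int]
    spacing_mm: Tuple[float, float, float]
    organs: List[OrganSpec]
    background_density_g_per_ml: float = 1.0
    fov: str = "full"

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        s = np.atleast_1d(np.asarray(self.spacing_mm, dtype=float))
        if s.size == 1:
            s = np.repeat(s, 3)
        self.spacing_mm = tuple(float(x) for x in s)
        if any(n <= 0 for n in self.shape) or any(x <= 0 for x in self.spacing_mm):
            raise ValueError("grid shape and spacing must be positive")
        if self.background_density_g_per_ml <= 0:
            raise ValueError("background density must be > 0")
        if self.fov not in FOV_PRESETS:
            raise ValueError(f"unknown FOV preset {self.fov!r}; expected one of {FOV_PRESETS}")


@dataclass
class AcquisitionSpec:
    """Imaging schedule and degradation model for a SPECT-like series."""

    times_h: Sequence[float]
    calibration_factor_cps_per_mbq: float = 5000.0
    blur_sigma_mm: float = 0.0
    noise: str = "none"  # none | poisson
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        if t.size < 1:
            raise ValueError("at least one time-point is required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time-points must be strictly increasing")
        if np.any(t < 0) or np.any(t > 360):
            raise ValueError("time-points must lie within [0, 360] h post administration")
        self.times_h = tuple(float(x) for x in t)
        if self.calibration_factor_cps_per_mbq <= 0:
            raise ValueError("calibration factor must be > 0")
        if self.blur_sigma_mm < 0:
            raise ValueError("blur sigma must be >= 0")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class RetentionSpec:
    """Whole-body retention model: 1-2 exponential components, normalised to
    the administered activity at t=0."""

    fractions: Sequence[float]
    half_lives_h: Sequence[float]
    times_h: Sequence[float]
    relative_noise: float = 0.0
    seed: int = 0
    mass_kg: float = 70.0
    administered_mbq: float = 3700.0
    stimulation: str = "rhTSH"  # rhTSH | THW

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        hl = np.asarray(self.half_lives_h, dtype=float)
        if f.size != hl.size or f.size not in (1, 2):
            raise ValueError("need 1 or 2 (fraction, half-life) components")
        if np.any(f <= 0):
            raise ValueError("component fractions must be positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1 (got {f.sum():.6g})")
        if np.any(hl <= 0) or np.any(hl > I131_PHYSICAL_HALF_LIFE_H):
            raise ValueError(
                f"half-lives must lie in (0, {I131_PHYSICAL_HALF_LIFE_H}] h"
            )
        t = np.asarray(self.times_h, dtype=float)
        if t.size < 1 or np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ValueError("measurement times must be non-negative and strictly increasing")
        if self.relative_noise < 0:
            raise ValueError("relative noise must be >= 0")
        if self.mass_kg <= 0 or self.administered_mbq <= 0:
            raise ValueError("patient mass and administered activity must be > 0")
        if self.stimulation not in ("rhTSH", "THW"):
            raise ValueError("stimulation must be 'rhTSH' or 'THW'")
        self.fractions = tuple(float(x) for x in f)
        self.half_lives_h = tuple(float(x) for x in hl)
        self.times_h = tuple(float(x) for x in t)

    @property
    def true_tiac_h(self) -> float:
        """Analytic TIAC of the retention model: sum f_i T_i / ln 2 (hours)."""
        return float(
            sum(f * hl for f, hl in zip(self.fractions, self.half_lives_h)) / LN2
        )


# ---------------------------------------------------------------------------
# phantom


@dataclass
class OrganTruth:
    activity0_mbq: float
    half_life_h: float
    mass_g: float
    volume_ml: float
    uptake_half_life_h: Optional[float] = None

    @property
    def tia_mbq_h(self) -> float:
        """Analytic time-integrated activity, 0 to infinity."""
        tia = self.activity0_mbq * self.half_life_h / LN2
        if self.uptake_half_life_h is not None:
            tia -= self.activity0_mbq * self.uptake_half_life_h / LN2
        return tia


@dataclass
class Phantom:
    density: VoxelImage
    masks: Dict[str, VOIMask]
    truth: Dict[str, OrganTruth]
    spec: PhantomSpec

    def activity_image(self, time_h: float) -> VoxelImage:
        """Noise-free, blur-free activity map at ``time_h`` (MBq per voxel)."""
        vol_ml = self.density.voxel_volume_ml
        grid = np.zeros(self.density.shape)
        for organ in self.spec.organs:
            if organ.name not in self.masks:
                continue
            conc = organ.concentration_mbq_per_ml * 2.0 ** (-time_h / organ.half_life_h)
            if organ.uptake_half_life_h is not None:
                conc -= organ.concentration_mbq_per_ml * 2.0 ** (
                    -time_h / organ.uptake_half_life_h
                )
            grid[self.masks[organ.name].data] = conc * vol_ml
        return VoxelImage(grid, self.density.spacing, "activity", time_h=time_h)

    def ground_truth_table(self) -> pd.DataFrame:
        """Per-organ truth: A(0), T_eff, TIA, mass, and the local-deposition
        absorbed dose (charged-particle energy absorbed where it is emitted)."""
        delta = charged_particle_delta()
        rows = []
        for name, tr in self.truth.items():
            dose = tr.tia_mbq_h * delta / tr.mass_g if tr.mass_g > 0 else 0.0
            rows.append(
                {
                    "organ": name,
                    "activity0_MBq": tr.activity0_mbq,
                    "half_life_h": tr.half_life_h,
                    "tia_MBq_h": tr.tia_mbq_h,
                    "volume_mL": tr.volume_ml,
                    "mass_g": tr.mass_g,
                    "local_deposition_dose_Gy": dose,
                }
            )
        return pd.DataFrame(rows)


def _primitive_mask(organ: OrganSpec, shape, spacing) -> np.ndarray:
    """Voxelize a primitive: a voxel belongs to it iff the voxel centre is
    inside. Voxel centre of index i lies at i * spacing (mm)."""
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    dx = gx - organ.center_mm[0]
    dy = gy - organ.center_mm[1]
    dz = gz - organ.center_mm[2]
    rx, ry, rz = organ.radii_mm
    if organ.primitive == "box":
        return (np.abs(dx) <= rx) & (np.abs(dy) <= ry) & (np.abs(dz) <= rz)
    # sphere is an ellipsoid with equal radii
    return (dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2 <= 1.0


def _check_inside_grid(organ: OrganSpec, shape, spacing) -> None:
    for ax in range(3):
        lo = organ.center_mm[ax] - organ.radii_mm[ax]
        hi = organ.center_mm[ax] + organ.radii_mm[ax]
        extent_lo = -0.5 * spacing[ax]
        extent_hi = (shape[ax] - 0.5) * spacing[ax]
        if lo < extent_lo or hi > extent_hi:
            raise ValueError(
                f"organ {organ.name!r} extends outside the grid along axis {ax} "
                f"([{lo:.1f}, {hi:.1f}] mm vs grid [{extent_lo:.1f}, {extent_hi:.1f}] mm)"
            )


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelize a phantom spec into a density image, per-organ VOI masks and
    ground truth (true activities at t=0 and effective half-lives).

    Raises if any organ lies outside the grid or two primitives overlap.
    Organs outside the FOV preset (abdomen for head/neck-only) are dropped
    from the mask map, emulating a restricted field of view.
    """
    shape, spacing = spec.shape, spec.spacing_mm
    density = np.full(shape, spec.background_density_g_per_ml, dtype=float)
    occupied = np.zeros(shape, dtype=bool)
    vol_ml = float(np.prod(spacing)) / 1000.0

    masks: Dict[str, VOIMask] = {}
    truth: Dict[str, OrganTruth] = {}
    for organ in spec.organs:
        _check_inside_grid(organ, shape, spacing)
        m = _primitive_mask(organ, shape, spacing)
        if np.any(m & occupied):
            raise ValueError(f"organ {organ.name!r} overlaps a previously placed organ")
        occupied |= m
        density[m] = organ.density_g_per_ml
        if spec.fov == "head-neck-only" and organ.name in ABDOMINAL_ORGANS:
            continue
        nvox = int(m.sum())
        masks[organ.name] = VOIMask(m, spacing, label=organ.name)
        truth[organ.name] = OrganTruth(
            activity0_mbq=organ.concentration_mbq_per_ml * nvox * vol_ml,
            half_life_h=organ.half_life_h,
            mass_g=organ.density_g_per_ml * nvox * vol_ml,
            volume_ml=nvox * vol_ml,
            uptake_half_life_h=organ.uptake_half_life_h,
        )

    return Phantom(
        density=VoxelImage(density, spacing, "density"),
        masks=masks,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# imaging


def _blur(grid: np.ndarray, sigma_mm: float, spacing) -> np.ndarray:
    if sigma_mm <= 0:
        return grid
    sigma_vox = [sigma_mm / s for s in spacing]
    # constant-zero boundary keeps the kernel normalised: total counts are
    # conserved for objects away from the grid edge
    return ndimage.gaussian_filter(grid, sigma=sigma_vox, mode="constant", cval=0.0)


def make_timeseries(phantom: Phantom, acq: AcquisitionSpec) -> List[VoxelImage]:
    """Simulate a SPECT-like count-rate series from a phantom.

    Per time-point: decay each organ's uniform concentration, blur with the
    system resolution kernel, convert to count-rate with the calibration
    factor, and (optionally) draw Poisson counting noise. Identical seeds
    give bit-identical images.
    """
    rng = np.random.default_rng(acq.seed)
    series: List[VoxelImage] = []
    for t in acq.times_h:
        activity = phantom.activity_image(t).data
        activity = _blur(activity, acq.blur_sigma_mm, phantom.density.spacing)
        counts = activity * acq.calibration_factor_cps_per_mbq
        if acq.noise == "poisson":
            counts = rng.poisson(counts).astype(float)
        series.append(VoxelImage(counts, phantom.density.spacing, "counts", time_h=t))
    return series


# ---------------------------------------------------------------------------
# whole-body retention


def make_retention_series(spec: RetentionSpec) -> Tuple[pd.DataFrame, Dict]:
    """Whole-body retention table (time_h, retained_MBq) plus patient metadata.

    The noise-free series lies exactly on the specified multi-exponential and
    equals the administered activity at t=0; multiplicative Gaussian noise of
    the given relative size is reproducible by seed.
    """
    t = np.asarray(spec.times_h, dtype=float)
    retained = spec.administered_mbq * sum(
        f * 2.0 ** (-t / hl) for f, hl in zip(spec.fractions, spec.half_lives_h)
    )
    if spec.relative_noise > 0:
        rng = np.random.default_rng(spec.seed)
        retained = retained * (1.0 + spec.relative_noise * rng.standard_normal(t.size))
        retained = np.clip(retained, 0.0, None)
    table = pd.DataFrame({"time_h": t, "retained_MBq": retained})
    meta = {
        "A0_MBq": spec.administered_mbq,
        "mass_kg": spec.mass_kg,
        "stimulation": spec.stimulation,
        "true_tiac_h": spec.true_tiac_h,
    }
    return table, meta


# ---------------------------------------------------------------------------
# calibration acquisitions


@dataclass
class CalibrationSet:
    """A system-sensitivity acquisition plus a sphere series for recovery
    coefficients, with ground truth attached."""

    calibration_image: VoxelImage  # counts, large uniform source
    calibration_true_mbq: float
    true_cf_cps_per_mbq: float
    #: rows: volume_mL (voxelized), measured_MBq (inside the true mask,
    #: after blur/noise), true_MBq
    sphere_table: pd.DataFrame


def make_calibration_set(
    true_activity_mbq: float,
    true_cf_cps_per_mbq: float,
    sphere_volumes_ml: Sequence[float],
    blur_sigma_mm: float = 0.0,
    seed: int = 0,
    spacing_mm: float = 2.0,
    noise: str = "none",
) -> CalibrationSet:
    """Emulate site set-up: a large uniform phantom of known activity for the
    system-volume calibration factor, and a series of spheres of decreasing
    volume for recovery coefficients.

    With blur the measured/true ratio decreases with sphere volume (the
    partial-volume effect); with sigma=0 all ratios are 1.
    """
    if true_activity_mbq <= 0:
        raise ValueError("true activity must be > 0")
    if true_cf_cps_per_mbq <= 0:
        raise ValueError("true calibration factor must be > 0")
    vols = np.asarray(sphere_volumes_ml, dtype=float)
    if vols.size < 1 or np.any(vols <= 0) or np.any(np.diff(vols) <= 0):
        raise ValueError("sphere volumes must be positive and strictly increasing")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")

    rng = np.random.default_rng(seed)

    # calibration source: a large box well away from the edge
    margin = max(4 * blur_sigma_mm, 8 * spacing_mm)
    half_mm = 40.0
    n = int(np.ceil(2 * (half_mm + margin) / spacing_mm)) + 1
    shape = (n, n, n)
    center = ((n - 1) / 2 * spacing_mm,) * 3
    box = OrganSpec(
        name="calibration_source",
        primitive="box",
        center_mm=center,
        radii_mm=(half_mm, half_mm, half_mm),
        concentration_mbq_per_ml=1.0,  # rescaled below
        half_life_h=I131_PHYSICAL_HALF_LIFE_H,
    )
    mask = _primitive_mask(box, shape, (spacing_mm,) * 3)
    vox_ml = spacing_mm**3 / 1000.0
    act = np.zeros(shape)
    act[mask] = true_activity_mbq / mask.sum()
    act = _blur(act, blur_sigma_mm, (spacing_mm,) * 3)
    counts = act * true_cf_cps_per_mbq
    if noise == "poisson":
        counts = rng.poisson(counts).astype(float)
    cal_img = VoxelImage(counts, (spacing_mm,) * 3, "counts")

    # sphere series, one grid per sphere, concentration 0.1 MBq/mL
    conc = 0.1
    rows = []
    for v in vols:
        r_mm = (3.0 * v * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        half = r_mm + max(4 * blur_sigma_mm, 6 * spacing_mm)
        ns = int(np.ceil(2 * half / spacing_mm)) + 1
        c = ((ns - 1) / 2 * spacing_mm,) * 3
        sphere = OrganSpec(
            name="sphere",
            primitive="sphere",
            center_mm=c,
            radii_mm=(r_mm, r_mm, r_mm),
            concentration_mbq_per_ml=conc,
            half_life_h=I131_PHYSICAL_HALF_LIFE_H,
        )
        smask = _primitive_mask(sphere, (ns,) * 3, (spacing_mm,) * 3)
        true_mbq = conc * smask.sum() * vox_ml
        s_act = np.zeros((ns,) * 3)
        s_act[smask] = conc * vox_ml
        s_act = _blur(s_act, blur_sigma_mm, (spacing_mm,) * 3)
        s_counts = s_act * true_cf_cps_per_mbq
        if noise == "poisson":
            s_counts = rng.poisson(s_counts).astype(float)
        measured_mbq = float(s_counts[smask].sum() / true_cf_cps_per_mbq)
        rows.append(
            {
                "volume_mL": smask.sum() * vox_ml,
                "measured_MBq": measured_mbq,
                "true_MBq": true_mbq,
            }
        )

    return CalibrationSet(
        calibration_image=cal_img,
        calibration_true_mbq=true_activity_mbq,
        true_cf_cps_per_mbq=true_cf_cps_per_mbq,
        sphere_table=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# a ready-made study-like phantom


def default_phantom_spec(
    fov: str = "full",
    spacing_mm: float = 4.0,
    activity_scale: float = 1.0,
) -> PhantomSpec:
    """A six-organ torso-like phantom at study-realistic activity levels.

    Concentrations approximate the early distribution after a 3.7-GBq
    administration (a few percent of the activity in the neck remnant and
    salivary glands, low diffuse organ uptake); effective half-lives span the
    short salivary washout (~9 h) to the slow neck-remnant clearance (~68 h).
    """
    organs = [
        OrganSpec("neck_uptake", "sphere", (80, 80, 40), (12, 12, 12), 0.50 * activity_scale, 68.0),
        OrganSpec("salivary_glands", "ellipsoid", (80, 40, 40), (18, 12, 12), 0.20 * activity_scale, 9.3),
        OrganSpec("lung_left", "ellipsoid", (52, 80, 104), (20, 24, 32), 0.02 * activity_scale, 20.0, density_g_per_ml=0.3),
        OrganSpec("lung_right", "ellipsoid", (108, 80, 104), (20, 24, 32), 0.02 * activity_scale, 20.0, density_g_per_ml=0.3),
        OrganSpec("liver", "ellipsoid", (56, 80, 180), (28, 24, 24), 0.015 * activity_scale, 24.0),
        OrganSpec("spleen", "ellipsoid", (116, 80, 184), (14, 12, 16), 0.01 * activity_scale, 18.0),
    ]
    n = int(168 / spacing_mm)
    nz = int(232 / spacing_mm)
    return PhantomSpec(
        shape=(n, n, nz),
        spacing_mm=(spacing_mm,) * 3,
        organs=organs,
        fov=fov,
    )
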