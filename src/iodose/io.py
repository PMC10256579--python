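"""File interfaces: NIfTI volumes with JSON sidecars, CSV tables, JSON
calibration objects, YAML specs, and CSV voxel-kernel files.

Conventions: images are NIfTI (.nii or .nii.gz) with voxel spacing in mm on
the affine diagonal; each image may carry a JSON sidecar
``{role, time_h, calibration_factor_cps_per_MBq, seed}``. Masks are integer
NIfTI volumes with a JSON label map. All times are hours post
administration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationFactor, RecoveryCurve
from .image import VoxelImage, VOIMask
from .quantify import TimeActivitySeries
from .synthdata import (
    AcquisitionSpec,
    OrganSpec,
    PhantomSpec,
    RetentionSpec,
)
from .voxdose import DoseRecord, VoxelKernel

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# NIfTI images


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_image(image: VoxelImage, path: PathLike, seed: Optional[int] = None,
               calibration_factor: Optional[float] = None) -> None:
    path = Path(path)
    affine = np.diag(list(image.spacing) + [1.0])
    nib.save(nib.Nifti1Image(image.data.astype(np.float64), affine), str(path))
    sidecar = {"role": image.role, "time_h": image.time_h}
    if calibration_factor is not None:
        sidecar["calibration_factor_cps_per_MBq"] = calibration_factor
    if seed is not None:
        sidecar["seed"] = seed
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def load_image(path: PathLike, role: Optional[str] = None,
               time_h: Optional[float] = None) -> VoxelImage:
    path = Path(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        role = role or meta.get("role")
        time_h = time_h if time_h is not None else meta.get("time_h")
    if role is None:
        raise ValueError(f"no role for image {path}: pass role= or provide a sidecar")
    return VoxelImage(np.asarray(img.dataobj, dtype=float), spacing, role, time_h=time_h)


def save_masks(masks: Dict[str, VOIMask], path: PathLike) -> None:
    """Write a label volume (1..n) with a JSON sidecar mapping label->organ."""
    path = Path(path)
    names = sorted(masks)
    first = masks[names[0]]
    label_img = np.zeros(first.shape, dtype=np.int16)
    mapping = {}
    for i, name in enumerate(names, start=1):
        label_img[masks[name].data] = i
        mapping[str(i)] = name
    affine = np.diag(list(first.spacing) + [1.0])
    nib.save(nib.Nifti1Image(label_img, affine), str(path))
    _sidecar_path(path).write_text(json.dumps({"labels": mapping}, indent=2))


def load_masks(path: PathLike) -> Dict[str, VOIMask]:
    path = Path(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj)
    mapping = json.loads(_sidecar_path(path).read_text())["labels"]
    return {
        organ: VOIMask(data == int(lbl), spacing, label=organ)
        for lbl, organ in mapping.items()
    }


# ---------------------------------------------------------------------------
# CSV tables


def save_time_activity(series_list: Sequence[TimeActivitySeries], path: PathLike) -> None:
    rows = []
    for s in series_list:
        for i in range(len(s)):
            rows.append(
                {
                    "organ": s.organ,
                    "time_h": s.times_h[i],
                    "activity_MBq": s.activities_mbq[i],
                    "volume_mL": s.volumes_ml[i],
                    "mass_g": s.masses_g[i],
                    "A0_MBq": s.a0_mbq,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_time_activity(path: PathLike) -> List[TimeActivitySeries]:
    df = pd.read_csv(path)
    out = []
    for organ, sub in df.groupby("organ", sort=True):
        sub = sub.sort_values("time_h")
        out.append(
            TimeActivitySeries(
                organ=str(organ),
                times_h=sub["time_h"].to_numpy(),
                activities_mbq=sub["activity_MBq"].to_numpy(),
                volumes_ml=sub["volume_mL"].to_numpy(),
                masses_g=sub["mass_g"].to_numpy(),
                a0_mbq=float(sub["A0_MBq"].iloc[0]),
            )
        )
    return out


def save_dose_records(records: Sequence[DoseRecord], path: PathLike) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "centre": r.centre,
            "organ": r.organ,
            "dose_Gy": r.dose_gy,
            "dose_mGy_per_MBq": r.dose_per_admin_mgy_per_mbq,
            "A0_MBq": r.a0_mbq,
            "method": r.method,
            "flags": ";".join(r.flags),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# calibration JSON


def save_calibration_factor(cf: CalibrationFactor, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(
            {"value_cps_per_MBq": cf.value, "system": cf.system,
             "reference_date": cf.reference_date},
            indent=2,
        )
    )


def load_calibration_factor(path: PathLike) -> CalibrationFactor:
    d = json.loads(Path(path).read_text())
    return CalibrationFactor(d["value_cps_per_MBq"], d.get("system", ""),
                             d.get("reference_date"))


def save_recovery_curve(curve: RecoveryCurve, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps({"volumes_mL": list(curve.volumes_ml), "rc": list(curve.rc)}, indent=2)
    )


def load_recovery_curve(path: PathLike) -> RecoveryCurve:
    d = json.loads(Path(path).read_text())
    return RecoveryCurve(tuple(d["volumes_mL"]), tuple(d["rc"]))


# ---------------------------------------------------------------------------
# voxel kernels (CSV with header rows)


def save_kernel(kernel: VoxelKernel, path: PathLike) -> None:
    """CSV format: comment header lines for spacing/medium/delta, then one
    row (di, dj, dk, S_Gy_per_MBq_h) per nonzero element."""
    lines = [
        f"# voxel_spacing_mm,{kernel.spacing_mm[0]},{kernel.spacing_mm[1]},{kernel.spacing_mm[2]}",
        f"# medium,{kernel.medium}",
        f"# delta_Gy_g_per_MBq_h,{kernel.delta_gy_g_per_mbq_h!r}",
        "di,dj,dk,S_Gy_per_MBq_h",
    ]
    c = tuple(n // 2 for n in kernel.svalues.shape)
    for idx in np.ndindex(kernel.svalues.shape):
        s = float(kernel.svalues[idx])
        if s != 0.0:
            lines.append(f"{idx[0]-c[0]},{idx[1]-c[1]},{idx[2]-c[2]},{s!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_kernel(path: PathLike) -> VoxelKernel:
    spacing = None
    medium = "water"
    delta = None
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = [p.strip() for p in line.lstrip("#").split(",")]
            if parts[0] == "voxel_spacing_mm":
                spacing = tuple(float(x) for x in parts[1:4])
            elif parts[0] == "medium":
                medium = parts[1]
            elif parts[0] == "delta_Gy_g_per_MBq_h":
                delta = float(parts[1])
        elif not line.startswith("di,"):
            di, dj, dk, s = line.split(",")
            rows.append((int(di), int(dj), int(dk), float(s)))
    if spacing is None or delta is None or not rows:
        raise ValueError(f"kernel file {path} is missing spacing, delta or data rows")
    arr = np.asarray([(r[0], r[1], r[2]) for r in rows])
    half = np.abs(arr).max(axis=0)
    shape = tuple(2 * h + 1 for h in half)
    sval = np.zeros(shape)
    for di, dj, dk, s in rows:
        sval[di + half[0], dj + half[1], dk + half[2]] = s
    return VoxelKernel(sval, spacing, delta, medium=medium)


# ---------------------------------------------------------------------------
# YAML specs


def load_phantom_spec(path: PathLike) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    organs = [OrganSpec(**o) for o in d.pop("organs")]
    return PhantomSpec(organs=organs, **d)


def load_acquisition_spec(path: PathLike) -> AcquisitionSpec:
    return AcquisitionSpec(**yaml.safe_load(Path(path).read_text()))


def load_retention_spec(path: PathLike) -> RetentionSpec:
    return RetentionSpec(**yaml.safe_load(Path(path).read_text()))
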