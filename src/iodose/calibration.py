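"""Imaging-system characterisation: system-volume calibration factors and
recovery-coefficient (partial-volume) curves.

A calibration factor converts measured count-rate to activity (cps/MBq).
Recovery coefficients RC(V) = measured/true for objects of known volume
correct the apparent activity loss of small objects caused by finite system
resolution. Physics demands RC be non-decreasing in volume and bounded by 1;
noisy sphere measurements are repaired by least-squares isotonic regression
and clipped into (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.isotonic import IsotonicRegression

_RC_FLOOR = 1e-6  # RC lives in (0, 1]; guard against a zero measurement


@dataclass
class CalibrationFactor:
    """System volume sensitivity in counts per second per MBq."""

    value: float
    system: str = ""
    reference_date: Optional[str] = None

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("calibration factor must be > 0")


@dataclass
class RecoveryCurve:
    """Monotone recovery coefficients sampled at known volumes.

    Between nodes RC is interpolated linearly in log10(volume) — the
    conventional axis for recovery curves; outside the node range it clamps
    to the nearest node.
    """

    volumes_ml: Tuple[float, ...]
    rc: Tuple[float, ...]

    def __post_init__(self):
        v = np.asarray(self.volumes_ml, dtype=float)
        r = np.asarray(self.rc, dtype=float)
        if v.size == 0 or v.size != r.size:
            raise ValueError("curve needs matching, non-empty volume and RC arrays")
        if np.any(v <= 0) or np.any(np.diff(v) <= 0):
            raise ValueError("volumes must be positive and strictly increasing")
        if np.any(r <= 0) or np.any(r > 1):
            raise ValueError("recovery coefficients must lie in (0, 1]")
        if np.any(np.diff(r) < 0):
            raise ValueError("recovery coefficients must be non-decreasing with volume")
        self.volumes_ml = tuple(float(x) for x in v)
        self.rc = tuple(float(x) for x in r)

    def __call__(self, volume_ml: float) -> float:
        if volume_ml <= 0:
            raise ValueError("volume must be > 0")
        logv = np.log10(self.volumes_ml)
        # np.interp clamps outside the node range
        return float(np.interp(np.log10(volume_ml), logv, self.rc))


def compute_calibration_factor(
    total_count_rate_cps: float,
    true_activity_mbq: float,
    system: str = "",
    reference_date: Optional[str] = None,
) -> CalibrationFactor:
    """System sensitivity from a known-activity acquisition.

    The caller supplies the activity already decay-corrected to the
    acquisition time; the factor is simply count-rate / activity.
    """
    if total_count_rate_cps <= 0 or true_activity_mbq <= 0:
        raise ValueError("count-rate and true activity must both be > 0")
    return CalibrationFactor(
        value=total_count_rate_cps / true_activity_mbq,
        system=system,
        reference_date=reference_date,
    )


def compute_recovery_curve(
    spheres: Sequence[Tuple[float, float, float]],
) -> RecoveryCurve:
    """Recovery curve from sphere measurements (volume_mL, measured, true).

    RC nodes are measured/true clipped into (0, 1]; any non-monotonicity from
    measurement noise is repaired by pool-adjacent-violators isotonic
    regression, which is the least-squares monotone fit.
    """
    if len(spheres) < 2:
        raise ValueError("at least two spheres are required")
    arr = np.asarray(spheres, dtype=float)
    order = np.argsort(arr[:, 0])
    arr = arr[order]
    vols = arr[:, 0]
    if np.any(np.diff(vols) == 0):
        raise ValueError("duplicate sphere volumes")
    if np.any(arr[:, 2] <= 0):
        raise ValueError("true activities must be > 0")
    rc = np.clip(arr[:, 1] / arr[:, 2], _RC_FLOOR, 1.0)
    iso = IsotonicRegression(y_min=_RC_FLOOR, y_max=1.0, increasing=True)
    rc = iso.fit_transform(np.log10(vols), rc)
    return RecoveryCurve(tuple(vols), tuple(rc))


def apply_recovery_correction(
    measured_mbq: float, volume_ml: float, curve: RecoveryCurve
) -> float:
    """Divide a measured VOI activity by RC(volume) to undo partial-volume
    loss. Since RC <= 1, correction never decreases the activity."""
    if volume_ml <= 0:
        raise ValueError("VOI volume must be > 0")
    return measured_mbq / curve(volume_ml)
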