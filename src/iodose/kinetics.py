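"""Kinetic fitting: time-integrated activity (TIA) and TIA coefficients
(TIAC) from organ time-activity data and whole-body retention curves.

Three estimation routes mirror multi-centre practice:

* ``fit_monoexp`` — mono-exponential washout fit for organs with two or more
  imaging time-points; two points use the closed form, more points use a
  log-linear fit refined by nonlinear least squares on the linear scale.
* ``tiac_single_timepoint`` — single-scan extrapolation with an assumed
  effective half-life, either a population value (68 h for the neck uptake,
  9.3 / 8.6 h for parotid / submandibular salivary glands) or the patient's
  own whole-body half-life from external counting.
* ``fit_multiexp_retention`` — 1- or 2-component exponential fit of
  whole-body retention, anchored to 100% of the administered activity at
  t=0, with automatic fallback to one component when a second is not
  supported by the data.

All integrations run from t=0 (administration, instantaneous uptake) to
infinity, so TIA = sum(amplitude_i / lambda_i). Effective decay constants
are clamped at the physical decay constant of I-131 — biological clearance
can only speed up washout — and clamped fits carry an audit flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .config import I131_PHYSICAL_HALF_LIFE_H, LAMBDA_PHYS_MIN
from .quantify import TimeActivitySeries

LN2 = float(np.log(2))

#: shipped population effective half-lives (hours) for single-time-point
#: dosimetry: neck uptake from an rhTSH-treated population, salivary glands
#: per gland type
DEFAULT_HALF_LIVES_H: Dict[str, float] = {
    "neck_uptake": 68.0,
    "parotid": 9.3,
    "submandibular": 8.6,
}

FLAG_HALF_LIFE_CLAMPED = "half_life_clamped"
FLAG_UPTAKE_SUSPECTED = "uptake_suspected"
FLAG_FALLBACK_MONO = "fallback_to_mono"


@dataclass
class ExpComponent:
    """One exponential term: amplitude x exp(-lambda t)."""

    amplitude: float  # MBq (or A0-normalised fraction x A0)
    decay_constant_per_h: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.decay_constant_per_h <= 0:
            raise ValueError("decay constant must be > 0")

    @property
    def half_life_h(self) -> float:
        return LN2 / self.decay_constant_per_h


@dataclass
class KineticFit:
    """Fitted exponential model with closed-form TIA and TIAC."""

    components: List[ExpComponent]
    a0_mbq: Optional[float] = None  # administered activity for TIAC
    rss: float = 0.0
    n_points: int = 0
    flags: List[str] = field(default_factory=list)

    @property
    def tia_mbq_h(self) -> float:
        return float(sum(c.amplitude / c.decay_constant_per_h for c in self.components))

    @property
    def tiac_h(self) -> Optional[float]:
        if self.a0_mbq is None:
            return None
        return self.tia_mbq_h / self.a0_mbq

    @property
    def t_eff_h(self) -> Optional[float]:
        """Effective half-life; defined for mono-exponential fits only."""
        if len(self.components) != 1:
            return None
        return self.components[0].half_life_h

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum(
            c.amplitude * np.exp(-c.decay_constant_per_h * t) for c in self.components
        )


def _clamp_lambda(lam: float, flags: List[str]) -> float:
    if lam < LAMBDA_PHYS_MIN:
        if FLAG_HALF_LIFE_CLAMPED not in flags:
            flags.append(FLAG_HALF_LIFE_CLAMPED)
        return LAMBDA_PHYS_MIN
    return lam


def _fit_monoexp_points(
    t: np.ndarray, y: np.ndarray, flags: List[str]
) -> Tuple[float, float, float]:
    """Mono-exponential fit of positive samples; returns (A0, lambda, RSS).

    Two points: exact closed form. More: activity-weighted least squares of
    log(y) on t (down-weights the late, noisier tail of the log transform),
    refined by unweighted nonlinear least squares on the linear scale.
    """
    if t.size == 2:
        lam = float(np.log(y[0] / y[1]) / (t[1] - t[0]))
        lam = _clamp_lambda(lam, flags)
        a0 = float(y[0] * np.exp(lam * t[0]))
        rss = float(np.sum((a0 * np.exp(-lam * t) - y) ** 2))
        return a0, lam, rss

    scale = float(y.max())  # normalise so the solve is scale-equivariant
    ys = y / scale
    w = ys / ys.sum()
    coeffs = np.polyfit(t, np.log(ys), 1, w=np.sqrt(w))
    lam0 = max(-float(coeffs[0]), 1e-6)
    a00 = float(np.exp(coeffs[1]))

    def resid(p):
        return p[0] * np.exp(-p[1] * t) - ys

    sol = least_squares(
        resid,
        x0=[a00, lam0],
        bounds=([0.0, 1e-9], [np.inf, np.inf]),
        method="trf",
    )
    a0, lam = float(sol.x[0]), float(sol.x[1])
    if lam < LAMBDA_PHYS_MIN:
        lam = _clamp_lambda(lam, flags)
        # re-solve the amplitude at the clamped decay constant (linear LS)
        e = np.exp(-lam * t)
        a0 = float((e @ ys) / (e @ e))
    a0 *= scale
    rss = float(np.sum((a0 * np.exp(-lam * t) - y) ** 2))
    return a0, lam, rss


def fit_monoexp(series: TimeActivitySeries) -> KineticFit:
    """Mono-exponential fit of an organ time-activity series.

    Needs at least two samples with positive activity; single-scan patients
    should use :func:`tiac_single_timepoint` instead. A series that does not
    decrease over a >24 h span is returned flagged (uptake phase suspected)
    rather than rejected.
    """
    pos = series.activities_mbq > 0
    t = series.times_h[pos]
    y = series.activities_mbq[pos]
    if t.size < 2:
        raise ValueError(
            f"organ {series.organ!r}: fewer than 2 positive samples; "
            "use tiac_single_timepoint for single-scan data"
        )
    flags: List[str] = []
    if np.all(np.diff(y) >= 0) and (t[-1] - t[0]) > 24.0:
        flags.append(FLAG_UPTAKE_SUSPECTED)
    a0, lam, rss = _fit_monoexp_points(t, y, flags)
    return KineticFit(
        components=[ExpComponent(a0, lam)],
        a0_mbq=series.a0_mbq,
        rss=rss,
        n_points=int(t.size),
        flags=flags,
    )


def tiac_single_timepoint(
    activity_mbq: float,
    time_h: float,
    organ: str,
    a0_mbq: float,
    defaults: Optional[Dict[str, float]] = None,
    half_life_h: Optional[float] = None,
) -> KineticFit:
    """Single-scan TIAC with an assumed effective half-life.

    The half-life comes from ``half_life_h`` (e.g. the patient's own fitted
    whole-body half-life) or from the organ's entry in ``defaults``
    (population values for the neck uptake and salivary glands). The
    activity is extrapolated back to t=0 along the assumed exponential and
    integrated to infinity: TIA = A(t1) e^{lambda t1} / lambda.
    """
    if time_h <= 0:
        raise ValueError("the scan time must be > 0 h post administration")
    if half_life_h is None:
        table = DEFAULT_HALF_LIVES_H if defaults is None else defaults
        if organ not in table:
            raise ValueError(
                f"no assumed effective half-life for organ {organ!r}: pass "
                "half_life_h explicitly (e.g. the patient's whole-body half-life)"
            )
        half_life_h = table[organ]
    if not (0 < half_life_h <= I131_PHYSICAL_HALF_LIFE_H):
        raise ValueError(
            f"assumed half-life must lie in (0, {I131_PHYSICAL_HALF_LIFE_H}] h"
        )
    lam = LN2 / half_life_h
    a0_extrap = activity_mbq * np.exp(lam * time_h)
    return KineticFit(
        components=[ExpComponent(float(a0_extrap), lam)],
        a0_mbq=a0_mbq,
        rss=0.0,
        n_points=1,
    )


# ---------------------------------------------------------------------------
# whole-body retention fitting

#: deterministic multi-start grid, expressed as half-lives in hours
_START_HALF_LIVES_H = (2.0, 8.0, 24.0, 96.0)
_LAMBDA_LO = LAMBDA_PHYS_MIN
_LAMBDA_HI = LN2 / 0.5  # nothing clears with an effective half-life under 30 min


def _fit_retention_1(t, y, a0):
    """Best 1-component fit with the amplitude pinned to A0."""
    def resid(p):
        return a0 * np.exp(-p[0] * t) - y

    best = None
    for hl in _START_HALF_LIVES_H:
        sol = least_squares(
            resid, x0=[LN2 / hl], bounds=([_LAMBDA_LO], [_LAMBDA_HI]), method="trf"
        )
        if best is None or sol.cost < best.cost:
            best = sol
    lam = float(best.x[0])
    rss = float(2 * best.cost)
    return [ExpComponent(a0, lam)], rss


def _fit_retention_2(t, y, a0):
    """Best 2-component fit with amplitudes >= 0 summing to A0.

    Parameterised as (f, lambda_fast, lambda_slow) with f in [0, 1] the fast
    fraction; started from a deterministic grid of half-life pairs.
    """
    def resid(p):
        f, l1, l2 = p
        return a0 * (f * np.exp(-l1 * t) + (1 - f) * np.exp(-l2 * t)) - y

    best = None
    for hl_fast, hl_slow in itertools.combinations(_START_HALF_LIVES_H, 2):
        for f0 in (0.3, 0.7):
            sol = least_squares(
                resid,
                x0=[f0, LN2 / hl_fast, LN2 / hl_slow],
                bounds=([0.0, _LAMBDA_LO, _LAMBDA_LO], [1.0, _LAMBDA_HI, _LAMBDA_HI]),
                method="trf",
            )
            if best is None or sol.cost < best.cost:
                best = sol
    f, l1, l2 = (float(v) for v in best.x)
    comps = [ExpComponent(a0 * f, l1), ExpComponent(a0 * (1 - f), l2)]
    comps.sort(key=lambda c: -c.decay_constant_per_h)  # faster component first
    rss = float(2 * best.cost)
    return comps, rss


def fit_multiexp_retention(
    times_h: Sequence[float],
    retained_mbq: Sequence[float],
    a0_mbq: Optional[float] = None,
    n_components: int = 2,
) -> KineticFit:
    """Multi-exponential fit of whole-body retention measurements.

    The model is anchored to retention = A0 at administration (amplitudes
    are non-negative and sum to A0). If A0 is not given, the first
    measurement must lie within 4 h of administration and is used as the
    anchor. A 2-component fit falls back to 1 component when there are fewer
    than 4 points or when the extra component does not reduce the residual
    sum of squares by at least 5%; the fit is flagged accordingly.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(retained_mbq, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if t.size < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} measurements for a "
            f"{n_components}-component fit"
        )
    if np.all(y == 0):
        raise ValueError("retention is zero everywhere; nothing to fit")
    if a0_mbq is None:
        if t[0] > 4.0:
            raise ValueError(
                "first measurement is later than 4 h post administration; "
                "pass a0_mbq as an explicit t=0 anchor"
            )
        a0_mbq = float(y[0])
    if a0_mbq <= 0:
        raise ValueError("administered activity must be > 0")

    flags: List[str] = []
    comps1, rss1 = _fit_retention_1(t, y, a0_mbq)
    if n_components == 1:
        comps, rss = comps1, rss1
    else:
        comps2, rss2 = _fit_retention_2(t, y, a0_mbq)
        # a numerically perfect 1-component fit cannot be improved by 5%
        perfect1 = rss1 <= 1e-18 * float(np.sum(y**2))
        use_two = t.size >= 4 and not perfect1 and rss2 <= 0.95 * rss1
        if use_two:
            comps, rss = comps2, rss2
        else:
            comps, rss = comps1, rss1
            flags.append(FLAG_FALLBACK_MONO)

    return KineticFit(
        components=comps,
        a0_mbq=a0_mbq,
        rss=rss,
        n_points=int(t.size),
        flags=flags,
    )
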