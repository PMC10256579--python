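"""Cohort-level reporting: median (range) absorbed-dose summaries per organ
and centre, and exploratory Mann-Whitney comparisons between activity and
stimulation groups.

Organs outside a patient's field of view are missing values, never zeros;
group summaries report the number of contributing patients. The
Mann-Whitney test uses midranks for ties with an exact permutation p-value
for small groups and a tie-corrected, continuity-corrected normal
approximation otherwise — small multi-centre cohorts sit squarely in the
exact regime.
"""

from __future__ import annotations

import itertools
import logging
from math import comb
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .voxdose import DoseRecord
from .wbdose import Patient

logger = logging.getLogger(__name__)

#: largest smaller-group size for which the exact permutation p is used
EXACT_N_MAX = 8
#: cap on the number of arrangements enumerated exactly
EXACT_ARRANGEMENTS_MAX = 100_000


def records_to_frame(records: Iterable[DoseRecord], patients: Iterable[Patient]) -> pd.DataFrame:
    """Join dose records to patient metadata; one row per (patient, organ).

    Every record must resolve to exactly one patient. The joined frame is the
    CohortTable all reporting operates on.
    """
    pat = {p.patient_id: p for p in patients}
    rows = []
    for r in records:
        if r.patient_id not in pat:
            raise ValueError(f"dose record for unknown patient {r.patient_id!r}")
        p = pat[r.patient_id]
        rows.append(
            {
                "patient_id": r.patient_id,
                "centre": r.centre or p.centre,
                "organ": r.organ,
                "dose_Gy": r.dose_gy,
                "dose_mGy_per_MBq": r.dose_per_admin_mgy_per_mbq,
                "method": r.method,
                "mass_kg": p.mass_kg,
                "A0_MBq": p.administered_mbq,
                "stimulation": p.stimulation,
                "nominal_activity_GBq": p.nominal_activity_gbq,
            }
        )
    return pd.DataFrame(rows)


def summarize(
    table: pd.DataFrame,
    keys: Sequence[str] = ("organ", "centre"),
    value: str = "dose_mGy_per_MBq",
) -> pd.DataFrame:
    """Median (range) and n per group, excluding missing values.

    The median is the midpoint of the two central values for even n; empty
    groups are omitted with a logged notice.
    """
    out = []
    for group, sub in table.groupby(list(keys), dropna=False, sort=True):
        vals = sub[value].dropna().to_numpy()
        if vals.size == 0:
            logger.info("group %s has no non-missing %s values; omitted", group, value)
            continue
        if not isinstance(group, tuple):
            group = (group,)
        row = dict(zip(keys, group))
        row.update(
            {
                "median": float(np.median(vals)),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n": int(vals.size),
            }
        )
        out.append(row)
    return pd.DataFrame(out)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of group A via midranks of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks for ties
    ra = ranks[: a.size].sum()
    return float(ra - a.size * (a.size + 1) / 2.0)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U of group A, p).

    Ties are handled with midranks. When the smaller group has at most
    ``EXACT_N_MAX`` observations and the number of arrangements is at most
    ``EXACT_ARRANGEMENTS_MAX``, the p-value is the exact permutation
    probability of a U at least as far from its null mean as observed;
    otherwise a normal approximation with tie-corrected variance and a
    continuity correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(a, b)
    na, nb = a.size, b.size
    mu = na * nb / 2.0

    if min(na, nb) <= EXACT_N_MAX and comb(na + nb, na) <= EXACT_ARRANGEMENTS_MAX:
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        offset = na * (na + 1) / 2.0
        dev = abs(u - mu) - 1e-12  # guard against FP noise at the centre
        count = 0
        total = 0
        for idx in itertools.combinations(range(na + nb), na):
            u_perm = ranks[list(idx)].sum() - offset
            if abs(u_perm - mu) >= dev:
                count += 1
            total += 1
        p = count / total
    else:
        n = na + nb
        _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = na * nb / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return u, 1.0
        # continuity correction shrinks |U - mu| by 0.5
        z = (abs(u - mu) - 0.5) / np.sqrt(var)
        z = max(z, 0.0)
        p = float(min(1.0, 2.0 * norm.sf(z)))
    return u, max(p, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# report generation


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def make_report(
    records: Iterable[DoseRecord],
    patients: Iterable[Patient],
) -> str:
    """Markdown cohort report: per-organ per-centre median (range) of doses
    per administered activity (mGy/MBq, printed to 2 decimals), plus
    exploratory whole-body group comparisons (activity level, stimulation)
    with two-sided Mann-Whitney p-values."""
    table = records_to_frame(records, patients)
    lines: List[str] = []
    lines.append("# Cohort dose report")
    lines.append("")
    lines.append(f"Patients: {table['patient_id'].nunique()}")
    lines.append("")
    lines.append("## Median (range) of absorbed doses per administered activity (mGy/MBq)")
    lines.append("")
    centres = sorted(table["centre"].unique())
    header = "| Organ | " + " | ".join(f"Centre {c}" for c in centres) + " |"
    lines.append(header)
    lines.append("|" + "---|" * (len(centres) + 1))
    summ = summarize(table, keys=("organ", "centre"))
    for organ in sorted(table["organ"].unique()):
        cells = []
        for c in centres:
            row = summ[(summ["organ"] == organ) & (summ["centre"] == c)]
            if row.empty:
                cells.append("-")
            else:
                r = row.iloc[0]
                cells.append(
                    f"{_fmt(r['median'])} ({_fmt(r['min'])}-{_fmt(r['max'])}) n={int(r['n'])}"
                )
        lines.append(f"| {organ} | " + " | ".join(cells) + " |")
    lines.append("")

    wb = table[table["organ"] == "whole_body"]
    if not wb.empty:
        lines.append("## Whole-body group comparisons (exploratory, two-sided)")
        lines.append("")
        groups = wb.dropna(subset=["nominal_activity_GBq"]).groupby("nominal_activity_GBq")
        levels = sorted(g for g, sub in groups if len(sub) > 0)
        if len(levels) >= 2:
            lo, hi = levels[0], levels[-1]
            va = wb[wb["nominal_activity_GBq"] == lo]["dose_mGy_per_MBq"].to_numpy()
            vb = wb[wb["nominal_activity_GBq"] == hi]["dose_mGy_per_MBq"].to_numpy()
            u, p = mann_whitney(va, vb)
            lines.append(
                f"- {lo} vs {hi} GBq (per-MBq whole-body dose): "
                f"U = {u:.1f}, p = {p:.3f}"
            )
        for stim_pair in [("rhTSH", "THW")]:
            va = wb[wb["stimulation"] == stim_pair[0]]["dose_mGy_per_MBq"].to_numpy()
            vb = wb[wb["stimulation"] == stim_pair[1]]["dose_mGy_per_MBq"].to_numpy()
            if va.size and vb.size:
                u, p = mann_whitney(va, vb)
                lines.append(
                    f"- {stim_pair[0]} vs {stim_pair[1]} (per-MBq whole-body dose): "
                    f"U = {u:.1f}, p = {p:.3f}"
                )
        lines.append("")
    return "\n".join(lines)
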