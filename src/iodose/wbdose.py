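"""Whole-body absorbed dose via the MIRD formalism with a mass-adjusted
whole-body self-irradiation S-factor.

The whole-body dose D = TIA x S_WB(m_p), with the empirical mass scaling

    S_WB(m_p) = 1.34e-4 x m_p^(-0.921)  Gy MBq^-1 h^-1,

m_p the patient's weight in kg. The whole-body dose is frequently used in
radioiodine therapy as a surrogate for the absorbed dose to the bone marrow
(the surrogate relationship is documentation, not computation). Because both
TIA and the administered activity scale linearly with the administration,
the dose per administered activity (mGy/MBq) is invariant under rescaling
the administration — which is why per-MBq whole-body doses are comparable
across fixed-activity groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .kinetics import KineticFit
from .voxdose import DoseRecord

S_WB_COEFFICIENT = 1.34e-4  # Gy MBq^-1 h^-1 at 1 kg
S_WB_EXPONENT = -0.921


@dataclass
class Patient:
    """Per-patient metadata joined to dose records at cohort level."""

    patient_id: str
    mass_kg: float
    administered_mbq: float
    stimulation: str  # rhTSH | THW
    centre: str = ""
    nominal_activity_gbq: Optional[float] = None  # 1.1 | 2.5 | 3.7

    def __post_init__(self):
        if self.mass_kg <= 0:
            raise ValueError("patient mass must be > 0 kg")
        if self.administered_mbq <= 0:
            raise ValueError("administered activity must be > 0 MBq")
        if self.stimulation not in ("rhTSH", "THW"):
            raise ValueError("stimulation must be 'rhTSH' or 'THW'")


def wb_s_factor(mass_kg: float) -> float:
    """Mass-adjusted whole-body S-factor, Gy MBq^-1 h^-1."""
    if mass_kg <= 0:
        raise ValueError("patient mass must be > 0 kg")
    return S_WB_COEFFICIENT * mass_kg**S_WB_EXPONENT


def wb_dose(fit: KineticFit, patient: Patient) -> DoseRecord:
    """Whole-body absorbed dose from a fitted retention curve.

    D = TIA x S_WB(m_p); the record also carries dose per administered
    activity in mGy/MBq, the cohort reporting unit.
    """
    dose = fit.tia_mbq_h * wb_s_factor(patient.mass_kg)
    return DoseRecord(
        patient_id=patient.patient_id,
        centre=patient.centre,
        organ="whole_body",
        dose_gy=dose,
        a0_mbq=patient.administered_mbq,
        method="whole-body",
        flags=list(fit.flags),
    )
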