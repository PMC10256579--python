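"""Physical constants and configurable defaults.

Values here are data, not hard-coded truths: every quantity that a site or
study might legitimately override (mean charged-particle energy, reference
medium density) is a module-level default that callers can replace.
"""

import numpy as np

#: Physical half-life of I-131 in hours (8.02 d). Bounds every effective
#: half-life: biological clearance can only shorten retention, never extend it.
I131_PHYSICAL_HALF_LIFE_H: float = 192.5

#: Smallest physically admissible decay constant (1/h) for I-131 kinetics.
LAMBDA_PHYS_MIN: float = float(np.log(2) / I131_PHYSICAL_HALF_LIFE_H)

#: Mean charged-particle (beta + conversion/Auger electron) energy emitted per
#: I-131 decay, MeV. Shipped default for the local-deposition dose model;
#: source: ICRP-107-style decay data, rounded. Treat as configuration.
I131_MEAN_CHARGED_PARTICLE_ENERGY_MEV: float = 0.192

#: Reference medium for voxel S-value kernels (water), g/mL.
REFERENCE_DENSITY_G_PER_ML: float = 1.0

MEV_TO_J: float = 1.602e-13


def charged_particle_delta(energy_mev: float = I131_MEAN_CHARGED_PARTICLE_ENERGY_MEV) -> float:
    """Energy emitted per unit cumulated activity, in Gy·g per MBq·h.

    1 MBq·h of cumulated activity is 3.6e9 decays; each decay deposits
    ``energy_mev`` locally under the charged-particle-only model. Dividing
    the joules by a mass in grams (1e-3 kg) yields Gy·g.
    """
    joules_per_mbq_h = energy_mev * MEV_TO_J * 1.0e6 * 3600.0
    return joules_per_mbq_h / 1.0e-3
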