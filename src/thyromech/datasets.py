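"""Published porcine-thyroid reference values used as worked-example inputs.

These are the summary quantities reported for quasi-static uniaxial tests on
porcine thyroid parenchyma (cylindrical specimens, ⌀10 mm × 6 mm, strain rates
0.005/0.05 s⁻¹): the calibrated Yeoh coefficients, a four-term Prony relaxation
fit, per-replicate stage moduli and relaxation stresses, and a tensile
prediction-vs-measurement comparison table.  They serve as in-package inputs
for the error-analysis and replicate-statistics examples; they are not fixtures
for the synthetic generator, which simulates full curves.
"""

from __future__ import annotations

import numpy as np

from .mechanics import HyperelasticParams
from .viscoelastic import PronyParams

__all__ = [
    "REFERENCE_YEOH",
    "REFERENCE_PRONY",
    "STAGE_MODULUS_REPLICATES",
    "RELAXATION_STRESS_REPLICATES",
    "RELAXATION_HOLD_STRAIN",
    "TENSILE_COMPARISON",
    "COMPRESSION_PROTOCOL",
]

#: Calibrated Yeoh coefficients (MPa): C10, C20, C30.
REFERENCE_YEOH = HyperelasticParams.yeoh(1.9e-3, -2.3e-3, 0.04)

#: Four-term Prony relaxation fit: E_i (MPa), τ_i (s) and equilibrium modulus.
REFERENCE_PRONY = PronyParams(
    moduli=(0.91, 0.82, 0.76, 0.49),
    taus=(8.83, 88.68, 784.29, 2.89e3),
    equilibrium=0.51,
)

#: Stage Young's moduli (MPa) of six compression replicates:
#: E1 = toe-region slope, E2 = compacted-region slope.
STAGE_MODULUS_REPLICATES = {
    "E1": np.array([2.238e-5, 1.696e-5, 2.459e-5, 2.670e-5, 2.362e-5, 1.972e-5]),
    "E2": np.array([3.430e-3, 3.590e-3, 2.680e-3, 2.950e-3, 2.740e-3, 3.260e-3]),
}

#: Initial and residual stresses (MPa) of six stress-relaxation replicates
#: (ramp to 0.75·L0, i.e. held compressive strain 0.25, 1000 s hold).
RELAXATION_STRESS_REPLICATES = {
    "initial": np.array([2.646e-2, 2.854e-2, 1.762e-2, 2.931e-2, 1.912e-2, 2.491e-2]),
    "final": np.array([3.738e-3, 4.012e-3, 3.532e-3, 4.216e-3, 2.974e-3, 3.685e-3]),
}

#: Held engineering strain magnitude of the relaxation protocol.
RELAXATION_HOLD_STRAIN = 0.25

#: Tensile validation: strain, predicted stress (MPa, finite-element), and
#: measured stress (MPa, replicate mean) at seven strain levels.
TENSILE_COMPARISON = {
    "strain": np.array([0.0, 0.064, 0.121, 0.175, 0.253, 0.388, 0.413]),
    "predicted_MPa": np.array(
        [0.0, 5.576e-5, 6.477e-4, 2.690e-3, 1.227e-2, 6.298e-2, 0.1294]
    ),
    "measured_MPa": np.array(
        [0.0, 6.650e-5, 8.300e-4, 4.301e-3, 2.077e-2, 7.414e-2, 0.1489]
    ),
}

#: Quasi-static compression protocol constants.
COMPRESSION_PROTOCOL = {
    "specimen_diameter_mm": 10.0,
    "specimen_height_mm": 6.0,
    "sampling_rate_hz": 125.0,
    "strain_rates_per_s": (0.005, 0.05),
    "max_strain": 0.45,
    "relaxation_ramp_speed_mm_per_min": 200.0,
    "relaxation_hold_s": 1000.0,
}
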