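"""Physical constants and unit conversions.

Everything unit-sensitive in the package routes through this module so the
provenance of each derived constant is auditable in one place.

The dielectric fluctuation formula is evaluated in Gaussian-CGS units:

    eps = 1 + 4*pi * (<M^2> - <M>^2) / (3 * k_B * T * <V>)

with the dipole fluctuation in Debye^2, the volume in A^3 and the
temperature in K.  Folding the unit factors into a single prefactor gives

    C = 4*pi * (1 Debye)^2 / (3 * k_B * 1 A^3)
      = 4*pi * 1e-36 esu^2 cm^2 / (3 * 1.380649e-16 erg/K * 1e-24 cm^3)

so that eps = 1 + C * Flu[D^2] / (T[K] * V[A^3]).
"""

import math

#: gas constant, kJ mol^-1 K^-1
R_KJ = 8.3145e-3

#: default simulation temperature, K
DEFAULT_TEMPERATURE = 298.15

#: kJ per kcal (thermochemical calorie)
KJ_PER_KCAL = 4.184

#: Boltzmann constant, erg/K (CGS)
K_B_ERG = 1.380649e-16

#: 1 Debye in esu*cm
DEBYE_ESU_CM = 1e-18

#: 1 A^3 in cm^3
A3_CM3 = 1e-24

#: dielectric prefactor, K * A^3 / Debye^2  (~3.0339e4)
DIELECTRIC_C = 4.0 * math.pi * DEBYE_ESU_CM**2 / (3.0 * K_B_ERG * A3_CM3)

#: ln(10); the typeset "2.303" of the logP formula
LN10 = math.log(10.0)


def rt(temperature: float) -> float:
    """Thermal energy R*T in kJ/mol at the given temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return R_KJ * temperature
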