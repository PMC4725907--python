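"""Physical constants in the package's reduced unit system.

Units throughout: length in Angstrom, mass in amu (g/mol), energy in
kcal/mol.  The derived time unit is sqrt(amu * A^2 / (kcal/mol)) = 48.89 fs;
velocities are A per reduced time.  Temperatures are Kelvin.
"""

import math

#: Boltzmann constant, kcal / (mol K)
KB = 0.0019872041

#: Avogadro's number, 1/mol
AVOGADRO = 6.02214076e23

#: Coulomb constant e^2/(4 pi eps0) in kcal * A / mol
COULOMB_KCAL = 332.0637

#: relative dielectric constant of water used for screened electrostatics
WATER_EPS_R = 78.4

#: one reduced time unit in femtoseconds
TIME_UNIT_FS = math.sqrt(1.66053906660e-27 * 1e-20 / 6.947695e-21) * 1e15

#: elementary charge, C (SI, used only for the Debye-length closed form)
E_CHARGE = 1.602176634e-19

#: vacuum permittivity, F/m
EPS0 = 8.8541878128e-12

#: Boltzmann constant, J/K
KB_SI = 1.380649e-23


def kt(temperature: float) -> float:
    """Thermal energy k_B T in kcal/mol."""
    return KB * temperature
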