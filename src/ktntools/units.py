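"""Physical constants and unit conventions.

Internal unit system for bead models: energies in kcal/mol, lengths in
Angstrom, charges in elementary charge units, masses in Da, temperature
in Kelvin.  Analytic test surfaces use dimensionless model units with
``kB = 1`` passed explicitly where needed.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _c

#: Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL = _c.k * _c.N_A / (_c.calorie * 1000.0)

#: Coulomb constant e^2/(4 pi eps0) in kcal mol^-1 Angstrom e^-2 (vacuum)
COULOMB_KCAL = (
    _c.e**2 / (4.0 * np.pi * _c.epsilon_0) * _c.N_A / (_c.calorie * 1000.0) * 1e10
)

#: Relative permittivity of water used for the bead-peptide electrostatics.
#: Frozen near the value for liquid water at 310 K.
WATER_EPS_R = 74.0

#: Default analysis temperature (K)
T_BODY = 310.0


def debye_length(ionic_strength: float, temperature: float = T_BODY,
                 eps_r: float = WATER_EPS_R) -> float:
    """Debye screening length in Angstrom for a 1:1 electrolyte.

    Parameters
    ----------
    ionic_strength : molar concentration (mol/L) of a 1:1 salt.
    temperature : K.
    eps_r : relative permittivity of the solvent.

    Returns ``inf`` for zero ionic strength.
    """
    if ionic_strength < 0:
        raise ValueError("ionic_strength must be non-negative")
    if ionic_strength == 0:
        return np.inf
    # number density of each ion species in m^-3; I in mol/L -> mol/m^3 is *1000
    n = ionic_strength * 1000.0 * _c.N_A
    lam_sq = eps_r * _c.epsilon_0 * _c.k * temperature / (2.0 * n * _c.e**2)
    return float(np.sqrt(lam_sq) * 1e10)
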