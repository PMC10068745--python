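"""Physical constants and small built-in property tables.

All internal computation is SI (m, Pa, J/mol, mol/m^3, V).  The presentation
helpers in :mod:`monoion.io` convert to the customary interfacial units
(mN/m, Angstrom^2 per molecule, nm^-2, mol/kg, mV).
"""

from __future__ import annotations

import numpy as np

# CODATA 2018
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Effective radius of a water molecule used in the hydration-shell
#: geometry, in metres (1.39 Angstrom).
R_WATER = 1.39e-10

#: Default working temperature, K (20 C, the temperature of the historical
#: monolayer experiments analysed by the package).
T_DEFAULT = 293.15

#: Relative permittivity of pure water at 20 C.
EPS_WATER_20C = 80.1

#: Surface potential of pure water chi_0, volts.  No direct measurement
#: exists; this commonly adopted estimate is a named, overridable default.
CHI0_DEFAULT = -0.090

#: Default ratio of the "oil" (hydrocarbon-tail layer) to water quadrupolar
#: lengths, L_q^o / L_q^w, for a liquid-expanded monolayer.
LQ_RATIO_DEFAULT = 0.5

ANGSTROM = 1e-10
MN_PER_M = 1e-3  # 1 mN/m in N/m

# Density of pure water vs temperature (K -> kg/m^3); linear interpolation.
# End points extend slightly past 0-100 C (supercooled/superheated) so
# out-of-band temperatures can still be evaluated after a warning.
_RHO_W_T = np.array([268.15, 273.15, 283.15, 293.15, 313.15, 373.15, 378.15])
_RHO_W_V = np.array([999.30, 999.84, 999.70, 998.21, 992.22, 958.35, 955.10])


def water_density(T: float = T_DEFAULT) -> float:
    """Mass density of pure water at temperature ``T`` (kg/m^3).

    Linear interpolation on a 5-point built-in table spanning 0-100 C.
    """
    if not (_RHO_W_T[0] <= T <= _RHO_W_T[-1]):
        raise ValueError(f"T={T} K outside the water density table "
                         f"({_RHO_W_T[0]}-{_RHO_W_T[-1]} K)")
    return float(np.interp(T, _RHO_W_T, _RHO_W_V))


def kT(T: float = T_DEFAULT) -> float:
    """Thermal energy per molecule, J."""
    return BOLTZMANN * T
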