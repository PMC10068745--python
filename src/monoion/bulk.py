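"""Bulk-solution thermodynamics of strong electrolytes.

Everything downstream — the depletion model of the bare water|air surface,
the isotherm inversion machinery and the Volta-potential analysis — consumes
bulk quantities computed here: mean activity coefficients, osmotic
coefficients and pressures, electrolyte chemical potentials, molal/molar
conversion, ionic strength and the Debye and Bjerrum screening lengths.

Activities are *inputs*: they come from tabulated experimental data (or from
a synthetic closed form), never from a predictive model.  Tables are
interpolated with a monotone piecewise cubic (PCHIP); extrapolation beyond
the tabulated range is refused unless a table is explicitly flagged as
extrapolable.

Conventions
-----------
``C_m`` is molality (mol per kg of water), ``C_M`` molarity in SI
(mol/m^3).  The electrolyte chemical potential is used in the
formula-unit convention::

    mu_el = mu_el^0 + nu R T ln(gamma_el C_el,m)

so that the Gibbs isotherm reads ``dsigma = -Gamma_el dmu_el`` and the
Gibbs-Duhem link to the osmotic pressure is
``dmu_el = dp_osm / (rho_w C_el,m)`` with no stoichiometric factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    EPS_WATER_20C,
    GAS_CONSTANT,
    T_DEFAULT,
    VACUUM_PERMITTIVITY,
    water_density,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IonSpec",
    "PropertyTable",
    "ElectrolyteSpec",
    "SolutionState",
    "activity_coefficient",
    "osmotic_coefficient",
    "osmotic_pressure",
    "chemical_potential_increment",
    "molal_to_molar",
    "screening_lengths",
    "solution_state",
]

#: Bare-radius boundary between surface-inactive and "sticky" ions, m.
STICKY_RADIUS = 2.0e-10


@dataclass(frozen=True)
class IonSpec:
    """A single ionic species.

    Parameters
    ----------
    name:
        Label, e.g. ``"Na+"``.
    z:
        Absolute charge number (>= 1).
    R0:
        Crystallographic radius in metres.
    role:
        ``"cation"`` or ``"anion"``.
    """

    name: str
    z: int
    R0: float
    role: str

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError(f"{self.name}: charge number must be >= 1")
        if self.R0 <= 0:
            raise ValueError(f"{self.name}: R0 must be positive")
        if self.role not in ("cation", "anion"):
            raise ValueError(f"{self.name}: role must be cation or anion")
        if self.R0 >= STICKY_RADIUS:
            warnings.warn(
                f"{self.name}: bare radius {self.R0 * 1e10:.2f} A >= 2 A; "
                "the ion is 'sticky' and outside the surface-inactive "
                "depletion model", stacklevel=2)

    @property
    def is_surface_inactive(self) -> bool:
        return self.R0 < STICKY_RADIUS


class PropertyTable:
    """Two-column property table with monotone-cubic interpolation.

    Knots must be strictly increasing in ``C_m``.  Queries outside the
    tabulated range raise :class:`ValueError` unless ``extrapolate=True``
    was set at construction (PCHIP extrapolation is then used and a warning
    is logged on each out-of-range call).
    """

    def __init__(self, C_m, values, *, name: str = "table",
                 extrapolate: bool = False) -> None:
        C_m = np.asarray(C_m, dtype=float)
        values = np.asarray(values, dtype=float)
        if C_m.ndim != 1 or C_m.shape != values.shape:
            raise ValueError(f"{name}: need matching 1-d arrays")
        if C_m.size < 2:
            raise ValueError(f"{name}: need at least 2 knots")
        if np.any(np.diff(C_m) <= 0):
            raise ValueError(f"{name}: C_m knots must be strictly increasing")
        self.name = name
        self.C_m = C_m
        self.values = values
        self.extrapolate = extrapolate
        self._interp = PchipInterpolator(C_m, values, extrapolate=True)

    @property
    def C_min(self) -> float:
        return float(self.C_m[0])

    @property
    def C_max(self) -> float:
        return float(self.C_m[-1])

    def __call__(self, C_m):
        C = np.asarray(C_m, dtype=float)
        out_of_range = (C < self.C_min - 1e-15) | (C > self.C_max + 1e-15)
        if np.any(out_of_range):
            if not self.extrapolate:
                raise ValueError(
                    f"{self.name}: query {C[out_of_range].ravel()} outside "
                    f"tabulated range [{self.C_min}, {self.C_max}] mol/kg "
                    "(extrapolation disabled)")
            logger.warning("%s: extrapolating outside [%g, %g] mol/kg",
                           self.name, self.C_min, self.C_max)
        res = self._interp(C)
        return float(res) if np.isscalar(C_m) else res


@dataclass
class ElectrolyteSpec:
    """A strong, fully dissociated electrolyte and its bulk property tables.

    ``activity_table`` samples the mean activity coefficient
    ``gamma_el(C_m)``; ``density_model`` maps molality to solution mass
    density (kg/m^3); ``eps_table`` samples the static relative permittivity
    of the solution and ``chi_table`` the surface-potential change
    ``Delta chi(C_m)`` in volts (only needed for Volta analysis).
    """

    name: str
    cation: IonSpec
    anion: IonSpec
    nu_plus: int
    nu_minus: int
    V_el: float = 0.0  # partial molar volume, m^3/mol
    molar_mass: float = 0.0  # kg/mol, for the molal->molar mass balance
    activity_table: Optional[PropertyTable] = None
    density_model: Optional[Callable[[float], float]] = None
    eps_table: Optional[PropertyTable] = None
    chi_table: Optional[PropertyTable] = None

    def __post_init__(self) -> None:
        if self.nu_plus * self.cation.z != self.nu_minus * self.anion.z:
            raise ValueError(
                f"{self.name}: electroneutrality requires "
                "nu_+ z_+ == nu_- z_-")
        if self.activity_table is not None:
            g = self.activity_table.values
            if np.any(g <= 0):
                raise ValueError(f"{self.name}: non-positive gamma_el values")

    @property
    def nu(self) -> int:
        """Isotonic coefficient, total ions per formula unit."""
        return self.nu_plus + self.nu_minus

    def eps(self, C_m: float) -> float:
        """Relative permittivity of the solution (pure-water fallback)."""
        if self.eps_table is None:
            return EPS_WATER_20C
        return float(self.eps_table(C_m))

    def ions(self):
        yield self.nu_plus, self.cation
        yield self.nu_minus, self.anion


@dataclass
class SolutionState:
    """All derived bulk quantities at one concentration."""

    spec: ElectrolyteSpec
    C_m: float          # mol/kg
    C_M: float          # mol/m^3
    gamma_el: float
    phi_osm: float
    p_osm: float        # Pa
    dmu_el: float       # J/mol vs infinite-dilution reference at 1 mol/kg
    I_M: float          # mol/m^3
    I_m: float          # mol/kg
    L_D: float          # m
    L_B: float          # m
    eps: float
    T: float = T_DEFAULT


def _anchored_lngamma(tab: PropertyTable) -> PchipInterpolator:
    """PCHIP of ln(gamma) through the table knots, anchored at (0, 0).

    The anchor encodes the exact infinite-dilution limit gamma(0) = 1 and
    makes the dilute closure of Gibbs-Duhem integrals well defined.
    """
    if tab.C_min == 0.0:
        m, lng = tab.C_m, np.log(tab.values)
    else:
        m = np.concatenate(([0.0], tab.C_m))
        lng = np.concatenate(([0.0], np.log(tab.values)))
    return PchipInterpolator(m, lng, extrapolate=False)


def activity_coefficient(spec: ElectrolyteSpec, C_m) -> float:
    """Mean activity coefficient ``gamma_el`` at molality ``C_m``.

    Monotone-cubic interpolation of the electrolyte's activity table,
    anchored at the infinite-dilution limit ``gamma_el(0) = 1``.  Queries
    above the last knot are refused unless the table allows extrapolation.
    """
    scalar = np.isscalar(C_m)
    C = np.atleast_1d(np.asarray(C_m, dtype=float))
    if np.any(C < 0):
        raise ValueError("molality must be non-negative")
    tab = spec.activity_table
    out = np.ones_like(C)
    nz = C > 0
    if np.any(nz):
        if tab is None:
            raise ValueError(f"{spec.name}: no activity table")
        if np.any(C > tab.C_max + 1e-15):
            if not tab.extrapolate:
                raise ValueError(
                    f"{tab.name}: query above tabulated maximum "
                    f"{tab.C_max} mol/kg (extrapolation disabled)")
            out[nz] = tab(C[nz])
            return float(out[0]) if scalar else out
        out[nz] = np.exp(_anchored_lngamma(tab)(C[nz]))
    return float(out[0]) if scalar else out


def osmotic_coefficient(spec: ElectrolyteSpec) -> Callable:
    """Molal osmotic coefficient ``phi(C_m)`` by Gibbs-Duhem integration.

    From the tabulated ``gamma_el``::

        phi(m) = 1 + (1/m) \\int_0^m m' dln(gamma)(m')
               = 1 + ln gamma(m) - (1/m) \\int_0^m ln gamma(m') dm'

    (integration by parts avoids differentiating the table).  The table is
    anchored at ``(0, gamma=1)`` so the integral closes at infinite
    dilution; ``phi(0) = 1``.
    """
    tab = spec.activity_table
    if tab is None:
        raise ValueError(f"{spec.name}: no activity table")
    if np.any(tab.values <= 0):
        raise ValueError(f"{spec.name}: non-positive gamma_el in table")
    if tab.C_m.size < 4 or tab.C_min > 0.1:
        warnings.warn(
            f"{spec.name}: activity table is sparse or lacks a knot below "
            "0.1 mol/kg; the dilute closure of the Gibbs-Duhem integral "
            "is poorly constrained", stacklevel=2)
    lngam = _anchored_lngamma(tab)
    lngam_int = lngam.antiderivative()

    def phi(C_m):
        scalar = np.isscalar(C_m)
        m = np.atleast_1d(np.asarray(C_m, dtype=float))
        if np.any(m < 0) or np.any(m > tab.C_max + 1e-12):
            raise ValueError(
                f"{spec.name}: phi query outside [0, {tab.C_max}] mol/kg")
        out = np.ones_like(m)
        nz = m > 0
        out[nz] = 1.0 + lngam(m[nz]) - lngam_int(m[nz]) / m[nz]
        return float(out[0]) if scalar else out

    return phi


def osmotic_pressure(spec: ElectrolyteSpec, C_m: float, *,
                     phi: Optional[float] = None,
                     T: float = T_DEFAULT) -> float:
    """Osmotic pressure ``p_osm = phi nu R T rho_w C_m`` in Pa.

    With ``phi = 1`` this is the van 't Hoff limit
    ``p_osm = nu R T rho_w C_m``.  ``phi`` defaults to the Gibbs-Duhem
    value from the activity table.
    """
    if not (273.0 <= T <= 373.0):
        warnings.warn(f"T={T} K outside 273-373 K", stacklevel=2)
    if C_m == 0:
        return 0.0
    if C_m < 0:
        raise ValueError("molality must be non-negative")
    if phi is None:
        phi = float(osmotic_coefficient(spec)(C_m))
    return phi * spec.nu * GAS_CONSTANT * T * water_density(T) * C_m


def chemical_potential_increment(spec: ElectrolyteSpec, C_m_ref: float,
                                 C_m: float, *, T: float = T_DEFAULT) -> float:
    """Formula-unit chemical potential increment, J/mol::

        Delta mu_el = nu R T ln[ (gamma_el C_m) / (gamma_el C_m)_ref ]

    A zero molality with a finite reference is at minus infinity; that is
    flagged explicitly rather than silently returned.
    """
    if C_m_ref <= 0:
        raise ValueError("reference molality must be positive "
                         "(the standard state is not a valid reference here)")
    if C_m == 0:
        raise ValueError("Delta mu_el -> -infinity at C_m = 0; "
                         "integrate from a finite lower bound instead")
    g = activity_coefficient(spec, C_m)
    g_ref = activity_coefficient(spec, C_m_ref)
    return spec.nu * GAS_CONSTANT * T * np.log((g * C_m) / (g_ref * C_m_ref))


def molal_to_molar(spec: ElectrolyteSpec, C_m, *, T: float = T_DEFAULT):
    """Convert molality (mol/kg water) to molarity (mol/m^3).

    Mass balance: 1 kg of water carries ``C_m`` moles of electrolyte, so the
    solution mass is ``1 + C_m M_el`` kg and::

        C_M = C_m rho_solution / (1 + C_m M_el)

    with ``M_el`` in kg/mol.  Without a density model the pure-water density
    is used and a warning logged (adequate below ~0.5 mol/kg).
    """
    C = np.asarray(C_m, dtype=float)
    if np.any(C < 0):
        raise ValueError("molality must be non-negative")
    if spec.density_model is not None:
        rho = np.vectorize(spec.density_model)(C)
    else:
        logger.warning("%s: no density model; using pure-water density",
                       spec.name)
        rho = water_density(T)
    out = C * rho / (1.0 + C * spec.molar_mass)
    return float(out) if np.isscalar(C_m) else out


def screening_lengths(spec: ElectrolyteSpec, C_m: float, *,
                      T: float = T_DEFAULT,
                      eps: Optional[float] = None) -> tuple[float, float]:
    """Debye and Bjerrum lengths ``(L_D, L_B)`` in metres.

    SI forms ``L_B = e^2/(4 pi eps0 eps k T)`` and
    ``L_D = sqrt(eps0 eps k T / (2 e^2 N_A I_M))`` with the molar ionic
    strength ``I_M = (1/2) sum_k C_k,M z_k^2`` (mol/m^3).
    """
    if eps is None:
        eps = spec.eps(C_m)
    L_B = ELEMENTARY_CHARGE**2 / (
        4 * np.pi * VACUUM_PERMITTIVITY * eps * BOLTZMANN * T)
    if C_m == 0:
        return np.inf, L_B
    C_M = molal_to_molar(spec, C_m, T=T)
    I_M = 0.5 * sum(nu_k * ion.z**2 for nu_k, ion in spec.ions()) * C_M
    L_D = np.sqrt(VACUUM_PERMITTIVITY * eps * BOLTZMANN * T /
                  (2 * ELEMENTARY_CHARGE**2 * AVOGADRO * I_M))
    return float(L_D), float(L_B)


def solution_state(spec: ElectrolyteSpec, C_m: float, *,
                   T: float = T_DEFAULT,
                   C_m_ref: Optional[float] = None) -> SolutionState:
    """Bundle every derived bulk quantity at one molality.

    ``dmu_el`` is reported against ``C_m_ref`` (default: 1 mol/kg, clipped
    to the activity table's range).
    """
    if C_m_ref is None:
        C_m_ref = 1.0
        if spec.activity_table is not None:
            C_m_ref = min(1.0, spec.activity_table.C_max)
    gamma = activity_coefficient(spec, C_m)
    phi = float(osmotic_coefficient(spec)(C_m)) if C_m > 0 else 1.0
    p = osmotic_pressure(spec, C_m, phi=phi, T=T)
    C_M = molal_to_molar(spec, C_m, T=T)
    I_m = 0.5 * sum(nu_k * ion.z**2 for nu_k, ion in spec.ions()) * C_m
    eps = spec.eps(C_m)
    L_D, L_B = screening_lengths(spec, C_m, T=T, eps=eps)
    dmu = (chemical_potential_increment(spec, C_m_ref, C_m, T=T)
           if C_m > 0 else -np.inf)
    I_M = 0.5 * sum(nu_k * ion.z**2 for nu_k, ion in spec.ions()) * C_M
    return SolutionState(spec=spec, C_m=C_m, C_M=C_M, gamma_el=gamma,
                         phi_osm=phi, p_osm=p, dmu_el=dmu, I_M=I_M, I_m=I_m,
                         L_D=L_D, L_B=L_B, eps=eps, T=T)
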