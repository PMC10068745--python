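"""Modified-Schmutzer (MS) model of the bare electrolyte|air surface.

Surface-inactive ions (bare radius < 2 A) are expelled from the water|air
surface by two forces of the same ion/dipole origin but different range:
the short-range *hydration* force, idealised as a hard wall that keeps an
ion with its retained hydration shell(s) a distance ``R_i`` below the plane
where the dielectric permittivity jumps, and the longer-ranged *image*
force of Onsager-Samaras type, screened over the Debye length.  The model
has no adjustable parameters: the depletion thicknesses follow from the
crystallographic radii and the geometry of the hydration shell, and the
remaining inputs (activity coefficients, permittivity) are bulk data.

Geometry
--------
A monovalent ion approaching the surface keeps one complete hydration
shell, a di- or trivalent ion two, so the hydrated radius is::

    R_h,i = R_0,i + 2 n_i R_w,   n_i = 1 (z=1) or 2 (z=2,3)

with ``R_w = 1.39 A`` the effective water radius.  The permittivity
discontinuity sits in the middle of the last water layer, i.e. ``R_w``
below the top of that layer, while the ion centre can approach to
``R_h,i`` below the top, so the depletion thickness is::

    R_i = R_h,i - R_w

Surface excess
--------------
Linearising the Boltzmann factor of the screened image potential
``W_i(x) = z_i^2 kT (L_B/4x) exp(-2x/L_D)`` beyond the hard wall and
imposing electroneutrality of the full ion profile gives the closed form
(per formula unit of electrolyte, at the epsilon-discontinuity plane)::

    Gamma_el^eps = -(C_M/nu) sum_k nu_k [ R_k + (z_k^2 L_B/4) E1(2R_k/L_D) ]

where ``E1`` is the first-order exponential integral.  The electroneutral
combination of the per-ion excesses reduces exactly to this stoichiometric
mean (the identity ``(nu_+ + nu_-) z_+ z_- = q(z_+ + z_-)`` with
``q = nu_+ z_+ = nu_- z_-`` makes the charge-weighted and the
stoichiometric averages coincide).

The asymmetry of the two depletion thicknesses leaves a charged gap
populated only by the smaller ion, producing a small electric double
layer; its potential follows from the linear Poisson-Boltzmann equation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import exp1

from .bulk import (
    ElectrolyteSpec,
    IonSpec,
    SolutionState,
    chemical_potential_increment,
    solution_state,
)
from .constants import (
    AVOGADRO,
    ELEMENTARY_CHARGE,
    R_WATER,
    T_DEFAULT,
    VACUUM_PERMITTIVITY,
)

__all__ = [
    "DepletionGeometry",
    "WASurfaceState",
    "hydrated_radius",
    "depletion_thickness",
    "depletion_geometry",
    "excess_at_eps_plane",
    "excess_at_equimolecular",
    "edl_potential_wa",
    "surface_tension_increment",
    "wa_surface_state",
]


def hydrated_radius(ion: IonSpec) -> float:
    """Hydrated radius ``R_h`` (m) of an ion with its retained shell(s).

    Tangent-sphere geometry: each retained hydration shell of water
    molecules (radius ``R_w``) adds ``2 R_w`` to the bare radius.
    Monovalent ions retain one complete shell, di- and trivalent two.
    """
    if ion.z not in (1, 2, 3):
        raise ValueError(f"{ion.name}: unsupported valence z={ion.z}")
    n_shells = 1 if ion.z == 1 else 2
    return ion.R0 + 2 * n_shells * R_WATER


def depletion_thickness(ion: IonSpec) -> float:
    """Depletion-layer thickness ``R_i = R_h,i - R_w`` (m).

    Distance from the permittivity-discontinuity plane (middle of the last
    water layer) to the ion's plane of closest approach.
    """
    return hydrated_radius(ion) - R_WATER


@dataclass(frozen=True)
class DepletionGeometry:
    """Hydrated radii and depletion thicknesses of an ion pair.

    ``smaller``/``bigger`` order the two ions by depletion thickness; for
    the degenerate equal-thickness pair the cation is labelled smaller
    (the sign it controls is then multiplied by a zero gap anyway).
    """

    spec: ElectrolyteSpec
    R_h_cation: float
    R_h_anion: float
    R_dep_cation: float
    R_dep_anion: float

    @property
    def smaller(self) -> IonSpec:
        if self.R_dep_cation <= self.R_dep_anion:
            return self.spec.cation
        return self.spec.anion

    @property
    def bigger(self) -> IonSpec:
        if self.R_dep_cation <= self.R_dep_anion:
            return self.spec.anion
        return self.spec.cation

    @property
    def R_dep_smaller(self) -> float:
        return min(self.R_dep_cation, self.R_dep_anion)

    @property
    def R_dep_bigger(self) -> float:
        return max(self.R_dep_cation, self.R_dep_anion)

    @property
    def cation_is_smaller(self) -> bool:
        return self.R_dep_cation <= self.R_dep_anion


def depletion_geometry(spec: ElectrolyteSpec) -> DepletionGeometry:
    return DepletionGeometry(
        spec=spec,
        R_h_cation=hydrated_radius(spec.cation),
        R_h_anion=hydrated_radius(spec.anion),
        R_dep_cation=depletion_thickness(spec.cation),
        R_dep_anion=depletion_thickness(spec.anion),
    )


def _warn_if_sticky(spec: ElectrolyteSpec) -> None:
    for _, ion in spec.ions():
        if not ion.is_surface_inactive:
            warnings.warn(
                f"{ion.name} is a sticky ion (R0 >= 2 A); the depletion "
                "model does not describe its specific adsorption",
                stacklevel=3)


def excess_at_eps_plane(spec: ElectrolyteSpec,
                        state: SolutionState) -> float:
    """Electrolyte surface excess at the eps-discontinuity plane, mol/m^2.

    Closed form of the linearised depletion + image model (module
    docstring); strictly negative for surface-inactive pairs at finite
    concentration.
    """
    _warn_if_sticky(spec)
    if state.C_M == 0:
        return 0.0
    total = 0.0
    # the closed form is symmetric in the bigger/smaller assignment
    for nu_k, ion in spec.ions():
        R_k = depletion_thickness(ion)
        total += nu_k * (R_k + ion.z**2 * state.L_B / 4.0
                         * float(exp1(2.0 * R_k / state.L_D)))
    return -state.C_M / spec.nu * total


def excess_at_equimolecular(Gamma_eps: float, spec: ElectrolyteSpec,
                            state: SolutionState) -> float:
    """Excess at water's equimolecular plane: ``Gamma_el = Gamma^eps / (1 - V_el C_M)``.

    The factor ``1 - V_el C_el,M`` accounts for the shift of the water
    equimolecular plane toward the solution as electrolyte (of partial
    molar volume ``V_el``) replaces water.
    """
    factor = 1.0 - spec.V_el * state.C_M
    if factor <= 0:
        raise ValueError(
            f"{spec.name}: V_el*C_M = {spec.V_el * state.C_M:.3f} >= 1 "
            "is nonphysical")
    return Gamma_eps / factor


def edl_potential_wa(spec: ElectrolyteSpec, state: SolutionState) -> float:
    """Diffuse-layer potential ``phi`` (V) of the bare surface.

    Only the smaller ion populates the gap between the two depletion
    planes; solving the linear Poisson-Boltzmann equation with that fixed
    charge slab and screening beyond the bigger ion's plane gives::

        phi = +/- (z_s e nu_s C_M N_A / (eps0 eps)) (R_b - R_s)
                  (L_D + (R_b - R_s)/2)

    the sign being that of the smaller ion (plus if the cation is
    smaller).  Vanishes as ``C -> 0`` (through ``C_M L_D ~ sqrt(C)``) and
    as the depletion gap closes.
    """
    if state.C_M == 0:
        return 0.0
    geom = depletion_geometry(spec)
    gap = geom.R_dep_bigger - geom.R_dep_smaller
    if gap == 0.0:
        return 0.0
    s = geom.smaller
    nu_s = spec.nu_plus if s.role == "cation" else spec.nu_minus
    sign = 1.0 if geom.cation_is_smaller else -1.0
    magnitude = (s.z * ELEMENTARY_CHARGE * nu_s * state.C_M * AVOGADRO
                 / (VACUUM_PERMITTIVITY * state.eps)
                 * gap * (state.L_D + gap / 2.0))
    return sign * magnitude


def surface_tension_increment(spec: ElectrolyteSpec, C_grid, *,
                              T: float = T_DEFAULT,
                              rel_tol: float = 1e-3,
                              n_start: int = 64):
    """Surface tension increase ``sigma(C) - sigma(0)`` (N/m) on ``C_grid``.

    Integrates the Gibbs isotherm ``dsigma = -Gamma_el dmu_el`` from
    infinite dilution, with ``Gamma_el`` from the MS closed form at the
    equimolecular plane.  Trapezoid rule on a log-spaced inner molality
    grid, doubled until the result changes by less than ``rel_tol``
    everywhere.
    """
    C_grid = np.asarray(C_grid, dtype=float)
    if np.any(np.diff(C_grid) <= 0):
        raise ValueError("C_grid must be strictly increasing")
    if np.any(C_grid < 0):
        raise ValueError("C_grid must be non-negative")
    C_max = C_grid[-1]
    if C_max == 0:
        return np.zeros_like(C_grid)
    # contribution of (0, C_lo] is O(C_lo) since Gamma_el = O(C): negligible
    C_lo = max(1e-4, C_grid[C_grid > 0].min() * 1e-2)

    def run(n: int) -> np.ndarray:
        m = np.geomspace(C_lo, C_max, n)
        m = np.unique(np.concatenate((m, C_grid[C_grid > 0])))
        gam = np.array([
            excess_at_equimolecular(
                excess_at_eps_plane(spec, st), spec, st)
            for st in (solution_state(spec, mi, T=T) for mi in m)])
        mu = np.concatenate(([0.0], np.cumsum([
            chemical_potential_increment(spec, a, b, T=T)
            for a, b in zip(m[:-1], m[1:])])))
        dsig = np.concatenate(
            ([0.0], np.cumsum(-0.5 * (gam[1:] + gam[:-1]) * np.diff(mu))))
        return np.interp(C_grid, np.concatenate(([0.0], m)),
                         np.concatenate(([0.0], dsig)))

    prev = run(n_start)
    for _ in range(6):
        n_start *= 2
        cur = run(n_start)
        scale = np.max(np.abs(cur)) or 1.0
        if np.max(np.abs(cur - prev)) / scale < rel_tol:
            return cur
        prev = cur
    warnings.warn("surface_tension_increment: inner grid refinement did "
                  "not converge to requested tolerance", stacklevel=2)
    return cur


@dataclass(frozen=True)
class WASurfaceState:
    """MS-model prediction for the bare surface at one concentration."""

    Gamma_eps: float       # mol/m^2 at the eps plane
    Gamma_em: float        # mol/m^2 at water's equimolecular plane
    phi_DL: float          # V
    sigma_increment: float  # N/m vs pure water


def wa_surface_state(spec: ElectrolyteSpec, C_m: float, *,
                     T: float = T_DEFAULT) -> WASurfaceState:
    """All MS-model outputs for one electrolyte at one molality."""
    st = solution_state(spec, C_m, T=T)
    g_eps = excess_at_eps_plane(spec, st)
    g_em = excess_at_equimolecular(g_eps, spec, st)
    phi = edl_potential_wa(spec, st)
    if C_m > 0:
        dsig = float(surface_tension_increment(spec, np.array([C_m]), T=T)[0])
    else:
        dsig = 0.0
    return WASurfaceState(Gamma_eps=g_eps, Gamma_em=g_em, phi_DL=phi,
                          sigma_increment=dsig)
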