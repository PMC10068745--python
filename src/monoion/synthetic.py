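"""Thermodynamically self-consistent synthetic monolayer/electrolyte systems.

The whole inversion pipeline — plateau handling, spreading-area
extrapolation, chemical-potential integration, both adsorption routes and
the Volta decomposition — is exercised against systems with *closed-form*
ground truth, built so the Maxwell relation between the two routes holds
identically.

Construction
------------
The surface pressure is a smooth function of the surfactant chemical
potential ``x = (mu_s - mu_s,sp)/kT`` (per molecule, zero at the
equilibrium spread state) and of the electrolyte state through the reduced
osmotic pressure ``H(C) = p_osm(C)/p_scale``::

    pi(x, C) = F(x) + G(x) H(C)
    F(x)  = (kT Gamma_max / b) ln(1 + e^{b (x - x0)})     (Langmuir-like,
            cooperativity b sharpens the condensed branch)
    G(x)  = g * 4 theta (1 - theta),  theta = logistic(b (x - x0))

so that, exactly,

    Gamma_s(x, C)  = (1/kT) (F'(x) + G'(x) H)          [molecules/m^2]
    DGamma_el(x,C) = rho_w C_m G(x) / p_scale          [mol/m^2]
    pi_sp(C)       = F(0) + G(0) H(C)                  (linear in p_osm)

``DGamma_el`` is the osmotic-pressure derivative of ``pi`` at fixed
``mu_s`` mapped through ``d mu_el = d p_osm/(rho_w C_m)`` — the very
object the estimators reconstruct, which is what makes recovery a true
correctness test.  The coupling bump ``4 theta(1-theta)`` vanishes with
the monolayer (``DGamma_el -> 0`` as ``Gamma_s -> 0``) and places one
interior maximum at half coverage.  The default amplitude keeps
``Gamma_s > 0`` everywhere (``12 g H_max < kT Gamma_max`` with margin)
and is small enough that the global least-squares slope over the sparse
default molalities remains within its linear-response regime — i.e. the
chemical-potential surface is only weakly curved in the osmotic pressure
across the sampled span, as the near-linear historical pi_sp(p_osm) data
indicate for the real systems.

Bulk activities follow an extended Debye-Hueckel closed form
``ln gamma = -A sqrt(m)/(1 + B sqrt(m)) + b_lin m`` sampled into the same
table format measured data would use.  Defaults mimic the historical
data: molalities (0, 1, 2, 3.5) mol/kg, an oleic-acid-like monolayer
(collapse near 28 A^2, pi_sp near 17 mN/m) and optional multiplicative
digitization noise on pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .bulk import (
    ElectrolyteSpec,
    IonSpec,
    PropertyTable,
    solution_state,
)
from .constants import (
    AVOGADRO,
    EPS_WATER_20C,
    T_DEFAULT,
    kT,
    water_density,
)
from .isotherm import IsothermCurve, SpreadingSeries
from .msmodel import edl_potential_wa
from .volta import DEBYE, VoltaCurve, compose_deltaV

__all__ = [
    "SyntheticParams",
    "SyntheticSystem",
    "build_system",
    "sample_isotherms",
    "sample_deltaV",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic free-energy surface and bulk models."""

    # surface equation of state
    Gamma_max: float = 1.0 / 28.0e-20   # molecules/m^2 (28 A^2 collapse)
    b: float = 3.0                      # cooperativity of the sigmoid
    x0: float = -1.18                   # sets pi_sp ~ 17 mN/m
    g: float = 3.0e-5                   # N/m, ion-monolayer coupling
    p_scale: float = 5.0e6              # Pa, reduced-osmotic-pressure scale
    # extended Debye-Hueckel activity model (molal)
    A_dh: float = 1.17
    B_dh: float = 1.30
    b_lin: float = 0.05
    # bulk side tables
    V_el: float = 16.6e-6               # m^3/mol
    molar_mass: float = 0.0585          # kg/mol
    rho_slope: float = 38.0             # kg/m^3 per (mol/kg)
    eps_decrement: float = 8.0          # per (mol/kg)
    dchi_slope: float = -0.005          # V per (mol/kg)
    # dipole model for Volta sampling
    p_molecule_D: float = 0.8           # Debye per adsorbed molecule
    p_salt_slope: float = 0.0           # relative P_s change per (mol/kg)
    phi_dl_model: str = "zero"          # "zero" | "ms"
    # sampling
    noise: float = 0.0                  # multiplicative pi noise (sd)
    T: float = T_DEFAULT


def _make_spec(p: SyntheticParams) -> ElectrolyteSpec:
    """Synthetic NaCl-like 1:1 electrolyte with tables generated from the
    closed-form bulk models."""
    m = np.concatenate(([0.0], np.geomspace(1e-3, 4.0, 60)))
    sm = np.sqrt(m)
    lng = -p.A_dh * sm / (1.0 + p.B_dh * sm) + p.b_lin * m
    gamma = np.exp(lng)
    eps = EPS_WATER_20C - p.eps_decrement * m
    cation = IonSpec("M+", 1, 0.98e-10, "cation")
    anion = IonSpec("X-", 1, 1.81e-10, "anion")
    rho0 = water_density(p.T)
    return ElectrolyteSpec(
        name="synthetic-1:1",
        cation=cation, anion=anion, nu_plus=1, nu_minus=1,
        V_el=p.V_el, molar_mass=p.molar_mass,
        activity_table=PropertyTable(m, gamma, name="synthetic gamma"),
        density_model=lambda C_m: rho0 + p.rho_slope * C_m,
        eps_table=PropertyTable(m, eps, name="synthetic eps"),
        chi_table=PropertyTable(m, p.dchi_slope * m, name="synthetic dchi"),
    )


@dataclass
class SyntheticSystem:
    """A fully specified synthetic system with analytic ground truth."""

    params: SyntheticParams
    spec: ElectrolyteSpec
    seed: int
    rng: np.random.Generator = field(repr=False, default=None)  # type: ignore

    # -- closed-form surface ------------------------------------------------

    def _theta(self, x):
        p = self.params
        return 1.0 / (1.0 + np.exp(-p.b * (np.asarray(x, float) - p.x0)))

    def H(self, C_m: float) -> float:
        """Reduced osmotic pressure p_osm/p_scale."""
        if C_m == 0:
            return 0.0
        st = solution_state(self.spec, C_m, T=self.params.T)
        return st.p_osm / self.params.p_scale

    def F(self, x):
        p = self.params
        return (kT(p.T) * p.Gamma_max / p.b) * np.log1p(
            np.exp(p.b * (np.asarray(x, float) - p.x0)))

    def G(self, x):
        th = self._theta(x)
        return self.params.g * 4.0 * th * (1.0 - th)

    def pi(self, x, C_m: float):
        """Surface pressure (N/m)."""
        return self.F(x) + self.G(x) * self.H(C_m)

    def Gamma_s_number(self, x, C_m: float):
        """Surfactant density, molecules/m^2 (= d pi/d mu_s)."""
        p = self.params
        th = self._theta(x)
        Fp = kT(p.T) * p.Gamma_max * th
        Gp = p.g * 4.0 * p.b * th * (1.0 - th) * (1.0 - 2.0 * th)
        return (Fp + Gp * self.H(C_m)) / kT(p.T)

    def S_of_x(self, x, C_m: float):
        """Area per molecule, m^2."""
        return 1.0 / self.Gamma_s_number(x, C_m)

    def x_of_S(self, S: float, C_m: float) -> float:
        """Invert Gamma_s(x) (strictly increasing by construction)."""
        f = lambda x: self.Gamma_s_number(x, C_m) - 1.0 / S
        return brentq(f, -40.0, 10.0, xtol=1e-13)

    # -- analytic ground truth ---------------------------------------------

    def dGamma_el_true(self, x, C_m: float):
        """Monolayer-induced adsorption, mol/m^2 (exact)."""
        if C_m == 0:
            return np.zeros_like(np.asarray(x, float))
        rho_w = water_density(self.params.T)
        return rho_w * C_m * self.G(x) / self.params.p_scale

    def dGamma_el_true_at_S(self, S, C_m: float):
        x = np.array([self.x_of_S(s, C_m) for s in np.atleast_1d(S)])
        out = self.dGamma_el_true(x, C_m)
        return float(out[0]) if np.isscalar(S) else out

    def pi_sp(self, C_m: float) -> float:
        return float(self.pi(0.0, C_m))

    def S_sp(self, C_m: float) -> float:
        return float(self.S_of_x(0.0, C_m))

    def dmu_s_true(self, x):
        """Chemical potential vs the spread state, J/mol."""
        return np.asarray(x, float) * kT(self.params.T) * AVOGADRO

    def interior_maximum_Gamma_s(self, C_m: float) -> float:
        """Gamma_s (mol/m^2) at the analytic maximum of DGamma_el.

        The coupling bump peaks at theta = 1/2, i.e. x = x0.
        """
        return self.Gamma_s_number(self.params.x0, C_m) / AVOGADRO


def build_system(params: Optional[SyntheticParams] = None, *,
                 seed: int = 0) -> SyntheticSystem:
    """Deterministic system construction; ``seed`` drives only the
    sampling noise."""
    p = params or SyntheticParams()
    H_max = 0.0
    st_check = solution_state(_make_spec(p), 3.999, T=p.T)
    H_max = st_check.p_osm / p.p_scale
    if 12.0 * p.g * H_max >= kT(p.T) * p.Gamma_max:
        raise ValueError(
            "coupling amplitude g too large: Gamma_s would turn negative "
            "on the sampled domain (need 12 g H_max < kT Gamma_max)")
    return SyntheticSystem(params=p, spec=_make_spec(p), seed=seed,
                           rng=np.random.default_rng(seed))


def sample_isotherms(system: SyntheticSystem,
                     C_list: Sequence[float] = (0.0, 1.0, 2.0, 3.5),
                     *, n_points: int = 60,
                     x_range: tuple[float, float] = (-5.2, 0.02),
                     noise: Optional[float] = None,
                     surfactant: str = "synthetic-OA",
                     ) -> tuple[list[IsothermCurve], SpreadingSeries]:
    """Tabulate pi(S) per concentration plus the pi_sp(C) series.

    Points are laid out uniformly in the chemical potential between
    ``x_range`` bounds (dilute gas to just past the spread state, so the
    collapse-exclusion logic is exercised).  Optional multiplicative
    Gaussian noise on pi emulates digitization error; all randomness comes
    from the system's seeded generator.
    """
    if 0.0 not in C_list:
        raise ValueError("C_list must include pure water (0.0)")
    if noise is None:
        noise = system.params.noise
    x = np.linspace(x_range[0], x_range[1], n_points)
    curves = []
    for C in sorted(C_list):
        S = np.asarray(system.S_of_x(x, C), dtype=float)
        pi = np.asarray(system.pi(x, C), dtype=float)
        if noise:
            pi = pi * (1.0 + noise * system.rng.standard_normal(pi.shape))
            pi = np.maximum(pi, 0.0)
        curves.append(IsothermCurve(surfactant=surfactant, C_m=float(C),
                                    S=S, pi=pi, T=system.params.T))
    series = SpreadingSeries(
        surfactant=surfactant,
        C_m=np.asarray(sorted(C_list), dtype=float),
        pi_sp=np.array([system.pi_sp(C) for C in sorted(C_list)]))
    return curves, series


def sample_deltaV(system: SyntheticSystem,
                  C_list: Sequence[float] = (0.0, 1.0, 2.0, 3.5),
                  S_grid: Optional[np.ndarray] = None, *,
                  chi0: float | None = None,
                  Lq_ratio: float = 0.5,
                  surfactant: str = "synthetic-EP",
                  ) -> list[VoltaCurve]:
    """Volta curves composed through the forward dipole/double-layer model.

    ``P_s`` per molecule is ``p_molecule_D (1 + p_salt_slope C_m)``;
    ``phi_DL`` is zero or the bare-surface MS prediction, per
    ``params.phi_dl_model``.  Uses the same ``compose_deltaV`` the
    inversions invert (single source of truth).
    """
    from .constants import CHI0_DEFAULT
    if chi0 is None:
        chi0 = CHI0_DEFAULT
    if S_grid is None:
        S_grid = np.geomspace(120e-20, 30e-20, 25)
    p = system.params
    curves = []
    for C in sorted(C_list):
        eps = system.spec.eps(C)
        dchi = float(system.spec.chi_table(C)) if C > 0 else 0.0
        if C > 0 and p.phi_dl_model == "ms":
            st = solution_state(system.spec, C, T=p.T)
            phi_dl = edl_potential_wa(system.spec, st)
        else:
            phi_dl = 0.0
        gamma_number = 1.0 / S_grid
        P_s = (p.p_molecule_D * DEBYE * gamma_number
               * (1.0 + p.p_salt_slope * C))
        dV = compose_deltaV(P_s, phi_dl, dchi, eps, Lq_ratio, chi0=chi0)
        curves.append(VoltaCurve(surfactant=surfactant, C_m=float(C),
                                 S=S_grid.copy(), dV=np.asarray(dV)))
    return curves
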