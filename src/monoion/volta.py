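"""Volta potentials of uncharged monolayers: dipole double layer analysis.

The measured Volta potential change upon spreading a monolayer is the
difference between the surface potential with and without the film::

    DV = Gamma_p / eps0 + phi_DL - chi0 - Dchi(C)

``phi_DL`` is the electric double layer potential of the free ionic
charge; ``Gamma_p/eps0`` the potential of the total normal surface dipole
moment; ``chi0`` the (unmeasurable, conventionally -90 mV) surface
potential of pure water; and ``Dchi(C)`` the electrolyte-induced change of
the bare-solution surface potential (sign convention: solution side
positive up, so a negative ``Dchi`` partially cancels a negative
``phi_DL``).

The total dipole ``Gamma_p = P_s + P_diff`` couples the specifically
adsorbed normal dipole density ``P_s`` (oriented headgroups plus surface
water) to the oppositely polarised diffuse response of the adjacent media.
Quadrupolar electrostatics of the two half-spaces — water with quadrupolar
length ``L_q^w`` and the hydrocarbon-tail "oil" layer with ``L_q^o`` —
gives::

    Gamma_p = P_s (1 + eps r) / (eps (1 + r)),   r = L_q^o / L_q^w

so a vacuum-like medium (eps -> 1) leaves the dipole unscreened while a
higher solution permittivity counter-polarises more strongly.  ``r`` is
roughly 1/2 for a liquid-expanded tail layer and drifts toward 1 as the
layer dilutes; it is a named, overridable constant here.

Since one measured ``DV`` constrains the two unknowns ``P_s`` and
``phi_DL``, two limiting inversions are provided: hold ``P_s`` at its
pure-water value and solve for ``phi_DL``, or hold ``phi_DL`` at the
modified-Schmutzer bare-surface prediction and solve for ``P_s``.
Both invert the same forward composition (single source of truth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .bulk import ElectrolyteSpec, SolutionState
from .constants import (
    CHI0_DEFAULT,
    ELEMENTARY_CHARGE,
    LQ_RATIO_DEFAULT,
    VACUUM_PERMITTIVITY,
)
from .msmodel import edl_potential_wa

__all__ = [
    "VoltaCurve",
    "DipoleLayerState",
    "dipole_screening_factor",
    "total_dipole",
    "compose_deltaV",
    "phi_dl_assuming_fixed_Ps",
    "ps_assuming_ms_phi",
    "charge_density",
    "linear_gouy",
]

DEBYE = 3.33564e-30  # C m


@dataclass
class VoltaCurve:
    """DV(S) at one electrolyte molality.

    ``S`` in m^2/molecule (stored in compression order), ``dV`` in volts,
    ``reproducibility`` the +/- experimental scatter (10 mV default).
    """

    surfactant: str
    C_m: float
    S: np.ndarray
    dV: np.ndarray
    reproducibility: float = 0.010

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        dV = np.asarray(self.dV, dtype=float)
        if S.ndim != 1 or S.shape != dV.shape or S.size < 2:
            raise ValueError("need matching 1-d S and dV arrays")
        if np.any(S <= 0):
            raise ValueError("areas must be positive")
        order = np.argsort(-S)
        self.S = S[order]
        self.dV = dV[order]

    def interp(self) -> PchipInterpolator:
        return PchipInterpolator(self.S[::-1], self.dV[::-1],
                                 extrapolate=False)


@dataclass
class DipoleLayerState:
    """Decomposed dipole/double-layer state at one (Gamma_s, C)."""

    P_s: float        # C/m, specifically adsorbed normal dipole density
    P_diff: float     # C/m, diffuse counter-polarization
    Gamma_p: float    # C/m, total = P_s + P_diff
    phi_DL: float     # V
    dchi: float       # V
    eps: float
    Lq_ratio: float
    chi0: float = CHI0_DEFAULT


def dipole_screening_factor(eps: float, Lq_ratio: float = LQ_RATIO_DEFAULT
                            ) -> float:
    """``Gamma_p / P_s = (1 + eps r)/(eps (1 + r))``, in (0, 1]."""
    if not 0 < Lq_ratio <= 2:
        raise ValueError("Lq_ratio must lie in (0, 2]")
    if eps < 1:
        raise ValueError("relative permittivity must be >= 1")
    return (1.0 + eps * Lq_ratio) / (eps * (1.0 + Lq_ratio))


def total_dipole(P_s: float, eps: float,
                 Lq_ratio: float = LQ_RATIO_DEFAULT) -> float:
    """Total surface dipole moment ``Gamma_p`` (C/m) after diffuse
    counter-polarization of the two quadrupolar media."""
    return P_s * dipole_screening_factor(eps, Lq_ratio)


def compose_deltaV(P_s, phi_DL, dchi, eps, Lq_ratio=LQ_RATIO_DEFAULT, *,
                   chi0: float = CHI0_DEFAULT):
    """Forward model: the measured Volta potential (V).

    Single source of truth — both inversions and the synthetic generator
    call this function.
    """
    f = dipole_screening_factor(eps, Lq_ratio)
    return np.asarray(P_s) * f / VACUUM_PERMITTIVITY + phi_DL - chi0 - dchi


def _check_tables(spec: ElectrolyteSpec) -> None:
    if spec.chi_table is None:
        raise ValueError(
            f"{spec.name}: no Dchi(C) table; the Volta analysis cannot "
            "separate the dipolar and double-layer terms without it")
    if spec.eps_table is None:
        raise ValueError(f"{spec.name}: no eps(C) table")


def ps_from_water_curve(curve0: VoltaCurve, eps_w: float,
                        Lq_ratio: float = LQ_RATIO_DEFAULT, *,
                        chi0: float = CHI0_DEFAULT) -> np.ndarray:
    """``P_s(0, Gamma_s)`` (C/m) from the pure-water DV curve.

    On water there is no ionic double layer and ``Dchi = 0``, so the
    forward model inverts point-by-point.
    """
    f = dipole_screening_factor(eps_w, Lq_ratio)
    return VACUUM_PERMITTIVITY * (curve0.dV + chi0) / f


@dataclass
class InversionResult:
    """Per-point inversion output on the electrolyte curve's area grid."""

    S: np.ndarray          # m^2/molecule
    values: np.ndarray
    uncertainty: np.ndarray
    assumption: str


def phi_dl_assuming_fixed_Ps(curveC: VoltaCurve, curve0: VoltaCurve,
                             spec: ElectrolyteSpec, state: SolutionState,
                             Lq_ratio: float = LQ_RATIO_DEFAULT, *,
                             eps_water: Optional[float] = None,
                             chi0: float = CHI0_DEFAULT) -> InversionResult:
    """Double-layer potential under ``P_s(C, Gamma_s) = P_s(0, Gamma_s)``.

    Solves the forward model for ``phi_DL`` on the common area range of
    the two curves; the +/- reproducibility of both DV measurements is
    propagated in quadrature.
    """
    _check_tables(spec)
    if eps_water is None:
        eps_water = spec.eps(0.0)
    dchi = float(spec.chi_table(state.C_m))
    mask = (curveC.S >= curve0.S.min() - 1e-30) & \
           (curveC.S <= curve0.S.max() + 1e-30)
    if not np.any(mask):
        raise ValueError("curves share no common area range")
    S = curveC.S[mask]
    dV_C = curveC.dV[mask]
    dV_0 = np.asarray(curve0.interp()(S), dtype=float)
    ratio = (dipole_screening_factor(state.eps, Lq_ratio)
             / dipole_screening_factor(eps_water, Lq_ratio))
    phi = dV_C + chi0 + dchi - ratio * (dV_0 + chi0)
    sigma = np.hypot(curveC.reproducibility,
                     ratio * curve0.reproducibility)
    return InversionResult(S=S, values=phi,
                           uncertainty=np.full_like(phi, 1.0) * sigma,
                           assumption="P_s fixed at pure-water value")


def ps_assuming_ms_phi(curveC: VoltaCurve, curve0: VoltaCurve,
                       spec: ElectrolyteSpec, state: SolutionState,
                       Lq_ratio: float = LQ_RATIO_DEFAULT, *,
                       chi0: float = CHI0_DEFAULT,
                       phi_DL: Optional[float] = None) -> InversionResult:
    """Dipole moment per molecule (Debye) with ``phi_DL`` held at the
    bare-surface modified-Schmutzer value.

    ``P_s/Gamma_s`` is undefined at ``Gamma_s = 0``; such points are
    dropped.  ``curve0`` is accepted for interface symmetry with the other
    inversion (the pure-water ``P_s`` needs no monolayer-free reference).
    """
    _check_tables(spec)
    del curve0
    if phi_DL is None:
        phi_DL = edl_potential_wa(spec, state)
    dchi = float(spec.chi_table(state.C_m))
    f = dipole_screening_factor(state.eps, Lq_ratio)
    finite = np.isfinite(curveC.S)
    S = curveC.S[finite]
    P_s = VACUUM_PERMITTIVITY * (curveC.dV[finite] + chi0 + dchi - phi_DL) / f
    gamma_number = 1.0 / S  # molecules per m^2
    per_molecule_debye = P_s / gamma_number / DEBYE
    sigma = (VACUUM_PERMITTIVITY * curveC.reproducibility / f
             / gamma_number / DEBYE)
    return InversionResult(S=S, values=per_molecule_debye,
                           uncertainty=sigma,
                           assumption="phi_DL fixed at MS bare-surface value")


def charge_density(dGamma_ion: float, z: int) -> float:
    """Free surface charge density ``sigma = z e dGamma`` (C/m^2).

    ``dGamma_ion`` is the potential-determining ion's excess as a number
    density per m^2; ``z`` its signed valence.
    """
    return z * ELEMENTARY_CHARGE * dGamma_ion


def linear_gouy(sigma_free: float, state: SolutionState, *,
                warn_above: float = 0.025) -> float:
    """Linearised Gouy-Chapman potential ``dphi = sigma L_D/(eps0 eps)``.

    First-order exact in the charge; warns when the predicted potential
    leaves the linear regime (|dphi| > 25 mV).
    """
    dphi = sigma_free * state.L_D / (VACUUM_PERMITTIVITY * state.eps)
    if abs(dphi) > warn_above:
        warnings.warn(
            f"|dphi| = {abs(dphi) * 1e3:.0f} mV exceeds the linear-Gouy "
            "regime", stacklevel=2)
    return dphi
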