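"""Dividing-plane conversions for monolayer-induced adsorption.

``DGamma_el`` from the isotherm analysis refers to water's equimolecular
dividing surface, whose position relative to the physical (dielectric)
surface moves both with electrolyte concentration and with monolayer
density: the surfactant headgroups expel water from the surface layer,
shifting the equimolecular plane toward the solution and mimicking an ion
adsorption.  The sign of the ion/monolayer interaction is therefore read
at the plane of the permittivity discontinuity::

    DGamma_el^eps = (1 - C_el,M V_el) DGamma_el - C_el,M V_s Gamma_s

The first factor is the electrolyte-induced shift of the equimolecular
plane (``V_el`` may be of either sign); the second, linear in ``Gamma_s``,
is the headgroup "osmotic" term with ``V_s`` the partial molar volume of
the polar group below the dielectric surface.  ``V_s`` is data, not
computed: for a carboxylic headgroup the admissible range is bracketed by
the -OH moiety (18 mL/mol, the molar volume of water) and the full -COOH
(35 mL/mol, partial molar volume of formic acid), with 32 mL/mol as the
central estimate; results are reported as a band over those bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bulk import ElectrolyteSpec, SolutionState
from .isotherm import AdsorptionProfile

__all__ = [
    "SurfactantSpec",
    "PlaneConvertedProfile",
    "to_eps_plane",
    "from_eps_plane",
    "eps_plane_band",
]


@dataclass(frozen=True)
class SurfactantSpec:
    """An insoluble nonionic surfactant.

    ``V_s_bounds = (low, central, high)`` in m^3/mol; ``collapse_area`` in
    m^2/molecule.
    """

    name: str
    headgroup: str
    V_s_bounds: tuple[float, float, float] = (18e-6, 32e-6, 35e-6)
    collapse_area: float = 27.6e-20

    def __post_init__(self) -> None:
        lo, mid, hi = self.V_s_bounds
        if not (0 < lo <= mid <= hi):
            raise ValueError(f"{self.name}: V_s bounds must satisfy "
                             "0 < low <= central <= high")
        if self.collapse_area <= 0:
            raise ValueError(f"{self.name}: collapse area must be positive")

    @property
    def V_s(self) -> float:
        return self.V_s_bounds[1]


def _el_factor(spec: ElectrolyteSpec, state: SolutionState) -> float:
    factor = 1.0 - state.C_M * spec.V_el
    if factor <= 0:
        raise ValueError(
            f"{spec.name}: C_el,M V_el = {state.C_M * spec.V_el:.3f} >= 1 "
            "is nonphysical")
    return factor


def to_eps_plane(dGamma_el, Gamma_s, surf: SurfactantSpec,
                 spec: ElectrolyteSpec, state: SolutionState, *,
                 V_s: float | None = None):
    """Convert ``DGamma_el`` (equimolecular plane) to the eps plane.

    All inputs at the same concentration; arrays broadcast.  ``V_s``
    defaults to the surfactant's central value.
    """
    if V_s is None:
        V_s = surf.V_s
    dG = np.asarray(dGamma_el, dtype=float)
    G = np.asarray(Gamma_s, dtype=float)
    out = _el_factor(spec, state) * dG - state.C_M * V_s * G
    return float(out) if np.isscalar(dGamma_el) else out


def from_eps_plane(dGamma_eps, Gamma_s, surf: SurfactantSpec,
                   spec: ElectrolyteSpec, state: SolutionState, *,
                   V_s: float | None = None):
    """Inverse of :func:`to_eps_plane` (exact)."""
    if V_s is None:
        V_s = surf.V_s
    dGe = np.asarray(dGamma_eps, dtype=float)
    G = np.asarray(Gamma_s, dtype=float)
    out = (dGe + state.C_M * V_s * G) / _el_factor(spec, state)
    return float(out) if np.isscalar(dGamma_eps) else out


@dataclass
class PlaneConvertedProfile:
    """DGamma_el^eps with its V_s uncertainty band.

    ``sign_class`` per grid point: ``+1`` (attraction relative to the bare
    surface for every admissible V_s), ``-1`` (depletion for every V_s),
    ``0`` (sign-indeterminate within the band).
    """

    surfactant: str
    C_m: float
    Gamma_s: np.ndarray
    low: np.ndarray
    central: np.ndarray
    high: np.ndarray
    V_el: float
    C_M: float

    @property
    def sign_class(self) -> np.ndarray:
        # larger V_s subtracts more: 'low' bound uses V_s low -> upper curve
        upper = np.maximum(self.low, self.high)
        lower = np.minimum(self.low, self.high)
        out = np.zeros_like(self.central, dtype=int)
        out[lower > 0] = 1
        out[upper < 0] = -1
        return out

    @property
    def sign_indeterminate(self) -> np.ndarray:
        return self.sign_class == 0


def eps_plane_band(profile: AdsorptionProfile, surf: SurfactantSpec,
                   spec: ElectrolyteSpec,
                   state: SolutionState) -> PlaneConvertedProfile:
    """Convert an adsorption profile with the full ``V_s`` band.

    Three curves (low/central/high ``V_s``); the band collapses to a point
    when the bounds coincide, and widens linearly with ``Gamma_s`` (the
    osmotic term dominates the uncertainty).
    """
    lo, mid, hi = surf.V_s_bounds
    curves = {
        V_s: to_eps_plane(profile.dGamma_el, profile.Gamma_s, surf, spec,
                          state, V_s=V_s)
        for V_s in (lo, mid, hi)}
    return PlaneConvertedProfile(
        surfactant=profile.surfactant, C_m=profile.C_m,
        Gamma_s=profile.Gamma_s.copy(), low=curves[lo], central=curves[mid],
        high=curves[hi], V_el=spec.V_el, C_M=state.C_M)
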