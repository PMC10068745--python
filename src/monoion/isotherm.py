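"""Monolayer-induced electrolyte adsorption from tensiometric data.

The central thermodynamic object is the surface-pressure differential of a
monolayer-covered electrolyte solution::

    d pi = Gamma_s d mu_s + nu DGamma_el d mu_el            (*)

where ``Gamma_s`` is the surfactant surface density, ``mu_s`` its chemical
potential, and ``DGamma_el`` the *monolayer-induced* electrolyte adsorption
— the extra electrolyte surface excess relative to the bare surface at the
same ``mu_el``.  Two independent inversions of (*) extract
``DGamma_el(Gamma_s)`` from families of pi(S) isotherms measured at several
electrolyte molalities, supplemented by equilibrium spreading pressures
``pi_sp(C)``:

route A (iso-chemical-potential, after Pankratov and Frumkin)
    ``DGamma_el = rho_w C_el,m (d pi / d p_osm)`` at fixed ``mu_s``;

route B (isobaric)
    ``DGamma_el = -Gamma_s rho_w C_el,m (d mu_s / d p_osm)`` at fixed pi,

both using the Gibbs-Duhem link ``d mu_el = d p_osm / (rho_w C_el,m)``
(formula-unit convention, see :mod:`monoion.bulk`).  The surfactant
chemical potential relative to the equilibrium spread monolayer — whose
``mu_s,sp`` is taken independent of electrolyte since the bulk surfactant
phase is unaffected by it — follows from isotherm integration::

    Dmu_s(pi) = - N_A \\int_pi^{pi_sp} S(pi') dpi'        (J/mol)

On thermodynamically consistent data the two routes agree identically
(a Maxwell relation of (*)); their residual discrepancy measures the
mutual consistency of the pi(S) and pi_sp(C) data sets.

Internal units are SI: S in m^2/molecule, pi in N/m, Gamma in mol/m^2,
mu in J/mol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

from .bulk import ElectrolyteSpec, SolutionState, solution_state
from .constants import AVOGADRO, GAS_CONSTANT, T_DEFAULT, water_density

logger = logging.getLogger(__name__)

__all__ = [
    "IsothermCurve",
    "SpreadingSeries",
    "ChemicalPotentialField",
    "AdsorptionProfile",
    "SpreadStateAdsorption",
    "correct_plateau",
    "spreading_area",
    "interpolate_spreading_pressure",
    "surfactant_chemical_potential",
    "build_field",
    "induced_adsorption_spread",
    "induced_adsorption_isochemical",
    "induced_adsorption_isobaric",
    "route_consistency",
]


@dataclass
class IsothermCurve:
    """A pi(S) compression isotherm at one electrolyte molality.

    ``S`` (m^2/molecule) is stored in compression order (strictly
    decreasing); ``pi`` in N/m.
    """

    surfactant: str
    C_m: float
    S: np.ndarray
    pi: np.ndarray
    T: float = T_DEFAULT
    plateau_corrected: bool = False
    truncated_at_collapse: bool = False
    original_pi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if S.ndim != 1 or S.shape != pi.shape or S.size < 3:
            raise ValueError("need matching 1-d S and pi arrays (>=3 points)")
        order = np.argsort(-S)
        self.S = S[order]
        self.pi = pi[order]
        if np.any(np.diff(self.S) >= 0):
            raise ValueError("areas per molecule must be distinct")
        if np.any(self.pi < -1e-12):
            raise ValueError("surface pressure must be non-negative")

    @property
    def Gamma_s(self) -> np.ndarray:
        """Surfactant surface density, mol/m^2."""
        return 1.0 / (self.S * AVOGADRO)

    @property
    def is_monotone(self) -> bool:
        """pi non-decreasing under compression (decreasing S)."""
        return bool(np.all(np.diff(self.pi) >= -1e-12))


@dataclass
class SpreadingSeries:
    """Equilibrium spreading pressures pi_sp (N/m) vs molality."""

    surfactant: str
    C_m: np.ndarray
    pi_sp: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C_m, dtype=float)
        p = np.asarray(self.pi_sp, dtype=float)
        if C.shape != p.shape or C.ndim != 1:
            raise ValueError("need matching 1-d arrays")
        if np.unique(C).size != C.size:
            raise ValueError("one entry per concentration")
        order = np.argsort(C)
        self.C_m = C[order]
        self.pi_sp = p[order]
        if np.any(self.pi_sp <= 0):
            raise ValueError("pi_sp must be positive")

    @property
    def reference(self) -> float:
        """pi_sp on pure water (C_m = 0)."""
        if self.C_m[0] != 0.0:
            raise ValueError("series lacks the C_m = 0 reference")
        return float(self.pi_sp[0])


def correct_plateau(curve: IsothermCurve, *,
                    warn_fraction: float = 0.3) -> IsothermCurve:
    """Enforce thermodynamic admissibility of a digitized isotherm.

    A first-order 2D phase transition shows as a flat plateau in pi(S); in
    practice digitized plateaus tilt slightly (a kinetic capillary
    artefact).  The least-squares monotone (isotonic) projection of pi onto
    the cone {pi non-decreasing under compression} flattens exactly the
    offending region — pool-adjacent-violators produces constant pools —
    and leaves admissible curves untouched.  Original pressures are kept in
    ``original_pi``.
    """
    if curve.is_monotone:
        return replace(curve, plateau_corrected=True,
                       original_pi=curve.pi.copy())
    iso = IsotonicRegression(increasing=True)
    # compression order: pi non-decreasing as S decreases; only the point
    # ordering matters, so fit against ranks (metre-scale abscissae are
    # collapsed as duplicates by the isotonic unique-x preprocessing)
    pi_fit = iso.fit_transform(np.arange(curve.pi.size), curve.pi)
    n_changed = int(np.sum(np.abs(pi_fit - curve.pi) > 1e-12))
    if n_changed > warn_fraction * curve.pi.size:
        warnings.warn(
            f"plateau correction modified {n_changed}/{curve.pi.size} "
            "points; the digitization may be unreliable", stacklevel=2)
    logger.info("plateau correction: %d/%d points projected",
                n_changed, curve.pi.size)
    return replace(curve, pi=pi_fit, plateau_corrected=True,
                   original_pi=curve.pi.copy())


def spreading_area(curve: IsothermCurve, pi_sp: float, *,
                   k_points: int = 3) -> float:
    """Area per molecule ``S_sp`` (m^2) of the equilibrium spread monolayer.

    The dense 2D phase near collapse is elastically linear, so a
    least-squares line through the last ``k_points`` (2-4) measured points
    is extrapolated to its intersection with ``pi = pi_sp``.
    """
    if not 2 <= k_points <= 4:
        raise ValueError("k_points must be 2-4")
    if curve.pi.max() < 0.8 * pi_sp:
        raise ValueError(
            f"isotherm tops out at {curve.pi.max():.4g} N/m, more than 20% "
            f"below pi_sp = {pi_sp:.4g} N/m; extrapolation unsafe")
    S_tail = curve.S[-k_points:]
    pi_tail = curve.pi[-k_points:]
    slope, intercept = np.polyfit(S_tail, pi_tail, 1)
    if slope >= 0:
        raise ValueError("non-compressive tail: pi does not rise as S "
                         "shrinks over the last points")
    S_sp = (pi_sp - intercept) / slope
    if S_sp <= 0:
        raise ValueError(f"extrapolated S_sp = {S_sp:.3g} m^2 <= 0")
    span = curve.S.max() - curve.S.min()
    if abs(S_sp - S_tail[-1]) > 0.25 * span:
        warnings.warn("S_sp extrapolation exceeds 25% of the data span",
                      stacklevel=2)
    return float(S_sp)


def interpolate_spreading_pressure(series: SpreadingSeries,
                                   spec: ElectrolyteSpec, C_m: float, *,
                                   T: float = T_DEFAULT,
                                   allow_extrapolation: bool = False) -> float:
    """pi_sp at molality ``C_m``, linearly interpolated in osmotic pressure.

    Osmotic pressure, not molality or activity, linearizes spreading
    pressures across electrolytes, so the interpolation abscissa is
    ``p_osm(C_m)``.
    """
    if series.C_m.size < 2 or series.C_m[0] != 0.0:
        raise ValueError("series needs the C_m = 0 reference and at least "
                         "one electrolyte point")
    p_knots = np.array([
        solution_state(spec, c, T=T).p_osm if c > 0 else 0.0
        for c in series.C_m])
    p_query = solution_state(spec, C_m, T=T).p_osm if C_m > 0 else 0.0
    if p_query > p_knots[-1] + 1e-9:
        if not allow_extrapolation:
            raise ValueError(
                f"C_m = {C_m} lies outside the series hull; pass "
                "allow_extrapolation=True to extrapolate the linear trend")
        slope = np.polyfit(p_knots, series.pi_sp, 1)[0]
        return float(series.pi_sp[-1] + slope * (p_query - p_knots[-1]))
    return float(np.interp(p_query, p_knots, series.pi_sp))


@dataclass
class MuInterpolant:
    """Dmu_s(pi) for one curve, with its inverse pi(Dmu_s)."""

    pi: np.ndarray       # strictly increasing grid, N/m
    dmu: np.ndarray      # J/mol, 0 at pi_sp
    S_of_pi: PchipInterpolator
    _fwd: PchipInterpolator = field(init=False, repr=False)
    _inv: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._fwd = PchipInterpolator(self.pi, self.dmu, extrapolate=False)
        self._inv = PchipInterpolator(self.dmu, self.pi, extrapolate=False)

    def dmu_at(self, pi):
        return self._fwd(pi)

    def pi_at(self, dmu):
        return self._inv(dmu)

    @property
    def dmu_min(self) -> float:
        return float(self.dmu[0])


def surfactant_chemical_potential(curve: IsothermCurve, pi_sp: float,
                                  S_sp: float) -> MuInterpolant:
    """Integrate the corrected isotherm to ``Dmu_s(pi)`` (J/mol).

    Trapezoid rule over the measured points of ``S(pi)`` from the spread
    reference ``(pi_sp, S_sp)`` down to each pressure; zero at the
    reference, negative below it.  Points above ``pi_sp`` (observed only
    past collapse) are excluded and logged.  Plateau ties (equal pi)
    contribute nothing to the integral, exactly as a first-order
    transition must.
    """
    if not curve.is_monotone:
        raise ValueError("isotherm is not thermodynamically admissible; "
                         "run correct_plateau first")
    keep = curve.pi <= pi_sp + 1e-12
    n_excluded = int(np.sum(~keep))
    if n_excluded:
        logger.info("excluding %d points above pi_sp from integration",
                    n_excluded)
    S = np.concatenate((curve.S[keep], [S_sp]))
    pi = np.concatenate((curve.pi[keep], [pi_sp]))
    order = np.argsort(pi)
    S, pi = S[order], pi[order]
    # cumulative trapezoid of S dpi, anchored at pi_sp (the last point)
    seg = 0.5 * (S[1:] + S[:-1]) * np.diff(pi)
    integral_from_top = np.concatenate(
        (-np.cumsum(seg[::-1])[::-1], [0.0]))  # \int_pi^{pi_sp} S dpi, >=0
    dmu = AVOGADRO * integral_from_top  # negative below pi_sp
    # deduplicate plateau ties for interpolation (integral already exact)
    pi_u, idx = np.unique(pi, return_index=True)
    dmu_u = dmu[idx]
    S_u = S[idx]
    return MuInterpolant(pi=pi_u, dmu=dmu_u,
                         S_of_pi=PchipInterpolator(pi_u, S_u,
                                                   extrapolate=False))


@dataclass
class ConcentrationSlice:
    curve: IsothermCurve
    state: Optional[SolutionState]  # None for pure water
    pi_sp: float
    S_sp: float
    mu: MuInterpolant

    @property
    def p_osm(self) -> float:
        return 0.0 if self.state is None else self.state.p_osm

    @property
    def C_m(self) -> float:
        return self.curve.C_m


@dataclass
class ChemicalPotentialField:
    """Dmu_s over (Gamma_s, C_m): one integrated slice per molality."""

    surfactant: str
    spec: ElectrolyteSpec
    slices: list[ConcentrationSlice]
    T: float = T_DEFAULT

    @property
    def C_values(self) -> np.ndarray:
        return np.array([s.C_m for s in self.slices])

    def slice_at(self, C_m: float) -> ConcentrationSlice:
        for s in self.slices:
            if s.C_m == C_m:
                return s
        raise KeyError(f"no slice at C_m = {C_m}")


def build_field(curves: Sequence[IsothermCurve], series: SpreadingSeries,
                spec: ElectrolyteSpec, *, k_points: int = 3,
                apply_plateau_correction: bool = True,
                T: float = T_DEFAULT) -> ChemicalPotentialField:
    """Assemble the chemical-potential field for a family of isotherms.

    Per concentration: interpolate ``pi_sp`` (linear in osmotic pressure),
    extrapolate ``S_sp`` from the elastic tail, correct the plateau if
    requested, and integrate to ``Dmu_s(pi)``.
    """
    if len(curves) < 2:
        raise ValueError("need isotherms at >= 2 concentrations")
    slices = []
    for curve in sorted(curves, key=lambda c: c.C_m):
        if apply_plateau_correction and not curve.plateau_corrected:
            curve = correct_plateau(curve)
        pi_sp = interpolate_spreading_pressure(series, spec, curve.C_m, T=T)
        S_sp = spreading_area(curve, pi_sp, k_points=k_points)
        mu = surfactant_chemical_potential(curve, pi_sp, S_sp)
        state = (solution_state(spec, curve.C_m, T=T)
                 if curve.C_m > 0 else None)
        slices.append(ConcentrationSlice(curve=curve, state=state,
                                         pi_sp=pi_sp, S_sp=S_sp, mu=mu))
    if slices[0].C_m != 0.0:
        raise ValueError("the family must include the C_m = 0 isotherm")
    return ChemicalPotentialField(surfactant=curves[0].surfactant,
                                  spec=spec, slices=slices, T=T)


@dataclass
class AdsorptionProfile:
    """DGamma_el(Gamma_s) extracted by one route, SI units.

    ``Gamma_s`` in mol/m^2 (grid of the target-concentration curve,
    anchored at the exact point ``DGamma_el(0) = 0``), ``dGamma_el`` in
    mol/m^2, evaluated at molality ``C_m``.
    """

    route: str
    surfactant: str
    C_m: float
    Gamma_s: np.ndarray
    dGamma_el: np.ndarray

    @property
    def dGamma_el_nm2(self) -> np.ndarray:
        """Display units: molecules (formula units) per nm^2."""
        return self.dGamma_el * AVOGADRO / 1e18

    @property
    def Gamma_s_nm2(self) -> np.ndarray:
        return self.Gamma_s * AVOGADRO / 1e18

    def interior_maximum(self) -> tuple[float, float]:
        """(Gamma_s, DGamma_el) at the profile's maximum."""
        i = int(np.argmax(self.dGamma_el))
        return float(self.Gamma_s[i]), float(self.dGamma_el[i])


@dataclass
class SpreadStateAdsorption:
    """DGamma_el of the equilibrium spread monolayer (the 'star' points)."""

    surfactant: str
    slope: float                 # d(Dpi_sp)/d(p_osm), dimensionless x m
    C_m: np.ndarray
    dGamma_el: np.ndarray        # mol/m^2 per concentration

    @property
    def dGamma_el_nm2(self) -> np.ndarray:
        return self.dGamma_el * AVOGADRO / 1e18


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope through all points (with intercept)."""
    if x.size < 2:
        raise ValueError("need at least two concentrations for the slope")
    return float(np.polyfit(x, y, 1)[0])


def induced_adsorption_spread(series: SpreadingSeries,
                              spec: ElectrolyteSpec, *,
                              T: float = T_DEFAULT) -> SpreadStateAdsorption:
    """Route of Eq (*) at the spread state: ``DGamma_el = rho_w C_m s``
    with ``s`` the global least-squares slope of ``Dpi_sp`` vs ``p_osm``.

    Valid because ``mu_s,sp`` is electrolyte-independent, so the whole
    ``pi_sp(C)`` series sits at constant ``mu_s``.
    """
    if series.C_m.size < 2:
        raise ValueError("need pi_sp at >= 2 concentrations (incl. water)")
    pi0 = series.reference
    p_osm = np.array([
        solution_state(spec, c, T=T).p_osm if c > 0 else 0.0
        for c in series.C_m])
    slope = _ols_slope(p_osm, series.pi_sp - pi0)
    rho_w = water_density(T)
    dG = rho_w * series.C_m * slope
    return SpreadStateAdsorption(surfactant=series.surfactant, slope=slope,
                                 C_m=series.C_m.copy(), dGamma_el=dG)


def _common_target(field: ChemicalPotentialField,
                   C_target: Optional[float]) -> ConcentrationSlice:
    if C_target is None:
        C_target = float(field.C_values.max())
    if C_target <= 0:
        raise ValueError("target molality must be positive")
    return field.slice_at(C_target)


def induced_adsorption_isochemical(field: ChemicalPotentialField, *,
                                   C_target: Optional[float] = None,
                                   n_levels: int = 60) -> AdsorptionProfile:
    """Route A: compare pressures at matched surfactant chemical potential.

    For each ``Dmu_s`` level in the overlap of all slices, read ``pi`` on
    every slice, fit ``pi`` vs ``p_osm`` by least squares, and convert the
    slope: ``DGamma_el = rho_w C_m (dpi/dp_osm)_{mu_s}``.  Reported on the
    ``Gamma_s`` grid of the target-concentration slice, anchored at
    ``DGamma_el(Gamma_s = 0) = 0``.
    """
    target = _common_target(field, C_target)
    lo = max(s.mu.dmu_min for s in field.slices)
    hi = 0.0
    if lo >= hi:
        raise ValueError("no overlapping Dmu_s range between slices")
    worst = min(s.mu.dmu_min for s in field.slices)
    if lo > worst + 1e-9:
        warnings.warn("Dmu_s ranges only partially overlap; domain clipped",
                      stacklevel=2)
    levels = np.linspace(lo * (1 - 1e-9), hi, n_levels)
    p_osm = np.array([s.p_osm for s in field.slices])
    pi_matrix = np.vstack([np.asarray(s.mu.pi_at(levels), dtype=float)
                           for s in field.slices])
    slopes = np.polyfit(p_osm, pi_matrix, 1)[0]
    rho_w = water_density(field.T)
    dG = rho_w * target.C_m * slopes
    pi_ref = np.asarray(target.mu.pi_at(levels), dtype=float)
    S_ref = np.asarray(target.mu.S_of_pi(pi_ref), dtype=float)
    Gamma_s = 1.0 / (S_ref * AVOGADRO)
    order = np.argsort(Gamma_s)
    Gamma_s, dG = Gamma_s[order], dG[order]
    return AdsorptionProfile(
        route="iso-mu (A)", surfactant=field.surfactant, C_m=target.C_m,
        Gamma_s=np.concatenate(([0.0], Gamma_s)),
        dGamma_el=np.concatenate(([0.0], dG)))


def induced_adsorption_isobaric(field: ChemicalPotentialField, *,
                                C_target: Optional[float] = None,
                                n_levels: int = 60) -> AdsorptionProfile:
    """Route B: compare chemical potentials at matched surface pressure.

    For each pi level in the overlap, read ``Dmu_s`` on every slice, fit
    vs ``p_osm``, and convert:
    ``DGamma_el = -Gamma_s rho_w C_m (dDmu_s/dp_osm)_pi``.
    """
    target = _common_target(field, C_target)
    lo = max(s.mu.pi[0] for s in field.slices)
    hi = min(s.mu.pi[-1] for s in field.slices)
    if lo >= hi:
        raise ValueError("no overlapping pressure range between slices")
    levels = np.linspace(lo, hi, n_levels)
    p_osm = np.array([s.p_osm for s in field.slices])
    dmu_matrix = np.vstack([np.asarray(s.mu.dmu_at(levels), dtype=float)
                            for s in field.slices])
    slopes = np.polyfit(p_osm, dmu_matrix, 1)[0]
    rho_w = water_density(field.T)
    S_ref = np.asarray(target.mu.S_of_pi(levels), dtype=float)
    Gamma_s = 1.0 / (S_ref * AVOGADRO)
    dG = -Gamma_s * rho_w * target.C_m * slopes
    order = np.argsort(Gamma_s)
    Gamma_s, dG = Gamma_s[order], dG[order]
    return AdsorptionProfile(
        route="iso-pi (B)", surfactant=field.surfactant, C_m=target.C_m,
        Gamma_s=np.concatenate(([0.0], Gamma_s)),
        dGamma_el=np.concatenate(([0.0], dG)))


@dataclass
class RouteDiscrepancy:
    max_rel: float
    mean_rel: float
    flagged: bool


def route_consistency(profileA: AdsorptionProfile,
                      profileB: AdsorptionProfile, *,
                      flag_threshold: float = 0.10) -> RouteDiscrepancy:
    """Max and mean |A - B| over the common ``Gamma_s`` range.

    Differences are normalised by the largest |DGamma_el| of either
    profile (a pointwise ratio diverges at the ``Gamma_s -> 0`` anchor
    where both routes vanish).  A discrepancy above ``flag_threshold``
    signals thermodynamically incompatible input data.
    """
    lo = max(profileA.Gamma_s[0], profileB.Gamma_s[0])
    hi = min(profileA.Gamma_s[-1], profileB.Gamma_s[-1])
    if lo >= hi:
        raise ValueError("profiles do not overlap in Gamma_s")
    g = np.linspace(lo, hi, 200)
    a = np.interp(g, profileA.Gamma_s, profileA.dGamma_el)
    b = np.interp(g, profileB.Gamma_s, profileB.dGamma_el)
    scale = max(np.abs(a).max(), np.abs(b).max())
    if scale == 0:
        return RouteDiscrepancy(0.0, 0.0, False)
    rel = np.abs(a - b) / scale
    return RouteDiscrepancy(max_rel=float(rel.max()),
                            mean_rel=float(rel.mean()),
                            flagged=bool(rel.max() > flag_threshold))


def dmu_in_kT(dmu_J_per_mol, T: float = T_DEFAULT):
    """Convert Dmu_s from J/mol to kT per molecule (display units)."""
    return np.asarray(dmu_J_per_mol) / (GAS_CONSTANT * T)
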