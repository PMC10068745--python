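# Methods

This note records the models implemented in `monoion`, their assumptions,
the defaults and why, the numerical choices, and what the synthetic-data
tests do and do not establish about real data.

## Conventions and units

All internal computation is SI (m, Pa, J/mol, mol/m³, V); presentation
helpers convert to the field's customary units (Å² per molecule, mN/m,
nm⁻², mV, mol/kg). The electrolyte chemical potential is carried in the
formula-unit convention, μ_el = μ° + νRT ln(γ_el C_m), paired with
dσ = −Γ_el dμ_el and the Gibbs–Duhem link dμ_el = dp_osm/(ρ_w C_m). The
equivalent mean-ion convention (μ divided by ν, with ν reappearing in the
other two relations) gives identical observables; the formula-unit pairing
was chosen so that no stoichiometric factor floats between equations.
Surface excesses Γ are per formula unit of electrolyte, so Γ_k = ν_k Γ_el
for each ion.

## Bulk solutions

Activities are inputs, never predicted: mean activity coefficients come
from tabulated data (or the synthetic closed form) interpolated with a
monotone piecewise cubic (PCHIP) on ln γ, anchored exactly at the
infinite-dilution limit γ(0) = 1. Extrapolation beyond a table is refused
unless the table is explicitly flagged. The osmotic coefficient follows
from Gibbs–Duhem integration, written by parts so only interpolant values
are integrated: φ(m) = 1 + ln γ(m) − (1/m)∫₀^m ln γ dm′. Osmotic pressure
is p_osm = φνRTρ_w C_m (van 't Hoff × osmotic coefficient). Molality →
molarity uses the mass balance C_M = C_m ρ_sol/(1 + C_m M_el) with a
linear density model per electrolyte; without one, the pure-water density
is used and logged (adequate below ~0.5 mol/kg). Debye and Bjerrum lengths
are the SI forms with the molar ionic strength; the solution permittivity
ε(C) enters both. Water density vs temperature is a small built-in table
(linear interpolation); T defaults to 293.15 K, the temperature of the
historical monolayer experiments.

## The depletion model of the bare surface

Assumptions: (i) a monovalent ion keeps one complete hydration shell at
the surface, a di-/trivalent ion two, reflecting the one vs. two strong
peaks of the ion–water radial distribution function; (ii) the
permittivity discontinuity sits in the middle of the last water layer
(the hydrophobic gap is about one water radius); (iii) beyond the
resulting hard wall at R_i = R₀ + 2nR_w − R_w, the ion feels the screened
image potential W_i(x) = z_i²kT(L_B/4x)e^(−2x/L_D). Linearising the
Boltzmann factor in W and imposing electroneutrality of the whole profile
gives the closed-form excess quoted in the README; the electroneutral
combination of per-ion excesses reduces *exactly* to the stoichiometric
mean because (ν₊+ν₋)z₊z₋ = q(z₊+z₋) for q = ν₊z₊ = ν₋z₋. The E₁ terms are
evaluated with `scipy.special.exp1` (checked against adaptive quadrature
to 1e-10 in the tests).

The unequal depletion thicknesses leave a slab between R_s and R_b
populated only by the smaller ion. Solving the linear Poisson–Boltzmann
equation with that fixed charge and screening beyond R_b gives the
surface potential φ = ±(z_s e ν_s C_M N_A/ε₀ε)(R_b−R_s)(L_D+(R_b−R_s)/2),
signed by the polarity of the smaller ion. For a degenerate equal-radius
pair the gap is zero and the sign convention is irrelevant.

σ(C) is obtained by trapezoid integration of dσ = −Γ_el dμ_el on a
log-spaced inner molality grid, doubled until the change is below 0.1%
(configurable); the dilute tail below the grid start contributes O(C_lo)
and is dropped. A finite-difference check that dσ/dμ_el returns −Γ_el to
1% is part of the test suite.

Ion radii are data, not code: the shipped registry carries
Goldschmidt-type crystallographic radii, and the ~0.1 Å spread between
literature radius scales is part of the model's input uncertainty. Ions
with R₀ ≥ 2 Å (I⁻, SCN⁻, and H₃O⁺ by behaviour) adsorb specifically
("sticky") and are outside the depletion model; constructing them only
raises a warning so mixed data sets can still be loaded.

## Isotherm inversion

The analysis assumes: insoluble surfactant (no exchange with the bulk),
full dissociation of the electrolyte, an uncharged monolayer (acidified
subphase for fatty acids; hydrolyzing salts such as KSCN, Na₂SO₄, MgSO₄
trigger a warning and should be excluded), and an electrolyte-independent
chemical potential of the equilibrium spread monolayer μ_s,sp (the bulk
surfactant phase is unaffected by the aqueous salt). A configuration
switch can perturb μ_s,sp for sensitivity analysis.

Numerical choices, in pipeline order:

* **Plateau correction.** Digitized first-order-transition plateaus tilt
  slightly (a kinetic 2D-capillary artefact). Admissibility (π
  non-decreasing under compression) is restored by least-squares monotone
  projection — isotonic regression, whose pool-adjacent-violators
  solution flattens exactly the offending region at the equal-deviation
  level. The original points are retained; modifying more than 30% of a
  curve triggers a bad-digitization warning. The projection is isolated
  behind one function so a different recipe can be swapped in.
* **π_sp interpolation.** Spreading pressures are interpolated *linearly
  in osmotic pressure*, the variable that linearizes π_sp data across
  electrolytes (the slope is proportional to ΔΓ_el/C_m, which is nearly
  constant in the relevant range). Extrapolation requires an explicit
  flag.
* **S_sp extrapolation.** The dense 2D phase near collapse is elastically
  linear; a least-squares line through the last k points (default 3,
  allowed 2–4) is intersected with π = π_sp. Extrapolating beyond 25% of
  the data span warns; a curve topping out more than 20% below π_sp is
  refused.
* **Δμ_s integration.** Trapezoid over the measured (π, S) points plus
  the (π_sp, S_sp) endpoint, from the spread reference downward. Points
  above π_sp (past collapse) are excluded and logged. Plateau ties
  contribute nothing to ∫S dπ, exactly as a first-order transition must.
  Doubling point density changes Δμ_s by <0.5% on smooth curves.
* **Slopes across concentration.** With only 2–4 historical
  concentrations, derivatives with respect to p_osm are estimated by one
  global ordinary-least-squares slope through all points including pure
  water. Interpolation of π at fixed Δμ_s (and vice versa) uses monotone
  cubics on the corrected, deduplicated grids.
* **Profiles.** Both routes report on the Γ_s grid of the
  target-concentration curve (default: the highest molality), anchored
  at the exact point ΔΓ_el(Γ_s = 0) = 0. The route discrepancy metric
  normalises |A − B| by the largest profile magnitude, since a pointwise
  ratio diverges at the common zero anchor; a discrepancy above 10% flags
  thermodynamically incompatible inputs.

## Dividing planes

ΔΓ_el^ε = (1 − C_M V_el)ΔΓ_el − C_M V_s Γ_s, derived from the
constant-partial-molar-volume balance across the surface layer: the first
factor is the electrolyte-induced shift of the water equimolecular plane,
the second the expulsion of surface water by headgroup volume V_s below
the dielectric plane. V_s is data: for −COOH the band 18/32/35 mL/mol
spans −OH-only to whole-headgroup immersion, with the central value from
a dielectric multilayer estimate. The conversion is exactly invertible;
the band's width grows linearly with Γ_s, and each grid point is
classified attraction/depletion/sign-indeterminate across the band.

## Volta potentials

Forward model: ΔV = P_s f(ε, r)/ε₀ + φ_DL − χ₀ − Δχ(C) with the
quadrupolar screening factor f = (1 + εr)/(ε(1+r)). The adopted form has
the required limits — no screening in vacuum (f → 1 as ε → 1), stronger
diffuse counter-polarisation at higher ε, effective permittivities of
order 3 for r = 1/2 (consistent with the low effective ε familiar from
monolayer dipole potentials), and a rising f as the tail layer dilutes
(r → 1). χ₀ = −90 mV (pure water; no direct measurement exists) and
r = 1/2 are named, overridable constants echoed in all outputs. Δχ uses
the solution-positive-up sign convention, so a negative Δχ partially
cancels a negative φ_DL. The two inversions solve this single forward
function for φ_DL (P_s pinned to its pure-water profile) or for P_s
(φ_DL pinned to the bare-surface depletion-model value, reported in
Debye per adsorbed molecule); the ±10 mV reproducibility of ΔV data is
propagated in quadrature. Because diffuse and adsorbed dipole layers
overlap in water, P_s is an effective quantity; no microscopic headgroup
model is attempted. The linear Gouy helper Δφ = σL_D/ε₀ε warns beyond
25 mV; tests verify first-order agreement with the closed-form nonlinear
Gouy–Chapman solution.

## Synthetic systems

The generator specifies the surface pressure as π(x, C) = F(x) + G(x)H(C)
on x = (μ_s − μ_s,sp)/kT with H the reduced osmotic pressure, making the
Maxwell relation between the two inversion routes an identity and every
downstream quantity (Γ_s, ΔΓ_el, Δμ_s, π_sp, S_sp, ΔV) available in
closed form. F is a Langmuir-type term with cooperativity b = 3 tuned to
an oleic-acid-like film (collapse near 28 Å², π_sp ≈ 17 mN/m); the
coupling bump G ∝ θ(1−θ) vanishes with the monolayer and peaks at half
coverage, producing the interior maximum of ΔΓ_el seen in real
monolayer data. Bulk activities follow an extended Debye–Hückel form
sampled into ordinary tables; ε(C) and Δχ(C) are linear models; the
dipole model is a constant (optionally salt-dependent) moment per
molecule with φ_DL either zero or the bare-surface prediction. The
default molalities (0, 1, 2, 3.5 mol/kg) mimic the sparsity of the
historical data sets, and curves carry 60 points per isotherm —
digitization-density sampling. Noise, when requested, is multiplicative
on π and fully seeded.

Two deliberate design choices: the ground-truth ΔΓ_el is *defined* as
the osmotic-pressure derivative of π at fixed μ_s — the same object the
estimators target — so recovery is a genuine correctness test rather
than a comparison of two unrelated models; and the default coupling
amplitude (g = 3×10⁻⁵ N/m, peak ΔΓ_el ≈ 0.013 nm⁻² per mol/kg) is small
enough that the single global OLS slope across the sparse concentration
grid sits in its linear-response regime, mirroring the near-linear
π_sp(p_osm) behaviour of the real systems. At several times this
coupling the chemical-potential surface curves visibly in p_osm over the
0–3.5 mol/kg span and the global-slope estimator acquires a secant bias
of several percent — a real limitation of sparse-concentration data that
the route-discrepancy diagnostic is designed to expose.

What passing the synthetic suite shows: the numerics (integration,
interpolation, projection, slope estimation, inversion algebra) are
correct and internally consistent at historical data densities. What it
does not show: that real digitized curves satisfy the model assumptions
(equilibrium spreading, monolayer neutrality, μ_s,sp constancy), nor how
large the secant bias is for a strongly coupled real system — for those,
the route A/B discrepancy computed on the actual data is the relevant
uncertainty measure.

## Degenerate inputs and edge cases

γ tables must be positive and strictly increasing in molality; queries
outside a table raise with the bounds named. C_m = 0 chemical-potential
increments are refused explicitly (−∞). V_el C_M ≥ 1 or equivalent
volume inconsistencies raise as nonphysical. Equal depletion radii give
φ_DL = 0 by symmetry. Γ_s = 0 points are skipped in per-molecule dipole
output. Curve files must declare kind and units; malformed rows are
reported with line numbers; write→read round trips are bit-exact (the
power-of-ten unit shift is performed in decimal, leaving a single
correctly-rounded conversion on read).

## Known limitations

* The depletion model covers surface-inactive ions only; specific
  adsorption of sticky ions is out of scope (warned, not modelled).
* The headgroup volume V_s and the quadrupolar ratio r are literature
  inputs with real uncertainty; results are reported as bands or with
  the values echoed, not sharpened.
* The global-OLS slope attributes a concentration-averaged derivative to
  the target molality; with ≤4 concentrations this is the faithful
  estimator, but it is a secant, not a local derivative.
* Charged monolayers, hydrolyzing electrolytes on acid subphases, and
  the microscopic ion–surface solvation potential are outside the
  package's scope.
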