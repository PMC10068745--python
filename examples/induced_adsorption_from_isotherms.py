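"""Extract the monolayer-induced electrolyte adsorption from pi(S) data.

Builds a synthetic oleic-acid-like isotherm family at 0/1/2/3.5 mol/kg
(with known ground truth), integrates each isotherm to the surfactant
chemical potential relative to the equilibrium spread monolayer, and then
inverts by the two independent thermodynamic routes: comparing pressures
at matched chemical potential (route A) and chemical potentials at matched
pressure (route B).  Their agreement is the thermodynamic-consistency
check of the input data.
"""

import warnings

import numpy as np

from monoion.constants import AVOGADRO
from monoion.isotherm import (
    build_field,
    induced_adsorption_isobaric,
    induced_adsorption_isochemical,
    induced_adsorption_spread,
    route_consistency,
)
from monoion.synthetic import build_system, sample_isotherms

system = build_system(seed=0)
curves, series = sample_isotherms(system)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    field = build_field(curves, series, system.spec)
    A = induced_adsorption_isochemical(field)
    B = induced_adsorption_isobaric(field)

print("spreading pressures pi_sp(C):",
      ", ".join(f"{p * 1e3:.2f} mN/m" for p in series.pi_sp))
star = induced_adsorption_spread(series, system.spec)
print("spread-state (star) DGamma_el at 3.5 mol/kg: "
      f"{star.dGamma_el_nm2[-1]:.4f} nm^-2")

d = route_consistency(A, B)
print(f"route A vs route B: max {100 * d.max_rel:.2f}%, "
      f"mean {100 * d.mean_rel:.2f}% of the profile maximum")

g_peak, dG_peak = A.interior_maximum()
truth_peak = system.dGamma_el_true(system.params.x0, 3.5)
print(f"interior maximum: DGamma_el = {dG_peak * AVOGADRO / 1e18:.4f} nm^-2 "
      f"at Gamma_s = {g_peak * AVOGADRO / 1e18:.2f} nm^-2 "
      f"(analytic truth {float(truth_peak) * AVOGADRO / 1e18:.4f} nm^-2)")

print()
print("The extra electrolyte pulled in by the monolayer rises from zero at")
print("vanishing coverage, peaks at intermediate coverage and falls again")
print("toward the dense film — the squeezing-out effect; the two routes")
print("agree within ~2%, as the underlying Maxwell relation demands.")
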