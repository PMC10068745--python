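# Electrolyte registry.  Table paths are relative to this file.
# Activity coefficients are literature means (Robinson-Stokes compilation,
# 25 C); permittivities are smoothed literature values for illustration.
# density model: rho(C_m) = density_intercept + density_slope * C_m
NaCl:
  cation: Na+
  anion: Cl-
  nu_plus: 1
  nu_minus: 1
  V_el_mL_per_mol: 16.6
  molar_mass_g_per_mol: 58.44
  density_intercept: 998.2
  density_slope: 38.0
  activity_table: nacl_gamma.tsv
  eps_table: nacl_eps.tsv
KBr:
  cation: K+
  anion: Br-
  nu_plus: 1
  nu_minus: 1
  V_el_mL_per_mol: 33.7
  molar_mass_g_per_mol: 119.0
  density_intercept: 998.2
  density_slope: 77.0
  activity_table: kbr_gamma.tsv
CaCl2:
  cation: Ca2+
  anion: Cl-
  nu_plus: 1
  nu_minus: 2
  V_el_mL_per_mol: 17.8
  molar_mass_g_per_mol: 110.98
  density_intercept: 998.2
  density_slope: 80.0
  activity_table: cacl2_gamma.tsv
  eps_table: cacl2_eps.tsv
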