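# Insoluble nonionic surfactants analysed by the package.
# V_s_mL_per_mol: [low, central, high] partial molar volume of the polar
# headgroup below the dielectric surface.  For a carboxylic headgroup the
# low bound is the -OH moiety (molar volume of water, 18 mL/mol), the high
# bound the full -COOH (partial molar volume of aqueous formic acid,
# 35 mL/mol); the central 32 mL/mol is a dielectric-multilayer estimate.
oleic_acid:
  headgroup: COOH
  V_s_mL_per_mol: [18, 32, 35]
  collapse_area_A2: 27.6
ethyl_palmitate:
  headgroup: ester
  V_s_mL_per_mol: [18, 32, 35]
  collapse_area_A2: 22.0
diethyl_sebacate:
  headgroup: diester
  V_s_mL_per_mol: [18, 32, 35]
  collapse_area_A2: 44.0
cetyl_alcohol:
  headgroup: OH
  V_s_mL_per_mol: [14, 18, 22]
  collapse_area_A2: 20.0
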