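# Crystallographic (Goldschmidt-type) ionic radii in Angstrom.
# These are editable data, not code: the depletion model consumes whatever
# radius set the user prefers, and the 0.1 A spread between common radius
# scales (e.g. Li+ 0.69-0.78) is part of the model's input uncertainty.
# Ions with R0 >= 2 A ("sticky": I-, SCN-, ClO4-, H3O+) fall outside the
# surface-inactive depletion model; loading them triggers a warning at use.
Li+:  {z: 1, R0_A: 0.78, role: cation}
Na+:  {z: 1, R0_A: 0.98, role: cation}
K+:   {z: 1, R0_A: 1.33, role: cation}
Rb+:  {z: 1, R0_A: 1.49, role: cation}
Cs+:  {z: 1, R0_A: 1.65, role: cation}
Mg2+: {z: 2, R0_A: 0.78, role: cation}
Ca2+: {z: 2, R0_A: 1.06, role: cation}
Ba2+: {z: 2, R0_A: 1.43, role: cation}
La3+: {z: 3, R0_A: 1.22, role: cation}
OH-:  {z: 1, R0_A: 1.53, role: anion}
F-:   {z: 1, R0_A: 1.33, role: anion}
Cl-:  {z: 1, R0_A: 1.81, role: anion}
Br-:  {z: 1, R0_A: 1.96, role: anion}
NO3-: {z: 1, R0_A: 1.89, role: anion}
I-:   {z: 1, R0_A: 2.20, role: anion}
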