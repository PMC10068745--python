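# CaCl2 solution static relative permittivity vs molality, ~20 C
# smoothed literature values (microwave dielectric data)
0.0	80.1
0.5	68.0
1.0	59.0
1.5	52.0
2.0	46.5
3.0	38.5
4.0	33.0
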