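# NaCl solution static relative permittivity vs molality, ~20 C
# smoothed literature values (microwave dielectric data)
0.0	80.1
0.5	72.6
1.0	66.6
2.0	57.3
3.0	50.2
4.0	44.7
5.0	41.0
6.0	38.0
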