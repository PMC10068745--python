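# CaCl2 mean activity coefficient vs molality (mol/kg), 25 C
# Robinson & Stokes compilation
0.01	0.732
0.1	0.518
0.3	0.455
0.5	0.448
0.7	0.460
1.0	0.500
1.5	0.587
2.0	0.792
3.0	1.483
4.0	2.934
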