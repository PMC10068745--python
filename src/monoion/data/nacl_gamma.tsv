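# NaCl mean activity coefficient vs molality (mol/kg), 25 C
# Robinson & Stokes compilation
0.01	0.903
0.05	0.822
0.1	0.778
0.2	0.735
0.3	0.710
0.5	0.681
0.7	0.667
1.0	0.657
1.5	0.656
2.0	0.668
3.0	0.714
4.0	0.783
5.0	0.874
6.0	0.986
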