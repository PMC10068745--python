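# KBr mean activity coefficient vs molality (mol/kg), 25 C
# Robinson & Stokes compilation
0.01	0.903
0.1	0.772
0.2	0.722
0.5	0.657
1.0	0.617
2.0	0.596
3.0	0.600
4.0	0.622
5.0	0.658
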