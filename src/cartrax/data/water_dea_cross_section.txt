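# Dissociative electron attachment cross section for the water molecule
# provenance: synthetic piecewise-linear digitisation-style table of the recommended H2O DEA resonances (H- peak near 6.5 eV ~6.6e-18 cm2, O-/OH- structures near 8.6 and 11.4 eV); magnitudes at the recommendation level, shape approximate.
# integrated strength: ~2.4e-3 nm2*eV over the 4-13 eV support
# W_eV	sigma_nm2
4.000	0.000000e+00
4.800	2.000000e-05
5.500	1.200000e-04
6.000	3.500000e-04
6.500	6.600000e-04
7.000	4.900000e-04
7.500	2.800000e-04
8.000	1.700000e-04
8.600	2.300000e-04
9.200	1.700000e-04
10.000	8.000000e-05
10.800	5.500000e-05
11.400	8.000000e-05
12.000	6.000000e-05
12.600	2.500000e-05
13.000	0.000000e+00
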