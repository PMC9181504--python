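# Screened-Coulomb (Yukawa-superposition) atomic potentials V(r) = -(Z/r) sum_i A_i exp(-alpha_i r)
# provenance: H = two-Yukawa least-squares fit to the exact H(1s) screening function (1+r)exp(-2r) (max error 4e-5); O = Yukawa fit to the screening function of a Slater-rules O density (zeta_1s=7.70, zeta_2=2.275; max fit error 0.016), validated against elastic cross sections (sigma_O(100 eV)=8.3 a.u.^2, sigma_H2O(1 keV)=0.0062 nm^2). Approximation standing in for Dirac-Hartree-Fock fit tables.
element=H Z=1 A=7.91841426,-6.91841426 alpha=1.93611191,2.07149945
element=O Z=8 A=0.055962,0.944038 alpha=28.797305,2.099711
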