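# name	sha256	provenance
water_elf_oscillators.txt	ce3f1b8e76b9ae8762019aae95ae13f4c1d5156c253eaa2a4b7c916b0237a062	synthetic Drude/Mermin parameterisation of the liquid-water optical ELF constructed under physical constraints (outer f-sum = 8 e/molecule, Bethe log-moment I = 79.4 eV with the K-shell term, Kramers-Kronig screening sum for n = 1.33, collective peak near 21-22 eV); not a digitisation of any published fit
water_optical_elf.txt	d34d981d21f5eec307cfe6e3ed968b37670953a678f4927f25c6f18192b48ca6	synthetic table evaluated from the packaged Mermin-oscillator fixture at k=0 (Drude limit); serves as the fit target for fit_optical_elf and mirrors the fixture exactly.
carbon_charge_fractions.txt	46e739f80f5a33241cb2eb9b1ad8fa7300acd5c7b91e7c4e9b54083940dcc605	synthetic parameterisation (stretched-exponential mean charge, Gaussian state distribution) anchored to fully stripped ions above 3 MeV/u, coexisting C2+..C6+ near 0.2 MeV/u and near-neutral transport near 10 keV/u; not a published table.
water_dea_cross_section.txt	a39aea5450e5df4f469818821a2abae0d447e3cb372301c7adcb4bb7586d4f65	synthetic piecewise-linear digitisation-style table of the recommended H2O DEA resonances (H- peak near 6.5 eV ~6.6e-18 cm2, O-/OH- structures near 8.6 and 11.4 eV); magnitudes at the recommendation level, shape approximate.
yukawa_screening.txt	ce8f034d40562eb084b80438c03ec9558957ceca45ceccd6c705e10bdd18f4e9	H = two-Yukawa least-squares fit to the exact H(1s) screening function (1+r)exp(-2r) (max error 4e-5); O = Yukawa fit to the screening function of a Slater-rules O density (zeta_1s=7.70, zeta_2=2.275; max fit error 0.016), validated against elastic cross sections (sigma_O(100 eV)=8.3 a.u.^2, sigma_H2O(1 keV)=0.0062 nm^2). Approximation standing in for Dirac-Hartree-Fock fit tables.
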