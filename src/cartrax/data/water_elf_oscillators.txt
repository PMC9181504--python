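# Mermin-oscillator parameterisation of an energy-loss function
# provenance: synthetic Drude/Mermin parameterisation of the liquid-water optical ELF constructed under physical constraints (outer f-sum = 8 e/molecule, Bethe log-moment I = 79.4 eV with the K-shell term, Kramers-Kronig screening sum for n = 1.33, collective peak near 21-22 eV); not a digitisation of any published fit
density_nm3 = 33.43
threshold_ev = 7.0
refractive_index = 1.33
oscillator A=0.06942317 hw_eV=18.5 hg_eV=5.5 Eth_eV=7.0
oscillator A=0.17448408 hw_eV=21.3 hg_eV=5.5 Eth_eV=7.0
oscillator A=0.20814254 hw_eV=24.0 hg_eV=6.5 Eth_eV=7.0
oscillator A=0.0387981 hw_eV=42.0 hg_eV=18.0 Eth_eV=7.0
oscillator A=0.01226166 hw_eV=80.0 hg_eV=55.0 Eth_eV=7.0
inner_shell element=O shell=1s B_eV=540.0 occupancy=2.0 stoichiometry=1.0
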