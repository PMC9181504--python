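# cartrax

Dielectric-formalism cross sections and event-by-event track-structure
Monte Carlo for carbon ions and their secondary electrons in liquid water.

Carbon-ion beams deposit most of their dose in a narrow Bragg peak, and the
biological effect of that dose is governed by what happens within nanometres
of each ion path: the spectrum of secondary electrons set free by the ion,
and the way those electrons cluster ionisations and dissociative excitations
around DNA-sized targets. `cartrax` computes this chain from first principles:

1. **Electronic response of liquid water.** The energy-loss function (ELF)
   Im[−1/ε(k, E)] over the full Bethe surface, built from a small set of
   Mermin-type oscillators fitted to the optical limit and extended to finite
   momentum transfer by the Mermin dielectric function, plus hydrogenic
   generalised oscillator strengths for the O K-shell. Sum-rule diagnostics
   (f-sum, KK-sum, mean excitation energy *I*) are built in.
2. **Ion inelastic cross sections.** First-Born inelastic cross sections for
   C^q+ (q = 0…6) projectiles dressed with Brandt–Kitagawa screening,
   averaged over equilibrium charge-state fractions: inverse mean free path,
   stopping power, energy-loss straggling, and the singly/doubly
   differential cross sections (SDCS/DDCS) for secondary-electron emission,
   with a binary-encounter angular model and a Salin enhancement factor.
3. **Electron cross sections.** Ionisation and discrete excitation from the
   same ELF with Born–Ochkur exchange and a low-energy Coulomb correction;
   relativistic (Dirac) partial-wave elastic scattering on screened atomic
   potentials combined into a molecular cross section with geometric
   interference; phonon emission, pre-hydration trapping and dissociative
   electron attachment (DEA) below the electronic thresholds.
4. **Event-by-event Monte Carlo.** A compiled transport kernel follows every
   secondary electron from its emission energy down to sub-excitation
   energies, scoring radial dose profiles and ionisation-cluster statistics
   (cluster-size distributions F₁, F₂, F₃ and damage-mechanism fractions) in
   DNA-sized cylindrical volumes (2.3 nm × 6.8 nm) at chosen impact
   parameters from the ion path.

## Model summary

The inelastic machinery rests on the plane-wave first Born approximation in
the dielectric formalism. For a bare or partially dressed ion of charge
structure ρ_q(k) and speed v, the doubly differential inverse mean free path
is

    d²Λ/dk dE = (2 / π v² N) [Z − ρ_q(k)]² (1/k) Im[−1/ε(k, E)]   (a.u.)

with N the molecular density of water. Moments of this kernel over (k, E)
give Λ, the stopping power and the straggling; restricting E to each shell's
ionisation continuum and transforming E → W + B gives the secondary-electron
SDCS. Electron-impact ionisation uses the same ELF with an Ochkur exchange
term and the indistinguishability cutoff W ≤ (T − B)/2. Elastic scattering
integrates the radial Dirac equations for the screened neutral-atom
potentials of O and H, matches to spherical Bessel functions and sums
spin-flip and direct amplitudes; the molecular differential cross section
includes the O–H and H–H interference terms. All condensed-phase
low-energy channels (phonon, trapping, DEA) use analytic or tabulated
inverse mean free paths.

All numeric fixtures shipped with the package (`src/cartrax/data/`) are
synthetic: they are generated by the package's own fitting and
parameterisation tools and are validated by checksums and by physical
sum rules in the test suite. See `docs/methods.md` for exactly what each
fixture represents and how it was produced.

## Worked example

```python
import numpy as np
from cartrax.dielectric import f_sum_rule, mean_excitation_energy
from cartrax.fixtures import load_water_elf_model
from cartrax.ion import IonCrossSections
from cartrax.scoring import stats_from_counts
from cartrax.transport import SimulationConfig, TransportModel

model = load_water_elf_model()
print(f"f-sum  = {f_sum_rule(model):.3f} electrons/molecule")
print(f"I      = {mean_excitation_energy(model):.2f} eV")

xs = IonCrossSections(model)
t = np.logspace(-2, 3, 160)                      # MeV/u
lam = xs.iimfp(t)
sp = xs.stopping_power(t)
print(f"min inelastic MFP = {1.0 / lam.max():.4f} nm "
      f"at {t[np.argmax(lam)] * 1e3:.0f} keV/u")
print(f"stopping maximum  = {sp.max():.1f} eV/nm "
      f"at {t[np.argmax(sp)] * 1e3:.0f} keV/u")

tm = TransportModel(ion_xs=xs)                   # builds all electron tables
cfg = SimulationConfig(t_mevu=1000.0 / 12.0,     # 1 GeV carbon
                       n_paths=400, multiplier=1, master_seed=7)
res = tm.run(cfg)
stats = stats_from_counts(res.counts, cfg.impact_parameters_nm)
s1 = stats[0]                                    # cylinder at b = 1 nm
print(f"mean damaging cluster at b = 1 nm: {s1.mean_total():.3f}")
print(f"F1, F2, F3: {s1.fn(1):.3f}, {s1.fn(2):.3f}, {s1.fn(3):.3f}")
print(f"energy closure: {res.energy_closure():.2e}")
```

Output (a few minutes on one core; the transport tables dominate):

```
f-sum  = 10.009 electrons/molecule
I      = 79.38 eV
min inelastic MFP = 0.0474 nm at 181 keV/u
stopping maximum  = 1197.6 eV/nm at 181 keV/u
mean damaging cluster at b = 1 nm: 0.545
F1, F2, F3: 0.190, 0.070, 0.037
energy closure: 2.09e-13
```

The run uses `multiplier=1` so each history is a physical realization and
the cluster-size distribution statistics F₁–F₃ are meaningful; larger
multipliers give unbiased *means* at much lower variance per ion path.

The same quantities are available from the command line:

```bash
cartrax xs ion --quantity stopping --n-points 40 --out stopping.csv
cartrax xs electron --channel trap --energy 10 --out trap.csv
cartrax mc run --energy 0.2 --paths 20 --multiplier 20 --seed 3 --out run/
cartrax fixtures validate
cartrax recipe clusters --out clusters/ --seed 1
```

Every recipe writes a `manifest.json` recording the package version, the
master seed, all parameter overrides and the SHA-256 checksums of the data
fixtures, so any output directory can be reproduced exactly.

## Layout

| Path | Content |
| --- | --- |
| `src/cartrax/dielectric.py` | Mermin/Lindhard dielectric functions, ELF models, sum rules, optical-ELF fitting |
| `src/cartrax/gos.py` | hydrogenic generalised oscillator strengths (K-shell) |
| `src/cartrax/ion.py` | Brandt–Kitagawa screening, charge-state averaging, ion IMFP/stopping/straggling, SDCS/DDCS |
| `src/cartrax/inelastic.py` | electron-impact ionisation and excitation, low-energy channels |
| `src/cartrax/elastic.py` | Dirac partial-wave elastic scattering, molecular EDCS, sampling tables |
| `src/cartrax/transport.py`, `_kernel.py` | event-by-event Monte Carlo (numba kernel) |
| `src/cartrax/scoring.py` | radial dose, cluster statistics, F_n curves |
| `src/cartrax/events.py` | event-log container |
| `src/cartrax/fixtures.py`, `data/` | synthetic data fixtures + manifest |
| `src/cartrax/synthetic.py` | synthetic event-log and ELF generators for testing |
| `src/cartrax/recipes.py`, `cli.py` | reproducible study recipes and the `cartrax` CLI |
| `docs/methods.md` | methods note: models, parameters, numerics, limitations |
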