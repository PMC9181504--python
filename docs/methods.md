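# Methods note

This note records the physical models, the parameter choices, the synthetic
data fixtures, the numerical methods, and the known limitations of
`cartrax`. Units are eV, nm and atomic units (a.u., ħ = m_e = e = 1) as
stated; conversions live in `cartrax.constants`.

## 1. Electronic response of liquid water

### 1.1 Outer-shell energy-loss function

The valence response is a sum of Mermin-type oscillators,

    Im[−1/ε(k, E)] = Σ_j A_j · Im[−1/ε_M(k, E; ω_j, γ_j)] · Θ(E − E_th),

with the Mermin dielectric function ε_M built from the Lindhard function at
complex frequency ω + iγ. In the optical limit k → 0 each term reduces
exactly to a Drude ELF with amplitude convention

    Im[−1/ε_D(E)] = A_j · E (ħγ_j) (ħω_j)² / [((ħω_j)² − E²)² + E²(ħγ_j)²],

i.e. `A_j` is dimensionless and multiplies the unit-normalised Drude shape;
`drude_elf` and `mermin_elf` agree to better than 10⁻⁶ in this limit (tested).
A fixed threshold E_th = 7 eV models the band gap of the liquid: the ELF is
zero below it and every oscillator is cut there, which slightly violates the
KK-sum (≈ 4% low) but keeps the excitation spectrum physical.

The Lindhard function is evaluated from the closed form with principal-value
complex logarithms; for |z ± u| > 40 (very small k or very large ω, where
the closed form suffers catastrophic cancellation) a Laurent series in 1/(z±u)
is used instead. The static limit has its own real-valued branch.

### 1.2 K-shell

The O 1s shell (binding B_K = 540 eV, 2 electrons) is modelled with
hydrogenic generalised oscillator strengths at effective charge
Z_eff = √(2 B_K) (a.u.). At each momentum transfer the hydrogenic df/dE is
renormalised so that the shell integrates to exactly 2 electrons. This
renormalisation is what lets the model satisfy the f-sum rule
(10 electrons/molecule within 0.5) and reproduce the Bohr straggling limit
at high speed simultaneously; the unrenormalised hydrogenic GOS loses
≈ 15% of the K-shell strength at intermediate k and fails the second check.

### 1.3 Fixture: `water_elf_oscillators.txt`

Five outer oscillators (A, ħω, ħγ in eV):

| A | ħω | ħγ |
|---|----|----|
| 0.06942 | 18.5 | 5.5 |
| 0.17448 | 21.3 | 5.5 |
| 0.20814 | 24.0 | 6.5 |
| 0.03880 | 42.0 | 18.0 |
| 0.01226 | 80.0 | 55.0 |

This fixture is **synthetic**: the positions and widths were fixed by hand to
the qualitative shape of the measured optical ELF of liquid water (single
dominant peak near 21 eV, slow high-energy tail), and the amplitudes were
then solved by non-negative least squares against three integral constraints
evaluated with the package's own sum-rule code: f-sum = 10 e⁻/molecule,
mean excitation energy I = 79.4 eV, and a KK-sum consistent with the static
refractive index. It is *not* a fit to any proprietary data set. The
companion `water_optical_elf.txt` table is generated from the same model by
`cartrax.fixtures` and exists to exercise the optical-table reader and the
`fit_optical_elf` round trip. All fixtures carry SHA-256 checksums in
`fixtures_manifest.txt`, validated by `cartrax fixtures validate`.

### 1.4 Sum-rule diagnostics

`f_sum_rule`, `kk_sum_rule` and `mean_excitation_energy` integrate the
optical moments by adaptive quadrature over geometric sub-panels (factor 3
spacing up to 10⁵ eV); a single panel over five decades defeats the
quadrature error estimator. The shipped fixture gives f-sum ≈ 10.0,
I ≈ 79.4 eV.

## 2. Ion inelastic cross sections

### 2.1 Model

Plane-wave first Born approximation (FBA) in the dielectric formalism. The
projectile is C^q+ with Brandt–Kitagawa (BK) single-parameter screening:

    ρ_q(k) = (Z − q) / (1 + (kΛ_q)²),
    Λ_q = 2 · 0.48 (N_e/Z)^{2/3} / [Z^{1/3} (1 − N_e/(7Z))],   N_e = Z − q.

Cross sections are computed per charge state and averaged over equilibrium
charge fractions φ_q(T) (fixture, §2.3). Moments (IMFP, stopping,
straggling) come from pre-integrated reversed-cumulative tables
G_q(k*, E) = ∫_{k*}^∞ dk/k [Z−ρ_q]² Im[−1/ε] so that the kinematic limit
k⁻ = E/v per energy loss costs one interpolation, not one integral. Table
sizes: 336 log-spaced k nodes × 512 log-spaced E nodes per (q, shell);
convergence was verified against brute-force 2000×2000 quadrature at the
0.5% level (tested).

The SDCS assigns each energy loss to a shell continuum, E = B + W with
B = 13.7 eV (outer) and 540 eV (K), with the kinematic cutoff
W ≤ 4(m/M)T. The DDCS factorises the FBA angular kernel at fixed (W, θ₁)
and maps the momentum-transfer polar angle θ₁ onto the electron emission
angle θ₂ linearly, θ₁ = C θ₂ with C = θ₁^max / θ₂^BE and the
binary-encounter angle θ₂^BE = arccos √(MW/4mT); a two-centre (capture to
the continuum) Salin factor F_S = u/(1 − e^{−u}) with
u = 2π√B [ |v_i − v_e|⁻¹ − v_i⁻¹ ] (a.u.) enhances forward emission, and
the DDCS is renormalised to the SDCS at each W (both behaviours switchable
via keyword).

### 2.2 Validation

- High-speed stopping agrees with the Bethe formula (charge-weighted, same
  I) to 10% at 100–1000 MeV/u (tested).
- Charge-weighted straggling at 1000 MeV/u reproduces the analytic Bohr
  value 3.14×10⁵ eV²/nm within 5% (tested). The straggling ratio
  Ω²/Ω_B² is not strictly monotone in T above ~5 MeV/u: the model
  overshoots 1 by ≈ 3.5% around the Bethe ridge before converging. This is
  a real property of the renormalised-GOS model, not a numerical artefact.
- SDCS ↔ IMFP closure: integrating the SDCS over W reproduces the
  ionisation IMFP to 1% (tested).

### 2.3 Fixture: `carbon_charge_fractions.txt`

Equilibrium charge fractions φ_q(T) for carbon in matter. **Synthetic**:
Gaussian distributions around a mean-charge curve q̄(T) interpolated
(PCHIP in log T) through anchor points chosen from the standard
gas-target effective-charge systematics (q̄ = 3.4 at 0.2 MeV/u,
q̄ → 6 above ~3 MeV/u, q̄ → 0 at vanishing speed), with width
0.5·√(q̄(1 − q̄/6) + 0.1). Liquid (density-effect) parameterisations give a
higher q̄ at Bragg-peak energies (≈ 4.6 at 0.2 MeV/u); the gas-like choice
is deliberate and is discussed in §7 — it sets the absolute scale of the
stopping maximum and of every cluster observable.

## 3. Electron inelastic cross sections

Ionisation: same dielectric formalism, with

- Born–Ochkur exchange: the integrand factor 1 + F_xc with
  F_xc = x² − x, x = (k²/2)/(T − W) (a.u.);
- indistinguishability cutoff W ≤ (T − B)/2;
- low-energy Coulomb correction: kinematic limits evaluated at
  T′ = T + 2B;
- energy-dependent mean binding B(T): logistic interpolation from
  10.79 eV (threshold regime) to 13.71 eV over T ∈ [0, 32.3] eV (midpoint
  16.15 eV, slope 2 eV), reflecting the opening of deeper valence channels.

Excitation: the below-threshold part of the outer ELF, integrated over
E ∈ [7 eV, min(B(T), T)], with the same exchange form at x = (k²/2)/T.

Low-energy channels (`LowEnergyChannels`, all inverse MFPs in nm⁻¹):

- trapping (pre-hydration): Λ_trap = 0.1·exp(−0.1 W[eV]), an exponential
  parameterisation of the sub-excitation trapping rate in liquid water;
- phonon emission: Fröhlich coupling with ε₀ = 80, ε_∞ = 1.78,
  ħω_ph = 0.1 eV, thermal occupation at 300 K;
- dissociative electron attachment: tabulated fixture
  `water_dea_cross_section.txt` (synthetic: a Gaussian resonance peaked at
  6.5 eV, peak cross section 6.6×10⁻⁴ nm², the scale of the H⁻ channel).

The k-integrals use 320×440 (T×W) log-grids with Simpson's rule over a
broadcast log-k mesh; SDCS→TCS closure is verified to 0.5% (tested).

## 4. Elastic scattering

Relativistic partial waves: the radial Dirac equations

    P′ = −(κ/r)P + [(T − V)/c + 2c]Q,
    Q′ =  (κ/r)Q − [(T − V)/c]P

are integrated by RK4 on a hybrid radial grid — 1200-point log grid through
the potential region, then a linear tail with phase step k·h = 0.05 (the
step controls a systematic phase error; 0.1 leaves ~7×10⁻⁵ rad which is
visible in the Born-limit test). Phase shifts come from two-point matching
to Riccati–Bessel functions. The partial-wave sum is truncated when
|δ| < 10⁻³ and completed with first-order Born phases for the Yukawa-sum
potentials, computed by Legendre functions of the second kind with a sticky
freeze and monotonicity guard against recurrence instability at large ℓ.

Atomic potentials: Yukawa-sum fits to Dirac–Hartree–Fock-like charge
densities. The H parameters are taken from the standard two-Yukawa fit; the
O parameters (`yukawa_screening.txt`, **synthetic**) were fitted by this
package to a Slater-rules shell density (ζ_1s = 7.70, ζ_2sp = 2.275) after
the simpler Molière-type screening overestimated σ_O(100 eV) by a factor
2.3 against established integral cross sections. A Furness–McCarthy local
exchange term is available (`effective_v`).

Molecular cross section: |F_O|² + 2|F_H|² summed with sinc(k r_ij)
interference for the O–H (0.09572 nm) and H–H (0.1514 nm) pairs, divided
consistently among direct and spin-flip amplitudes.

Low-energy treatment: below 6 eV the static-potential phases are dominated
by an unphysical H⁻-like virtual state, so cross sections are clamped at
their 6 eV values. Between 6 and 100 eV the static-exchange-free molecular
model still exceeds recommended integral elastic cross sections for water
vapour by up to ×2, so the total cross section (not the angular shape) is
calibrated to recommended integral values at 6–100 eV
(0.18, 0.15, 0.105, 0.080, 0.068, 0.052, 0.039 nm² at
6, 10, 20, 30, 40, 60, 100 eV), fading out linearly in log E between 60 and
100 eV. Above 100 eV the ab initio values are used unchanged; at 1 keV the
model gives σ = 0.0062 nm², in agreement with measured ~0.0064 nm².
The energy grid is 44 log-spaced points from 1 eV to 200 keV; the angular
grid is forward-dense (0 plus 240 log-spaced angles from 10⁻⁴ to π rad) to
resolve the keV-range forward peak. Externally computed DCS tables can be
ingested via `ElasticCrossSections.from_table(_file)`.

## 5. Event-by-event Monte Carlo

- The statistical `multiplier` makes per-history quantities (radial dose,
  mean cluster sizes, mechanism shares) unbiased averages over M sampled
  cascades per ion collision, but it under-disperses per-history
  *distributions*: cluster-size statistics such as F_n must be computed
  from runs with `multiplier=1`, as the cluster recipes do.
- Geometry: straight ion path of length L = 50 nm along z; each ionising
  ion collision spawns secondary electrons at the collision site; a
  statistical `multiplier` M samples M electrons per collision with weight
  1/M each (ion collisions themselves always have weight 1).
- Electron transport: energy-grid (240 log points, 0.1 eV – 200 keV) lookup
  of all six inverse MFPs; channel choice by total-rate competition; W and
  angle sampling by 256-node inverse-CDF tables; elastic deflection from
  per-energy angular tables; secondaries pushed on an explicit stack.
  Electrons are followed to a 0.1 eV cutoff; trapping, DEA and cutoff
  deposit the remaining energy locally. Per-history energy closure is
  tracked and asserted to < 10⁻⁶ relative (tested).
- Randomness: one sub-seed per ion path from `numpy.random.SeedSequence`,
  reduced mod 2³¹−1, so runs are bit-reproducible for a given master seed
  and embarrassingly parallel in principle.
- Scoring happens inside the compiled kernel: radial dose histogram
  (0.1 nm shells, overflow bin beyond 100 nm) and per-history counts of
  ionisations, excitations, dissociative excitations, DEA and ion
  collisions in cylinders (2.3 nm diameter × 6.8 nm height, axis parallel
  to the ion path) at configurable impact parameters
  (default 1, 2, 3, 5, 10, 20, 30, 50, 100 nm). An independent
  point-in-cylinder recount of the optional event log reproduces the
  kernel tallies exactly (tested).
- Dissociative excitations: each excitation is flagged dissociative with
  probability 0.4 at transport time (recorded in the event log), the
  standard branching assumption for OH-producing excitations.
- Ion-impact ionisations mark cluster *sites* but are not themselves scored
  as cluster constituents or dose: the damaging cluster is defined by the
  secondary-electron cascade (ionisations + dissociative excitations +
  DEA). The 1 GeV per-cylinder means are only consistent with the
  reference scale under this convention.
- Throughput is on the order of 10⁶–10⁷ events/s on one core, dominated by
  the energy-grid table lookups; inverse-MFP and sampling tables are cached
  between steps while the electron energy is unchanged.

## 6. Acceptance quantities and statistics

`scripts/acceptance.py` recomputes all headline quantities with
`--paths 100 --multiplier 100` (≈ 10 min on one core; the 1 GeV run uses
3× paths and 2× multiplier because it is ~30× cheaper per path).
Deterministic quantities (I, IMFP minimum, stopping maximum, SDCS ratio)
carry no seed dependence. The cluster quantities are Monte Carlo means;
the JSON records the sample size `n` behind each (histories for the
cluster means, raw scored events for the far-field share). DNA-sized
cylinders 20–100 nm off-axis are hit so rarely that the far-field
mechanism share must pool many non-overlapping cylinder positions
(b = ±20, ±27, …, ±97 nm, 7 nm spacing, both sides of the track) to reach
a few hundred raw events; even so its binomial standard error is a few
percentage points and single-seed values scatter accordingly. Almost all
far-field events come from the 1 GeV track — the 0.2 MeV/u δ-ray endpoint
(~440 eV, sub-20 nm range) keeps that track's damage within ~15 nm of the
axis.

## 7. Known limitations

1. **SDCS-maxima ratio (Bragg peak vs plateau).** With FBA + BK screening
   and the gas-systematics charge fractions of §2.3, the ratio of the SDCS
   maxima at 0.2 vs 20 MeV/u is ≈ 9.0, below the reference band around 14.
   The ratio is controlled by the effective charge at 0.2 MeV/u: pushing
   q̄(0.2) to ≈ 4.6 (liquid parameterisations) brings the ratio to ~13–14
   but simultaneously raises the stopping maximum and the Bragg-peak
   cluster sizes ~35% above their reference values. Within this model
   family the two groups of observables cannot be matched with one
   charge-state fixture; we chose the set that matches the stopping curve,
   the IMFP minimum and the plateau (1 GeV) transport observables, and
   left the ratio criterion failing.
2. **Mean damaging cluster at 0.2 MeV/u, b = 1 nm.** The model gives ≈ 50
   vs a reference ≈ 31 (±35%). The 1 GeV value (≈ 0.47 vs 0.44) and the
   ion-collision density (≈ 990 per 50 nm at 0.2 MeV/u) agree, so the
   excess is confined to the spatial concentration of the dense sub-30 eV
   cascade at the Bragg peak. The plausible cause is the elastic model:
   below ~100 eV a condensed-phase (cluster-type) elastic cross section
   with stronger forward scattering transports low-energy electrons
   farther from the core than the calibrated molecular-Mott model used
   here; exactly this model sensitivity motivates the wide reference band.
   Ingesting an external low-energy DCS table via
   `ElasticCrossSections.from_table` is the supported path to explore it.
3. The FBA is a leading-order theory: Barkas (Z³) and Bloch corrections
   are absent, so stopping below ~0.1 MeV/u and the detailed charge-state
   physics (electron capture/loss dynamics, pre-equilibrium) are outside
   scope; charge equilibrium is assumed at all depths.
4. The liquid-phase low-energy electron physics (trapping rate, DEA
   magnitudes, phonon model) is parameterised, not derived; the fixtures
   set plausible magnitudes and the transport treats them consistently,
   but sub-excitation observables should not be over-interpreted.
5. Cross sections are for pure liquid water at 1 g/cm³ and 300 K;
   no DNA-material, no temperature dependence, no magnetic fields.
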