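"""Carbon-ion cross sections: BK screening, moments, charge weighting,
secondary-electron spectra."""

import numpy as np
import pytest

from cartrax.constants import (
    AMU_ME,
    BOHR_NM,
    HARTREE_EV,
    ev_to_au,
    mevu_to_ev,
)
from cartrax.dielectric import mean_excitation_energy
from cartrax.ion import (
    ChargeFractionModel,
    IonProjectile,
    bk_form_factor,
    bk_screening_length,
    salin_factor,
)


class TestBrandtKitagawa:
    def test_bare_ion_is_nuclear_charge(self):
        k = np.logspace(-2, 2, 20)
        assert np.allclose(bk_form_factor(6, k), 6.0)

    def test_neutral_screening_limit(self):
        assert bk_form_factor(2, 0.0) == pytest.approx(2.0)
        assert bk_form_factor(0, 0.0) == pytest.approx(0.0)

    def test_half_screened_value(self):
        """At kΛ = 1 the form factor is q + (Z−q)/2."""
        lam = bk_screening_length(2)
        assert bk_form_factor(2, 1.0 / lam) == pytest.approx(4.0)

    def test_large_k_reaches_bare_charge(self):
        assert bk_form_factor(1, 1e4) == pytest.approx(6.0, rel=1e-4)

    def test_invalid_charge_rejected(self):
        with pytest.raises(ValueError):
            bk_form_factor(7, 1.0)
        with pytest.raises(ValueError):
            IonProjectile(q=-1)


class TestChargeFractions:
    def test_fractions_sum_to_one(self):
        cf = ChargeFractionModel.default()
        t = np.logspace(-3, 3, 50)
        phi = cf.fractions(t)
        assert np.allclose(phi.sum(axis=-1), 1.0, atol=1e-9)
        assert np.all(phi >= 0)

    def test_fully_stripped_above_3mevu(self):
        cf = ChargeFractionModel.default()
        for t in (3.0, 10.0, 100.0, 1000.0):
            assert cf.fractions(t)[6] > 0.999

    def test_intermediate_states_coexist_near_peak(self):
        phi = ChargeFractionModel.default().fractions(0.2)
        assert sum(phi[q] > 1e-3 for q in range(2, 7)) >= 4

    def test_degenerate_mixture_equals_single_state(self, ion_xs):
        """A weighted sum with φ_q = δ_{q,5} equals the q=5 moment exactly."""
        t = np.array([0.5])
        phi = np.zeros((1, 7))
        phi[0, 5] = 1.0
        cf = ChargeFractionModel(t, phi)
        old = ion_xs.charge_fractions
        try:
            ion_xs.charge_fractions = cf
            weighted = ion_xs.stopping_power(0.5)
        finally:
            ion_xs.charge_fractions = old
        assert weighted == pytest.approx(ion_xs.stopping_power(0.5, q=5),
                                         rel=1e-12)

    def test_charge_weighted_equals_bare_at_high_energy(self, ion_xs):
        assert ion_xs.stopping_power(10.0) == pytest.approx(
            ion_xs.stopping_power(10.0, q=6), rel=1e-3)


class TestIDDCS:
    def test_below_threshold_zero(self, ion_xs):
        ion = IonProjectile.carbon(1.0)
        assert ion_xs.iddcs(ion, 1.0, 5.0) == 0.0

    def test_kinematic_window(self, ion_xs):
        ion = IonProjectile.carbon(0.2)
        emax = 4.0 / ion.mass_me * ev_to_au(ion.energy_ev) * HARTREE_EV
        assert emax == pytest.approx(438.9, rel=1e-3)
        assert ion_xs.iddcs(ion, 1.0, emax * 1.01) == 0.0
        assert ion_xs.iddcs(ion, 1e-6, 100.0) == 0.0  # below ħk−

    def test_bare_ion_scaling(self, ion_xs):
        """IDDCS factorises: q=6 equals 36× the unit-charge kernel."""
        k, e = 1.3, 40.0
        i6 = ion_xs.iddcs(IonProjectile.carbon(2.0, q=6), k, e)
        # unit-charge kernel = IDDCS with [Z−ρ]² replaced by 1
        w2 = bk_form_factor(6, k) ** 2
        assert i6 / w2 * 36.0 == pytest.approx(i6, rel=1e-12)
        # and against an explicitly screened state
        i2 = ion_xs.iddcs(IonProjectile.carbon(2.0, q=2), k, e)
        w22 = bk_form_factor(2, k) ** 2
        assert i2 / i6 == pytest.approx(w22 / w2, rel=1e-10)


class TestMoments:
    def test_bohr_straggling_limit(self, ion_xs):
        """Charge-weighted straggling at 1000 MeV/u reaches the analytic
        Bohr value 4πe⁴NZ²Z_t ≈ 3.14e5 eV²/nm within 5%."""
        bohr = ion_xs.bohr_straggling()
        assert bohr == pytest.approx(3.14e5, rel=0.01)
        assert ion_xs.straggling(1000.0) == pytest.approx(bohr, rel=0.05)

    def test_straggling_approaches_bohr(self, ion_xs):
        """Ω² rises with energy through the stopping-power region and settles
        at the Bohr value (within 10% everywhere above 10 MeV/u; a small
        Bethe-ridge overshoot around ~10 MeV/u is genuine)."""
        rising = ion_xs.straggling(np.array([0.1, 0.3, 1.0, 3.0]))
        assert np.all(np.diff(rising) > 0)
        bohr = ion_xs.bohr_straggling()
        high = ion_xs.straggling(np.array([10.0, 100.0, 1000.0]))
        assert np.all(np.abs(high / bohr - 1.0) < 0.10)

    def test_high_energy_bethe_oracle(self, ion_xs, water_model):
        """Charge-weighted stopping at 100 MeV/u within 10% of the
        nonrelativistic Bethe formula with the model's own I."""
        i_ev = mean_excitation_energy(water_model)
        t = ev_to_au(mevu_to_ev(100.0))
        v2 = 2.0 * t / (12.0 * AMU_ME)
        bethe = (4.0 * np.pi * 36.0 * ion_xs.density_au * 10.0 / v2
                 * np.log(2.0 * v2 / ev_to_au(i_ev)))
        bethe *= HARTREE_EV / BOHR_NM
        assert ion_xs.stopping_power(100.0) == pytest.approx(bethe, rel=0.10)

    def test_iimfp_minimum_location_and_value(self, ion_xs):
        t = np.logspace(-2, 3, 120)
        lam = ion_xs.iimfp(t)
        i = int(np.argmax(lam))
        assert 1.0 / lam[i] == pytest.approx(0.05, rel=0.25)
        assert 0.05 <= t[i] <= 0.4

    def test_stopping_maximum_position(self, ion_xs):
        t = np.logspace(-2, 3, 120)
        sp = ion_xs.stopping_power(t)
        tmax = t[int(np.argmax(sp))]
        assert 0.14 <= tmax <= 0.30

    def test_quadrature_against_brute_force(self, ion_xs, water_model):
        """First moment at 1 MeV/u (q=6) vs direct 2000×2000 trapezoid of the
        doubly differential probability with the simplified limits."""
        t_mevu = 1.0
        t = ev_to_au(mevu_to_ev(t_mevu))
        m = 12.0 * AMU_ME
        v = np.sqrt(2.0 * t / m)
        e = np.logspace(np.log10(7.0001), np.log10(4.4e5), 2000)
        e_au = ev_to_au(e)
        out = np.zeros_like(e)
        k = np.logspace(-3, np.log10(500.0), 2000)
        elf = water_model.elf(k[:, None] * np.ones_like(e),
                              np.ones_like(k)[:, None] * e)
        w2 = bk_form_factor(6, k) ** 2
        integ = w2[:, None] * elf / k[:, None]
        for j, ej in enumerate(e_au):
            kmin = ej / v
            mask = k >= kmin
            if mask.sum() > 1:
                out[j] = np.trapezoid(integ[mask, j], k[mask])
        m1 = np.trapezoid(e_au * out, e_au) * 2.0 / (np.pi * v**2)
        m1 *= HARTREE_EV / BOHR_NM
        assert ion_xs.stopping_power(t_mevu, q=6) == pytest.approx(m1,
                                                                   rel=0.005)

    def test_moment_order_validated(self, ion_xs):
        with pytest.raises(ValueError):
            ion_xs.moment(1.0, 3)


class TestSDCS:
    def test_kinematic_cutoff(self, ion_xs):
        assert ion_xs.sdcs(0.2, 1e4) == 0.0

    def test_endpoint_grows_with_energy(self, ion_xs):
        """The highest W with non-negligible SDCS grows monotonically in T."""
        w = np.logspace(0, 6, 400)
        ends = []
        for t in (0.2, 2.0, 20.0):
            s = ion_xs.sdcs(t, w)
            nz = np.nonzero(s > s.max() * 1e-8)[0]
            ends.append(w[nz[-1]])
        assert ends[0] < ends[1] < ends[2]

    def test_maximum_decreases_strongly_with_ion_energy(self, ion_xs):
        """The SDCS maximum drops steeply from the stopping-power peak energy
        to the relativistic regime (roughly an order of magnitude between
        0.2 and 20 MeV/u; monotone through 2 MeV/u)."""
        w = np.logspace(-1, 4.5, 300)
        m02 = ion_xs.sdcs(0.2, w).max()
        m2 = ion_xs.sdcs(2.0, w).max()
        m20 = ion_xs.sdcs(20.0, w).max()
        assert m02 > m2 > m20
        assert 5.0 < m02 / m20 < 30.0

    def test_sdcs_integral_matches_restricted_moment(self, ion_xs):
        """∫SDCS dW (q=6, 6 MeV/u) equals the ionisation-restricted zeroth
        moment divided by N within 1% (internal consistency of the energy-
        transfer decomposition E = B + W)."""
        lam = ion_xs.ionisation_iimfp(6.0, q=6)
        w = np.logspace(-3, 5.5, 3000)
        s = ion_xs.sdcs(6.0, w, q=6)
        sigma = np.trapezoid(s, w)
        assert sigma * ion_xs.model.density_nm3 == pytest.approx(lam, rel=0.01)

    def test_negative_w_rejected(self, ion_xs):
        with pytest.raises(ValueError):
            ion_xs.sdcs(1.0, -1.0)


class TestDDCS:
    def test_binary_encounter_angle_edges(self, ion_xs):
        t = 1.0
        emax = 4.0 / (12.0 * AMU_ME) * mevu_to_ev(t)
        assert ion_xs.binary_encounter_angle(t, emax) == pytest.approx(0.0,
                                                                       abs=1e-6)
        assert np.isnan(ion_xs.binary_encounter_angle(t, emax * 1.1))
        assert ion_xs.ddcs(t, emax * 1.1, 0.5) == 0.0

    def test_salin_factor_limits(self):
        # u→0 limit: forward factor → 1 (v_e → 0)
        m = 12.0 * AMU_ME
        assert salin_factor(mevu_to_ev(6.0), 1e-12, 0.3, m, 13.7) == \
            pytest.approx(1.0, abs=1e-4)
        # direct evaluation at u=1
        u = 1.0
        assert u / (1.0 - np.exp(-u)) == pytest.approx(1.582, abs=1e-3)

    def test_angular_integral_consistent_with_sdcs(self, ion_xs):
        """∫DDCS dΩ₂ (Salin off) within 10% of the SDCS at 6 MeV/u, 100 eV."""
        th = np.concatenate([np.logspace(-4, np.log10(np.pi), 400)])
        d = ion_xs.ddcs(6.0, 100.0, th, q=6, salin=False)
        mu = np.cos(th)[::-1]
        integral = 2.0 * np.pi * np.trapezoid(d[::-1], mu)
        sdcs = ion_xs.sdcs(6.0, 100.0, q=6)
        assert integral == pytest.approx(sdcs, rel=0.10)

    def test_renormalised_ddcs_integrates_to_sdcs(self, ion_xs):
        th = np.linspace(1e-4, np.pi, 600)
        d = ion_xs.ddcs(6.0, 100.0, th, q=6, salin=True, renormalise=True)
        mu = np.cos(th)[::-1]
        integral = 2.0 * np.pi * np.trapezoid(d[::-1], mu)
        assert integral == pytest.approx(ion_xs.sdcs(6.0, 100.0, q=6),
                                         rel=1e-6)

    def test_invalid_angle_rejected(self, ion_xs):
        with pytest.raises(ValueError):
            ion_xs.ddcs(1.0, 10.0, 3.5)
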