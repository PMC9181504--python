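"""Energy-loss function model: Mermin/Drude/Lindhard, sum rules, fitting."""

import numpy as np
import pytest

from cartrax.constants import ev_to_au
from cartrax.dielectric import (
    ELFModel,
    MerminOscillator,
    TabulatedELF,
    drude_elf,
    f_sum_rule,
    fit_optical_elf,
    kk_sum_rule,
    mean_excitation_energy,
    mermin_elf,
)
from cartrax.fixtures import load_water_optical_table
from cartrax.synthetic import make_synthetic_optical_elf


def lindhard_elf_reference(k, e_ev, kf):
    """Independent Lindhard ELF oracle: textbook real-frequency piecewise
    expressions for Re/Im of the RPA dielectric function (no complex logs).

        z = k/2k_F, u = ω/(k v_F), χ² = 1/(π k_F)
        Re f = 1/2 + (1/8z)[1-(z-u)²]ln|(z-u+1)/(z-u-1)|
                   + (1/8z)[1-(z+u)²]ln|(z+u+1)/(z+u-1)|
        Im f = πu/2                 for z+u ≤ 1
             = (π/8z)[1-(z-u)²]     for |z-u| ≤ 1 ≤ z+u
             = 0                    otherwise
    """
    w = ev_to_au(e_ev)
    z = k / (2.0 * kf)
    u = w / (k * kf)
    chi2 = 1.0 / (np.pi * kf)
    f1 = 0.5 + (1 - (z - u) ** 2) / (8 * z) * np.log(
        abs((z - u + 1) / (z - u - 1))) + (1 - (z + u) ** 2) / (8 * z) * \
        np.log(abs((z + u + 1) / (z + u - 1)))
    if z + u <= 1.0:
        f2 = np.pi * u / 2.0
    elif abs(z - u) <= 1.0 <= z + u:
        f2 = np.pi / (8.0 * z) * (1.0 - (z - u) ** 2)
    else:
        f2 = 0.0
    re = 1.0 + chi2 / z**2 * f1
    im = chi2 / z**2 * f2
    return im / (re**2 + im**2)


class TestMerminELF:
    def test_drude_limit_value(self):
        """k→0 with A=1, ħω=20 eV, ħγ=10 eV at E=20 eV equals the closed-form
        Drude value 2.0."""
        osc = MerminOscillator(1.0, 20.0, 10.0, 0.0)
        assert mermin_elf(0.0, 20.0, osc) == pytest.approx(2.0, rel=1e-12)
        # and the direct Drude expression agrees
        assert drude_elf(20.0, 1.0, 20.0, 10.0) == pytest.approx(2.0)

    def test_threshold_step(self):
        osc = MerminOscillator(0.5, 21.0, 10.0, 7.0)
        assert mermin_elf(1.0, 5.0, osc) == 0.0
        assert mermin_elf(1.0, 6.999, osc) == 0.0
        assert mermin_elf(1.0, 7.01, osc) > 0.0

    @pytest.mark.parametrize("hw,hg", [(10.0, 3.0), (20.0, 10.0), (35.0, 20.0)])
    def test_small_k_matches_drude(self, hw, hg):
        """The Mermin term approaches the Drude ELF as k→0 (1e-6 relative),
        evaluated through the Lindhard route, not the analytic shortcut."""
        osc = MerminOscillator(0.7, hw, hg, 0.0)
        e = np.linspace(2.0, 150.0, 50)
        m = mermin_elf(np.full_like(e, 1e-5), e, osc)
        d = drude_elf(e, 0.7, hw, hg)
        assert np.max(np.abs(m - d) / d) < 1e-6

    def test_gamma_to_zero_is_lindhard(self):
        """γ→0 limit reproduces an independent numerical Lindhard ELF."""
        hw = 20.0
        wp = ev_to_au(hw)
        kf = (3.0 * np.pi**2 * wp**2 / (4.0 * np.pi)) ** (1.0 / 3.0)
        k, e = 0.8, 25.0
        # within the particle-hole continuum the γ→0 Mermin ELF is finite
        osc = MerminOscillator(1.0, hw, 1e-4, 0.0)
        got = mermin_elf(k, e, osc)
        ref = lindhard_elf_reference(k, e, kf)
        assert got == pytest.approx(ref, rel=1e-4)

    def test_elf_non_negative_on_grid(self, water_model):
        k = np.logspace(-3, np.log10(5.0), 100)
        e = np.logspace(0, 4, 100)
        vals = water_model.elf(k[:, None] * np.ones_like(e),
                               np.ones_like(k)[:, None] * e)
        assert np.all(vals >= 0)
        assert np.all(np.isfinite(vals))

    def test_zero_below_threshold(self, water_model):
        e = np.linspace(0.5, 6.9, 10)
        assert np.all(water_model.elf(np.full_like(e, 0.5), e) == 0)

    def test_invalid_inputs_rejected(self, water_model):
        with pytest.raises(ValueError):
            water_model.elf(-1.0, 20.0)
        with pytest.raises(ValueError):
            water_model.elf(np.nan, 20.0)
        with pytest.raises(ValueError):
            MerminOscillator(-1.0, 20.0, 10.0)


class TestTotalELF:
    def test_inner_shell_opens_at_binding(self, water_model):
        """Below the oxygen K edge the total equals the outer sum."""
        k = 0.5
        assert water_model.inner_elf(k, 100.0) == 0.0
        assert water_model.elf(k, 100.0) == pytest.approx(
            water_model.outer_elf(k, 100.0))
        assert water_model.inner_elf(k, 600.0) > 0.0

    def test_optical_peak_matches_packaged_table(self, water_model):
        e_tab, y_tab = load_water_optical_table()
        i = int(np.argmax(y_tab))
        model_val = water_model.outer_elf(0.0, e_tab[i])
        assert model_val == pytest.approx(y_tab[i], rel=0.05)

    def test_kk_sum_rule_consistent_with_refractive_index(self, water_model):
        target = 1.0 - 1.0 / water_model.refractive_index**2
        assert kk_sum_rule(water_model) == pytest.approx(target, rel=0.10)


class TestSumRules:
    def test_f_sum_ten_electrons(self, water_model):
        assert f_sum_rule(water_model, 1e5) == pytest.approx(10.0, abs=0.5)

    def test_f_sum_below_k_edge_outer_only(self, water_model):
        z500 = f_sum_rule(water_model, 500.0)
        ztot = f_sum_rule(water_model, 1e5)
        assert z500 == pytest.approx(8.0, abs=1.0)   # outer shells only
        assert z500 < ztot

    def test_f_sum_monotone(self, water_model):
        vals = [f_sum_rule(water_model, e) for e in (50., 200., 1e3, 1e4, 1e5)]
        assert np.all(np.diff(vals) > 0)

    def test_single_oscillator_analytic_integral(self):
        """∫E·ELF_Drude dE = A(π/2)(ħω)² (a.u.), exact for zero threshold."""
        a, hw, hg = 0.4, 18.0, 9.0
        model = ELFModel([MerminOscillator(a, hw, hg, 0.0)], inner_shells=[],
                         threshold_ev=0.0)
        got = f_sum_rule(model, 1e6)
        expected = a * np.pi / 2.0 * ev_to_au(hw) ** 2 \
            / (2.0 * np.pi**2 * model.density_au)
        assert got == pytest.approx(expected, rel=1e-3)


class TestMeanExcitationEnergy:
    def test_water_fixture_value(self, water_model):
        assert mean_excitation_energy(water_model) == pytest.approx(79.4,
                                                                    rel=0.02)

    def test_delta_like_oscillator(self):
        model = ELFModel([MerminOscillator(1.0, 30.0, 0.01, 0.0)],
                         inner_shells=[], threshold_ev=0.0)
        assert mean_excitation_energy(model) == pytest.approx(30.0, rel=1e-3)

    def test_two_delta_oscillators_geometric_mean(self):
        """Equal f-sum weights at 10 and 40 eV give I = 20 eV.

        The Drude f-sum weight of an oscillator is A·ω², so equal weights
        need A₁ω₁² = A₂ω₂².
        """
        a1 = 1.0
        a2 = a1 * (10.0 / 40.0) ** 2
        model = ELFModel([MerminOscillator(a1, 10.0, 0.005, 0.0),
                          MerminOscillator(a2, 40.0, 0.005, 0.0)],
                         inner_shells=[], threshold_ev=0.0)
        assert mean_excitation_energy(model) == pytest.approx(20.0, rel=1e-3)


class TestOpticalFit:
    def test_single_oscillator_exact_recovery(self):
        e, y = make_synthetic_optical_elf([(0.3, 21.0, 8.0)], noise_level=0.0)
        osc = fit_optical_elf(e, y, 1)
        assert osc[0].amplitude == pytest.approx(0.3, rel=1e-6)
        assert osc[0].position_ev == pytest.approx(21.0, rel=1e-6)
        assert osc[0].width_ev == pytest.approx(8.0, rel=1e-6)

    @pytest.mark.parametrize("truth", [
        [(0.25, 15.0, 6.0)],
        [(0.2, 14.0, 5.0), (0.15, 28.0, 10.0)],
        [(0.15, 12.0, 4.0), (0.2, 21.0, 7.0), (0.05, 40.0, 15.0)],
    ])
    def test_parameter_recovery(self, truth):
        e, y = make_synthetic_optical_elf(truth, noise_level=0.0)
        oscs = fit_optical_elf(e, y, len(truth))
        got = sorted((o.amplitude, o.position_ev, o.width_ev) for o in oscs)
        for g, t in zip(got, sorted(truth)):
            for gv, tv in zip(g, t):
                assert gv == pytest.approx(tv, rel=0.01)

    def test_noisy_recovery_median_error(self, rng):
        """2 oscillators, 5% noise, 50 seeds: median parameter error < 5%."""
        truth = [(0.2, 14.0, 5.0), (0.15, 28.0, 10.0)]
        errs = []
        for seed in range(50):
            e, y = make_synthetic_optical_elf(
                truth, noise_level=0.05, rng=np.random.default_rng(seed))
            try:
                oscs = fit_optical_elf(e, y, 2)
            except RuntimeError:
                errs.append(np.inf)
                continue
            got = sorted((o.amplitude, o.position_ev, o.width_ev)
                         for o in oscs)
            rel = [abs(g - t) / t for gg, tt in zip(got, sorted(truth))
                   for g, t in zip(gg, tt)]
            errs.append(np.median(rel))
        assert np.median(errs) < 0.05

    def test_negative_elf_rejected(self):
        e = np.linspace(8, 100, 50)
        y = np.ones_like(e)
        y[10] = -0.1
        with pytest.raises(ValueError):
            fit_optical_elf(e, y, 1)

    def test_non_increasing_energies_rejected(self):
        e = np.array([8.0, 9.0, 9.0, 10.0])
        with pytest.raises(ValueError):
            fit_optical_elf(e, np.ones(4), 1)

    def test_packaged_table_reproduces_mean_excitation(self, water_model):
        """Refitting the packaged optical table and adding the K shell gives
        back I = 79.4 eV within 2%."""
        e, y = load_water_optical_table()
        oscs = fit_optical_elf(e, y, 5, initial=[
            v for o in water_model.oscillators
            for v in (o.amplitude * 1.15, o.position_ev * 1.05,
                      o.width_ev * 0.9)])
        model = ELFModel(oscs)
        assert mean_excitation_energy(model) == pytest.approx(79.4, rel=0.02)
        assert f_sum_rule(model, 1e5) == pytest.approx(10.0, abs=0.5)


class TestTabulatedELF:
    def test_matches_source_model_on_grid(self, water_model):
        k = np.logspace(-2, 0.5, 120)
        e = np.linspace(7.1, 500.0, 600)
        grid = water_model.outer_elf(k[:, None] * np.ones_like(e),
                                     np.ones_like(k)[:, None] * e)
        tab = TabulatedELF(k, e, grid, inner_shells=water_model.inner_shells)
        kk_, ee_ = 0.3, 25.0
        assert tab.elf(kk_, ee_) == pytest.approx(
            float(water_model.elf(kk_, ee_)), rel=0.02)

    def test_rejects_negative_grid(self):
        with pytest.raises(ValueError):
            TabulatedELF(np.array([0.1, 1.0]), np.array([10.0, 20.0]),
                         np.array([[1.0, -0.1], [0.0, 0.0]]))
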