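"""Radial dose and cluster-size scoring, with closed-form synthetic oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from cartrax.events import (
    KIND_DEA,
    KIND_EXCITATION,
    KIND_IONISATION,
    EventLog,
)
from cartrax.scoring import (
    ClusterGeometry,
    cluster_stats,
    fn_curves,
    mechanism_fractions,
    radial_dose,
    stats_from_counts,
)
from cartrax.synthetic import (
    make_poisson_cluster_log,
    make_ring_log,
    make_synthetic_event_log,
)


class TestRadialDose:
    def test_single_deposit_dose_value(self):
        """100 eV at r = 1 nm in a 0.1 nm shell over L = 50 nm:
        D = E/(ρ·2πr·dr·L) ≈ 5.1e5 Gy with r at the inner shell edge;
        the exact annulus mass used here gives the same up to the
        r = 1.00 vs r̄ = 1.05 convention (factor 1.05)."""
        log = make_ring_log(1.05, edep_ev=100.0, n=1)
        h = radial_dose(log, dr_nm=0.1, length_nm=50.0)
        i = int(1.05 / 0.1)
        mass = 1000.0 * np.pi * ((1.1e-9) ** 2 - (1.0e-9) ** 2) * 50e-9
        expected = 100.0 * 1.602176634e-19 / mass
        assert h.dose_gy[i] == pytest.approx(expected, rel=1e-12)
        assert expected * 1.05 == pytest.approx(5.10e5, rel=0.005)
        assert np.count_nonzero(h.dose_gy) == 1

    def test_empty_log(self):
        h = radial_dose(EventLog.empty(3))
        assert np.all(h.dose_gy == 0)
        assert h.overflow_ev == 0

    def test_energy_closure(self):
        rng = np.random.default_rng(4)
        log = make_synthetic_event_log(
            {"n_histories": 5, "components": [
                {"kind": "ionisation", "n_per_history": 40,
                 "position": lambda r, n: np.column_stack(
                     [r.normal(0, 5, n), r.normal(0, 5, n),
                      r.uniform(0, 50, n)]), "edep_ev": 20.0}]}, rng=rng)
        h = radial_dose(log, dr_nm=0.1, length_nm=50.0, r_max_nm=100.0)
        assert h.energy_closure(log.n_histories, 50.0) < 1e-9

    def test_overflow_reported_not_dropped(self):
        log = make_ring_log(150.0, edep_ev=10.0, n=4)
        h = radial_dose(log, r_max_nm=100.0)
        assert h.overflow_ev == pytest.approx(40.0)
        assert np.all(h.dose_gy == 0)

    def test_ring_hits_exactly_one_shell(self):
        log = make_ring_log(7.23, edep_ev=5.0, n=200)
        h = radial_dose(log, dr_nm=0.1)
        nz = np.nonzero(h.dose_gy)[0]
        assert nz.tolist() == [72]


class TestClusterGeometry:
    def test_contains_cylinder_limits(self):
        g = ClusterGeometry(impact_parameter_nm=2.0)
        assert g.contains([[2.0, 0.0, 25.0]])[0]
        assert g.contains([[2.0 + 3.39, 0.0, 25.0]])[0]      # along the axis
        assert not g.contains([[2.0 + 3.41, 0.0, 25.0]])[0]
        assert g.contains([[2.0, 1.14, 25.0]])[0]            # radial edge
        assert not g.contains([[2.0, 1.16, 25.0]])[0]
        # the cylinder at small impact parameter contains the ion path
        assert g.contains([[0.0, 0.0, 25.5]])[0]


class TestClusterStats:
    def test_degenerate_single_ionisation(self):
        geom = ClusterGeometry(impact_parameter_nm=1.0)
        log = make_synthetic_event_log(
            {"n_histories": 20, "components": [
                {"kind": "ionisation", "n_per_history": 1, "exact": True,
                 "position": [1.0, 0.0, 25.0]}]})
        s = cluster_stats(log, geom)
        assert s.mean_total() == 1.0
        assert s.fn(1) == 1.0
        assert s.fn(2) == 0.0
        assert s.fn(3) == 0.0

    def test_dissociative_fraction_zero_gates_excitations(self, rng):
        geom = ClusterGeometry()
        log = make_synthetic_event_log(
            {"n_histories": 10, "components": [
                {"kind": "ionisation", "n_per_history": 3, "exact": True,
                 "position": [1.0, 0.0, 25.0]},
                {"kind": "excitation", "n_per_history": 5, "exact": True,
                 "position": [1.0, 0.0, 25.0]},
                {"kind": "dea", "n_per_history": 1, "exact": True,
                 "position": [1.0, 0.0, 25.0]}]})
        s = cluster_stats(log, geom, dissociative_fraction=0.0, rng=rng)
        assert s.mean_total() == pytest.approx(4.0)   # ionisations + DEA only
        s2 = cluster_stats(log, geom, dissociative_fraction=1.0, rng=rng)
        assert s2.mean_total() == pytest.approx(9.0)

    def test_dissociative_mean_matches_fraction(self, rng):
        geom = ClusterGeometry()
        log = make_synthetic_event_log(
            {"n_histories": 400, "components": [
                {"kind": "excitation", "n_per_history": 10, "exact": True,
                 "position": [1.0, 0.0, 25.0]}]})
        s = cluster_stats(log, geom, dissociative_fraction=0.4, rng=rng)
        assert np.mean(s.dissociative_excitation) == pytest.approx(
            4.0, abs=3.0 * np.sqrt(10 * 0.4 * 0.6 / 400))

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_stats(EventLog.empty(1), ClusterGeometry(),
                          dissociative_fraction=1.5, rng=rng)

    def test_kernel_counts_match_brute_force_recount(self, small_track):
        """The in-kernel cylinder tallies reproduce an independent
        point-in-cylinder recount of the raw event log exactly."""
        log = small_track.event_log
        cfg = small_track.config
        flags = log.meta["flags"]
        for c, b in enumerate(cfg.impact_parameters_nm):
            geom = ClusterGeometry(
                diameter_nm=cfg.cylinder_diameter_nm,
                height_nm=cfg.cylinder_height_nm,
                impact_parameter_nm=b,
                z_centre_nm=cfg.path_length_nm / 2.0)
            inside = geom.contains(log.position)
            for mech, kind in ((0, KIND_IONISATION), (1, KIND_EXCITATION),
                               (3, KIND_DEA)):
                expect = np.zeros(cfg.n_paths)
                m = inside & (log.kind == kind)
                np.add.at(expect, log.history[m], log.weight[m])
                assert np.allclose(expect, small_track.counts[:, c, mech],
                                   rtol=0, atol=1e-12)
            # dissociative flags recorded during transport
            m = inside & (log.kind == KIND_EXCITATION) & (flags == 1)
            expect = np.zeros(cfg.n_paths)
            np.add.at(expect, log.history[m], log.weight[m])
            assert np.allclose(expect, small_track.counts[:, c, 2],
                               rtol=0, atol=1e-12)

    def test_cluster_stats_uses_recorded_flags(self, small_track):
        cfg = small_track.config
        geom = ClusterGeometry(impact_parameter_nm=cfg.impact_parameters_nm[0],
                               z_centre_nm=cfg.path_length_nm / 2.0)
        s = cluster_stats(small_track.event_log, geom,
                          dissociative_fraction=cfg.dissociative_fraction)
        assert np.allclose(s.dissociative_excitation,
                           small_track.counts[:, 0, 2])


class TestFnCurves:
    def test_poisson_oracle(self, rng):
        """Fₙ of Poisson(μ) clusters equals 1 − CDF(n−1; μ) within binomial
        error."""
        mu, n_hist = 2.5, 3000
        geom = ClusterGeometry(impact_parameter_nm=3.0)
        log = make_poisson_cluster_log(mu, n_hist, geom, rng=rng)
        s = cluster_stats(log, geom, rng=rng)
        assert s.mean_ionisation() == pytest.approx(
            mu, abs=3.0 * np.sqrt(mu / n_hist))
        for n in (1, 2, 3):
            expected = sps.poisson.sf(n - 1, mu)
            tol = 3.0 * np.sqrt(expected * (1 - expected) / n_hist)
            assert s.fn(n) == pytest.approx(expected, abs=tol)

    def test_fn_monotone_in_n(self, small_track):
        stats = stats_from_counts(small_track.counts,
                                  small_track.config.impact_parameters_nm)
        for s in stats:
            assert s.fn(1) >= s.fn(2) >= s.fn(3)

    def test_sorted_by_mean_cluster_size(self, rng):
        geoms = [ClusterGeometry(impact_parameter_nm=b) for b in (1.0, 2.0)]
        stats = [cluster_stats(make_poisson_cluster_log(mu, 200, g, rng=rng),
                               g, rng=rng)
                 for mu, g in zip((4.0, 1.0), geoms)]
        df = fn_curves(stats)
        assert np.all(np.diff(df["mean_ionisation_cluster"]) >= 0)
        assert set(df.columns) >= {"F1", "F2", "F3"}

    def test_needs_two_conditions(self, rng):
        g = ClusterGeometry()
        s = cluster_stats(make_poisson_cluster_log(1.0, 50, g, rng=rng), g,
                          rng=rng)
        with pytest.raises(ValueError):
            fn_curves([s])

    def test_mean_cluster_non_increasing_with_impact_parameter(
            self, small_track):
        stats = stats_from_counts(small_track.counts,
                                  small_track.config.impact_parameters_nm)
        means = np.array([s.mean_total() for s in stats])
        sems = np.array([s.sem_total() for s in stats])
        sems = np.nan_to_num(sems, nan=0.0)
        # allow 2σ statistical violations
        assert np.all(np.diff(means) < 2.0 * np.hypot(sems[1:], sems[:-1])
                      + 1e-12)


class TestMechanismFractions:
    def test_single_mechanism_fraction_one(self, rng):
        g = ClusterGeometry()
        log = make_poisson_cluster_log(3.0, 100, g, rng=rng)
        s = cluster_stats(log, g, rng=rng)
        fr = s.mechanism_fractions()
        assert fr["ionisation"] == pytest.approx(1.0)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_cluster_reported_missing(self):
        g = ClusterGeometry(impact_parameter_nm=50.0)
        log = EventLog.empty(5)
        s = cluster_stats(log, g, rng=np.random.default_rng(0))
        assert s.mechanism_fractions() is None
        df = mechanism_fractions([s])
        assert df.loc[0, "status"] == "missing"

    def test_fractions_sum_to_one(self, small_track):
        stats = stats_from_counts(small_track.counts,
                                  small_track.config.impact_parameters_nm)
        for s in stats:
            fr = s.mechanism_fractions()
            if fr is not None:
                assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)
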