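"""Event-by-event Monte Carlo of secondary-electron transport around an ion path.

A straight carbon-ion path of fixed energy crosses a 50 nm liquid-water
segment.  Ionising collision sites follow an exponential free-flight process
with the charge-weighted, ionisation-restricted inverse mean free path; at
each site a configurable number of statistical electron samples (weight
1/multiplier) is drawn from the ion's secondary-electron energy (SDCS) and
angle (DDCS) distributions and transported to completion through elastic
scattering, impact ionisation, electronic excitation, Fröhlich phonon
emission, polaron trapping and dissociative attachment.

Scoring (radial-dose histogram, per-history cylinder counts) happens inside
the compiled kernel so that full-scale runs do not materialise their event
lists; small runs can record every event into an :class:`cartrax.events.EventLog`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .constants import WATER_MEAN_BINDING_EV
from .events import EventLog

__all__ = ["SimulationConfig", "TransportModel", "TrackResult", "run_track"]


@dataclass
class SimulationConfig:
    """Run configuration for one ion energy."""

    t_mevu: float = 0.2
    path_length_nm: float = 50.0
    n_paths: int = 1200
    multiplier: int = 1000          # statistical electron samples per collision
    cutoff_ev: float = 0.1          # hard kill with local deposit
    master_seed: int = 12345
    dr_nm: float = 0.1
    r_max_nm: float = 100.0
    impact_parameters_nm: tuple = (1.0, 2.0, 3.0, 5.0, 10.0, 20.0, 30.0, 50.0, 100.0)
    cylinder_diameter_nm: float = 2.3
    cylinder_height_nm: float = 6.8
    dissociative_fraction: float = 0.4
    record_events: bool = False
    max_events: int = 2_000_000
    max_steps: int = 1_000_000
    stack_size: int = 200_000

    def __post_init__(self):
        if self.n_paths <= 0:
            raise ValueError("number of ion paths must be positive")
        if self.multiplier < 1:
            raise ValueError("statistical multiplier must be >= 1")
        if self.path_length_nm <= 0 or self.dr_nm <= 0 or self.r_max_nm <= 0:
            raise ValueError("lengths must be positive")
        if self.t_mevu <= 0:
            raise ValueError("ion energy must be positive")

    def path_seeds(self):
        """Independent per-path sub-seeds derived from the master seed."""
        ss = np.random.SeedSequence(int(self.master_seed))
        return (ss.generate_state(self.n_paths) % (2**31 - 1)).astype(np.int64)


@dataclass
class TrackResult:
    """Outputs of one run: scored histograms plus optional event log."""

    config: SimulationConfig
    r_edges_nm: np.ndarray
    dose_ev: np.ndarray          # weighted eV per shell, all histories
    dose_overflow_ev: float
    counts: np.ndarray           # (n_paths, n_cyl, 5) weighted mechanism counts
    budget_ev: np.ndarray
    deposited_ev: np.ndarray
    diagnostics: dict
    event_log: EventLog | None = None

    def radial_dose_gy(self):
        """Mean radial dose per ion path, Gy, from the scored histogram."""
        from .scoring import dose_from_histogram
        return dose_from_histogram(self.r_edges_nm, self.dose_ev,
                                   self.config.path_length_nm,
                                   self.config.n_paths)

    def energy_closure(self):
        b = np.where(self.budget_ev > 0, self.budget_ev, 1.0)
        return float(np.max(np.abs(self.budget_ev - self.deposited_ev) / b,
                            initial=0.0))


class TransportModel:
    """Cross-section tables for one ion energy, reusable across runs."""

    def __init__(self, ion_xs=None, electron_xs=None, elastic_xs=None,
                 low_energy=None, n_energies=240, e_min_ev=0.1,
                 e_max_ev=2.0e5, channels=("elastic", "ionisation",
                                           "excitation", "phonon", "trap",
                                           "dea")):
        from .fixtures import load_water_elf_model
        from .ion import IonCrossSections
        from .inelastic import ElectronInelastic, LowEnergyChannels
        from .elastic import ElasticCrossSections

        model = None
        if ion_xs is None or electron_xs is None:
            model = load_water_elf_model()
        self.ion_xs = ion_xs or IonCrossSections(model)
        self.electron_xs = electron_xs or ElectronInelastic(model)
        self.elastic_xs = elastic_xs or ElasticCrossSections()
        self.low_energy = low_energy or LowEnergyChannels()
        self.channels = set(channels)

        self.egrid = np.logspace(np.log10(e_min_ev), np.log10(e_max_ev),
                                 n_energies)
        self._build_electron_tables()
        self._ion_cache = {}

    # -- electron tables ------------------------------------------------------

    def _build_electron_tables(self):
        eg = self.egrid
        n = eg.size
        ex = self.electron_xs
        on = self.channels
        density = ex.density_nm3

        self.imfp_ion = np.zeros(n)
        self.imfp_exc = np.zeros(n)
        self.b_of_t = np.asarray(ex.binding(eg), dtype=float)
        self.wmax_rows = np.maximum(0.5 * (eg - self.b_of_t), 0.0)
        nx = 96
        self.ion_x = np.concatenate([[0.0], np.logspace(-4, 0, nx - 1)])
        self.ion_cdf_rows = np.zeros((n, nx))
        ny = 48
        self.exc_y = np.linspace(0.0, 1.0, ny)
        self.exc_cdf_rows = np.zeros((n, ny))
        self.ewin_lo = np.zeros(n)
        self.ewin_hi = np.zeros(n)

        for i, t in enumerate(eg):
            if "ionisation" in on and self.wmax_rows[i] > 0:
                w = self.ion_x * self.wmax_rows[i]
                s = ex.ionis_sdcs(t, w)
                cdf = np.concatenate([[0.0], np.cumsum(
                    0.5 * (s[1:] + s[:-1]) * np.diff(w))])
                total = cdf[-1]
                if total > 0:
                    self.imfp_ion[i] = density * total
                    self.ion_cdf_rows[i] = cdf / total
            if "excitation" in on:
                lo, hi = ex.excit_window(t)
                if hi > lo and t > lo:
                    e = lo + self.exc_y * (hi - lo)
                    s = ex.excit_sdcs(t, e)
                    cdf = np.concatenate([[0.0], np.cumsum(
                        0.5 * (s[1:] + s[:-1]) * np.diff(e))])
                    total = cdf[-1]
                    if total > 0:
                        self.imfp_exc[i] = density * total
                        self.exc_cdf_rows[i] = cdf / total
                        self.ewin_lo[i] = lo
                        self.ewin_hi[i] = hi

        self.imfp_el = (1.0 / self.elastic_xs.mfp(eg) if "elastic" in on
                        else np.zeros(n))
        self.imfp_ph = (self.low_energy.phonon(eg) if "phonon" in on
                        else np.zeros(n))
        self.imfp_trap = (self.low_energy.trap(eg) if "trap" in on
                          else np.zeros(n))
        self.imfp_dea = (self.low_energy.dea(eg) if "dea" in on
                         else np.zeros(n))

        el_e, el_mu_desc, el_cdf = self.elastic_xs.sampling_tables()
        # kernel samples cosθ via per-row inverse-CDF tables (equiprobable)
        el_mu = el_mu_desc[::-1].copy()
        el_cdf_asc = np.ascontiguousarray((1.0 - el_cdf)[:, ::-1])
        self.el_loge = np.log(el_e)
        n_inv = 256
        ugrid = np.linspace(0.0, 1.0, n_inv)
        self.el_inv = np.empty((el_e.size, n_inv))
        for i in range(el_e.size):
            self.el_inv[i] = np.interp(ugrid, el_cdf_asc[i], el_mu)
        self.ion_inv = np.empty((n, n_inv))
        self.exc_inv = np.empty((n, n_inv))
        for i in range(n):
            self.ion_inv[i] = np.interp(ugrid, self.ion_cdf_rows[i], self.ion_x)
            self.exc_inv[i] = np.interp(ugrid, self.exc_cdf_rows[i], self.exc_y)

    # -- ion tables ------------------------------------------------------------

    def ion_tables(self, t_mevu, n_w=160, n_thw=40, n_mu=121):
        """Collision density and (W, θ₂) sampling tables at one ion energy."""
        key = round(float(t_mevu), 9)
        if key in self._ion_cache:
            return self._ion_cache[key]
        xs = self.ion_xs
        lam = xs.ionisation_iimfp(t_mevu)
        from .constants import AMU_ME, mevu_to_ev
        emax_ev = 4.0 / (xs.mass_amu * AMU_ME) * mevu_to_ev(t_mevu, xs.mass_amu)
        wmax = max(emax_ev - WATER_MEAN_BINDING_EV, 10.0)
        w = np.concatenate([[0.0], np.logspace(-2, np.log10(wmax), n_w - 1)])
        s = xs.sdcs(t_mevu, w)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (s[1:] + s[:-1])
                                               * np.diff(w))])
        cdf /= cdf[-1]
        # angular tables on a coarse W grid
        thw = np.logspace(-1, np.log10(max(wmax, 1.0)), n_thw)
        mu = np.linspace(-1.0, 1.0, n_mu)
        theta = np.arccos(mu)[::-1]           # ascending θ = descending μ
        th_cdf = np.zeros((n_thw, n_mu))
        for j, wj in enumerate(thw):
            dd = xs.ddcs(t_mevu, wj, theta, salin=True)
            if np.all(dd == 0):
                # isotropic fallback outside the kinematic window
                th_cdf[j] = (mu + 1.0) / 2.0
                continue
            mu_asc = np.cos(theta)[::-1]
            dd_asc = dd[::-1]
            seg = 0.5 * (dd_asc[1:] + dd_asc[:-1]) * np.diff(mu_asc)
            c = np.concatenate([[0.0], np.cumsum(seg)])
            th_cdf[j] = c / c[-1]
        tables = dict(lam_site=lam, w_grid=w, w_cdf=cdf, thw_grid=thw,
                      mu_grid=mu, th_cdf=th_cdf)
        self._ion_cache[key] = tables
        return tables

    # -- running ---------------------------------------------------------------

    def run(self, config: SimulationConfig, _gun_w_ev=0.0) -> TrackResult:
        if _gun_w_ev > 0.0:
            ion = dict(lam_site=1.0, w_grid=np.array([0.0, 1.0]),
                       w_cdf=np.array([0.0, 1.0]),
                       thw_grid=np.array([0.5]),
                       mu_grid=np.array([-1.0, 1.0]),
                       th_cdf=np.array([[0.0, 1.0]]))
        else:
            ion = self.ion_tables(config.t_mevu)
        n_r = int(np.ceil(config.r_max_nm / config.dr_nm))
        dose = np.zeros(n_r + 1)
        cyl_x = np.asarray(config.impact_parameters_nm, dtype=float)
        counts = np.zeros((config.n_paths, cyl_x.size, 5))
        budget = np.zeros(config.n_paths)
        deposited = np.zeros(config.n_paths)
        diag = np.zeros(8)
        cap = config.max_events if config.record_events else 1
        ev_pos = np.zeros((cap, 3))
        ev_kind = np.zeros(cap, dtype=np.uint8)
        ev_edep = np.zeros(cap)
        ev_w = np.zeros(cap)
        ev_hist = np.zeros(cap, dtype=np.int64)
        ev_flag = np.zeros(cap, dtype=np.uint8)
        ev_count = np.zeros(1, dtype=np.int64)
        stack = np.zeros((config.stack_size, 8))

        lg = np.log(self.egrid)
        _kernel.run_paths(
            config.path_seeds(),
            float(ion["lam_site"]), float(config.path_length_nm),
            int(config.multiplier), float(WATER_MEAN_BINDING_EV),
            float(_gun_w_ev),
            ion["w_grid"], ion["w_cdf"], ion["thw_grid"], ion["mu_grid"],
            ion["th_cdf"],
            lg[0], lg[1] - lg[0],
            self.imfp_el, self.imfp_ion, self.imfp_exc, self.imfp_ph,
            self.imfp_trap, self.imfp_dea,
            self.b_of_t, self.wmax_rows,
            self.el_loge[0], self.el_loge[1] - self.el_loge[0],
            self.el_loge.size, self.el_inv,
            self.ion_inv, self.exc_inv,
            self.ewin_lo, self.ewin_hi,
            0.1, float(config.cutoff_ev), float(config.dissociative_fraction),
            float(config.dr_nm), n_r, float(config.path_length_nm) / 2.0,
            float(config.cylinder_diameter_nm) / 2.0,
            float(config.cylinder_height_nm) / 2.0, cyl_x,
            dose, counts, budget, deposited,
            bool(config.record_events), ev_pos, ev_kind, ev_edep, ev_w,
            ev_hist, ev_flag, ev_count, int(config.max_steps), stack, diag)

        log = None
        if config.record_events:
            m = int(ev_count[0])
            if m >= cap:
                raise RuntimeError(
                    "event buffer filled; raise max_events or disable recording")
            log = EventLog(ev_pos[:m].copy(), ev_kind[:m].copy(),
                           ev_edep[:m].copy(), ev_w[:m].copy(),
                           ev_hist[:m].copy(), budget.copy(),
                           deposited.copy(),
                           meta={"flags": ev_flag[:m].copy(),
                                 "config": config})
        diagnostics = {
            "n_primaries": diag[0], "n_secondaries": diag[1],
            "n_electron_events": diag[2], "n_truncated": diag[3],
            "n_ion_collisions": diag[4],
            "secondaries_per_primary": diag[1] / max(diag[0], 1.0),
        }
        return TrackResult(
            config=config,
            r_edges_nm=np.arange(n_r + 1) * config.dr_nm,
            dose_ev=dose[:n_r],
            dose_overflow_ev=float(dose[n_r]),
            counts=counts,
            budget_ev=budget,
            deposited_ev=deposited,
            diagnostics=diagnostics,
            event_log=log,
        )


def run_track(config: SimulationConfig, model: TransportModel | None = None):
    """Convenience one-shot runner (builds tables if not supplied)."""
    model = model or TransportModel()
    return model.run(config)


def run_electrons(model: TransportModel, w_ev, n_electrons, master_seed=1,
                  **config_kw) -> TrackResult:
    """Transport monoenergetic electrons launched isotropically from the
    segment midpoint (an 'electron gun'); full event recording by default.

    Each history holds one primary; useful for channel statistics and
    flight-length diagnostics at a fixed starting energy."""
    config_kw.setdefault("record_events", True)
    cfg = SimulationConfig(t_mevu=1.0, n_paths=int(n_electrons), multiplier=1,
                           master_seed=master_seed, **config_kw)
    return model.run(cfg, _gun_w_ev=float(w_ev))
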