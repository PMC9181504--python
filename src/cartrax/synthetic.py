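"""Synthetic data generators used to exercise and validate the package.

These produce inputs with *known* closed-form answers: optical-ELF tables
built from chosen Drude oscillators (for fit-recovery studies), and event
logs with prescribed spatial/mechanism structure (for scoring oracles,
e.g. Poisson cluster-size statistics or single-shell radial doses).
"""

from __future__ import annotations

import numpy as np

from .dielectric import drude_elf
from .events import (
    KIND_DEA,
    KIND_EXCITATION,
    KIND_IONISATION,
    EventLog,
)

__all__ = ["make_synthetic_optical_elf", "make_synthetic_event_log",
           "make_poisson_cluster_log", "make_ring_log"]


def make_synthetic_optical_elf(oscillators, e_grid_ev=None, noise_level=0.0,
                               rng=None, threshold_ev=7.0):
    """Optical (k=0) ELF table from a Drude sum, with optional multiplicative
    log-normal-ish noise.

    ``oscillators``: iterable of (amplitude, position_eV, width_eV).
    Returns (E_eV, ELF) arrays.
    """
    if noise_level < 0:
        raise ValueError("noise level must be >= 0")
    if e_grid_ev is None:
        e_grid_ev = np.linspace(threshold_ev + 0.05, 200.0, 400)
    e = np.asarray(e_grid_ev, dtype=float)
    y = np.zeros_like(e)
    for a, w, g in oscillators:
        y += drude_elf(e, a, w, g)
    y[e <= threshold_ev] = 0.0
    if noise_level > 0:
        rng = rng or np.random.default_rng(0)
        y = y * (1.0 + noise_level * rng.standard_normal(e.size))
        y = np.clip(y, 0.0, None)
    return e, y


def make_synthetic_event_log(spec, rng=None) -> EventLog:
    """Event log from a declarative spec with known scoring moments.

    ``spec`` is a list of dicts, one per mechanism component::

        {"kind": "ionisation" | "excitation" | "dea",
         "n_per_history": Poisson mean (or exact int with "exact": True),
         "position": callable(rng, n) -> (n, 3) nm,   # or fixed (3,) array
         "edep_ev": float, "weight": float}

    plus ``n_histories``; an empty spec list yields an empty log.
    """
    rng = rng or np.random.default_rng(0)
    if isinstance(spec, dict):
        components = spec.get("components", [])
        n_hist = spec.get("n_histories", 1)
    else:
        components, n_hist = spec, 1
    kinds = {"ionisation": KIND_IONISATION, "excitation": KIND_EXCITATION,
             "dea": KIND_DEA}
    pos_list, kind_list, edep_list, w_list, h_list = [], [], [], [], []
    for comp in components:
        kind = kinds[comp["kind"]]
        for h in range(n_hist):
            if comp.get("exact"):
                n = int(comp["n_per_history"])
            else:
                n = rng.poisson(comp["n_per_history"])
            if n == 0:
                continue
            position = comp["position"]
            p = position(rng, n) if callable(position) else \
                np.tile(np.asarray(position, dtype=float), (n, 1))
            pos_list.append(p)
            kind_list.append(np.full(n, kind, dtype=np.uint8))
            edep_list.append(np.full(n, comp.get("edep_ev", 10.0)))
            w_list.append(np.full(n, comp.get("weight", 1.0)))
            h_list.append(np.full(n, h, dtype=np.int64))
    if not pos_list:
        log = EventLog.empty(n_hist)
        log.budget = np.zeros(n_hist)
        log.deposited = np.zeros(n_hist)
        return log
    return EventLog.from_arrays(
        np.vstack(pos_list), np.concatenate(kind_list),
        np.concatenate(edep_list), np.concatenate(w_list),
        np.concatenate(h_list), n_histories=n_hist)


def make_poisson_cluster_log(mu, n_histories, geom, rng=None,
                             edep_ev=15.0) -> EventLog:
    """Ionisation events Poisson(mu) per history, uniform inside the scoring
    cylinder — the Fₙ oracle is 1 − CDF_Poisson(n−1; mu)."""
    rng = rng or np.random.default_rng(0)

    def inside_cylinder(rng, n):
        rr = geom.diameter_nm / 2.0 * np.sqrt(rng.random(n))
        th = 2.0 * np.pi * rng.random(n)
        x = geom.impact_parameter_nm + (rng.random(n) - 0.5) * geom.height_nm
        y = rr * np.cos(th)
        z = geom.z_centre_nm + rr * np.sin(th)
        return np.column_stack([x, y, z])

    return make_synthetic_event_log(
        {"n_histories": n_histories,
         "components": [{"kind": "ionisation", "n_per_history": mu,
                         "position": inside_cylinder, "edep_ev": edep_ev}]},
        rng=rng)


def make_ring_log(r0_nm, edep_ev=100.0, n=1, z_nm=25.0, rng=None) -> EventLog:
    """Deposits on a ring of fixed radius — nonzero in exactly one dose shell."""
    rng = rng or np.random.default_rng(0)
    phi = 2.0 * np.pi * rng.random(n)
    pos = np.column_stack([r0_nm * np.cos(phi), r0_nm * np.sin(phi),
                           np.full(n, z_nm)])
    return EventLog.from_arrays(
        pos, np.full(n, KIND_IONISATION, dtype=np.uint8),
        np.full(n, edep_ev), np.ones(n), np.zeros(n, dtype=np.int64),
        n_histories=1)
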