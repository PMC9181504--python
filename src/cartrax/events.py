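"""Event records produced by the track-structure Monte Carlo.

Events are stored in flat numpy arrays (one row per interaction) so that
scoring over tens of millions of events stays vectorised.  Kinds:

    0 elastic          no energy deposit
    1 ionisation       binding energy deposited locally by an electron
    2 excitation       full energy transfer deposited locally
    3 phonon           one phonon quantum deposited
    4 trap             polaron trapping; remaining energy deposited, track ends
    5 dea              dissociative attachment; remaining energy deposited
    6 ion_ionisation   ionising collision of the primary ion (binding deposit)
    7 cutoff           sub-cutoff electron killed, residual deposited
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KIND_ELASTIC = 0
KIND_IONISATION = 1
KIND_EXCITATION = 2
KIND_PHONON = 3
KIND_TRAP = 4
KIND_DEA = 5
KIND_ION_IONISATION = 6
KIND_CUTOFF = 7

KIND_NAMES = {
    KIND_ELASTIC: "elastic",
    KIND_IONISATION: "ionisation",
    KIND_EXCITATION: "excitation",
    KIND_PHONON: "phonon",
    KIND_TRAP: "trap",
    KIND_DEA: "dea",
    KIND_ION_IONISATION: "ion_ionisation",
    KIND_CUTOFF: "cutoff",
}

# kinds that deposit energy locally (everything except pure elastic)
DEPOSITING_KINDS = (1, 2, 3, 4, 5, 6, 7)


@dataclass
class EventLog:
    """Flat per-event arrays plus a per-history energy ledger.

    position : (N, 3) float64, nm — ion travels along +z from z=0
    kind     : (N,) uint8
    edep     : (N,) float64, eV deposited at the event site
    weight   : (N,) float64 statistical weight
    history  : (N,) int64 ion-path index
    budget   : (n_hist,) eV — energy handed to secondary electrons (incl. binding)
    deposited: (n_hist,) eV — total weighted deposit recorded per history
    """

    position: np.ndarray
    kind: np.ndarray
    edep: np.ndarray
    weight: np.ndarray
    history: np.ndarray
    budget: np.ndarray
    deposited: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return int(self.kind.size)

    @property
    def n_histories(self) -> int:
        return int(self.budget.size)

    def energy_closure(self):
        """Max relative per-history imbalance |budget − deposited|/budget."""
        b = np.where(self.budget > 0, self.budget, 1.0)
        return float(np.max(np.abs(self.budget - self.deposited) / b, initial=0.0))

    def radius(self):
        """Radial distance of each event from the ion axis (z)."""
        return np.hypot(self.position[:, 0], self.position[:, 1])

    @classmethod
    def empty(cls, n_histories=0):
        return cls(
            position=np.zeros((0, 3)),
            kind=np.zeros(0, dtype=np.uint8),
            edep=np.zeros(0),
            weight=np.zeros(0),
            history=np.zeros(0, dtype=np.int64),
            budget=np.zeros(n_histories),
            deposited=np.zeros(n_histories),
        )

    @classmethod
    def from_arrays(cls, position, kind, edep, weight, history, n_histories=None):
        position = np.atleast_2d(np.asarray(position, dtype=float))
        kind = np.asarray(kind, dtype=np.uint8)
        edep = np.asarray(edep, dtype=float)
        weight = np.asarray(weight, dtype=float)
        history = np.asarray(history, dtype=np.int64)
        if n_histories is None:
            n_histories = int(history.max()) + 1 if history.size else 0
        budget = np.zeros(n_histories)
        deposited = np.zeros(n_histories)
        np.add.at(deposited, history, weight * edep)
        budget[:] = deposited  # synthetic logs are balanced by construction
        return cls(position, kind, edep, weight, history, budget, deposited)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "x_nm": self.position[:, 0],
            "y_nm": self.position[:, 1],
            "z_nm": self.position[:, 2],
            "kind": [KIND_NAMES[k] for k in self.kind],
            "edep_ev": self.edep,
            "weight": self.weight,
            "history": self.history,
        })

    def save_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)
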