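"""Hydrogenic generalised oscillator strength (GOS) for inner shells.

The K shell of oxygen is treated as a scaled hydrogenic 1s level with an
effective nuclear charge fixed by the binding energy, Z_eff = sqrt(2B) (a.u.),
so that the shell ionisation edge sits at B = 540 eV for water.

The bare hydrogenic continuum carries only ~0.435 of the per-electron
oscillator strength in the optical limit (the rest belongs to bound-bound
transitions, which for an inner shell in a condensed target are Pauli-blocked
or merged into the edge).  The GOS is therefore renormalised at each momentum
transfer so the shell integrates to its full occupancy at every k; this keeps
both the optical f-sum and the Bethe sum on the whole surface consistent with
the electron count.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hydrogenic_df_de", "continuum_strength"]

# Bethe's continuum GOS for the 1s level of a hydrogenic system with Z=1,
# per electron, energies in Hartree.  E = (1 + kappa^2)/2 with kappa the
# ejected-electron momentum; Q = q^2 (squared momentum transfer).
_PREFACTOR = 2.0 ** 9


def _df_de_z1(q, e):
    """df/dE (Ha^-1) per electron for Z=1; q (a.u.), e (Ha) arrays."""
    q = np.asarray(q, dtype=float)
    e = np.asarray(e, dtype=float)
    kap2 = 2.0 * e - 1.0
    out = np.zeros(np.broadcast(q, e).shape)
    ok = kap2 > 0
    if not np.any(ok):
        return out
    kap2 = np.broadcast_to(kap2, out.shape)[ok]
    qq = np.broadcast_to(q, out.shape)[ok]
    ee = np.broadcast_to(e, out.shape)[ok]
    kap = np.sqrt(kap2)
    Q = qq**2
    denom_base = (Q - kap2 + 1.0) ** 2 + 4.0 * kap2
    # arctan taken in (0, π) so the phase is continuous through Q = kap2 - 1
    phase = np.arctan2(2.0 * kap, Q - kap2 + 1.0)
    expo = np.exp(-2.0 / kap * phase)
    norm = 1.0 - np.exp(-2.0 * np.pi / kap)
    out[ok] = (_PREFACTOR * ee * (Q + kap2 / 3.0 + 1.0 / 3.0)
               * expo / (denom_base**3 * norm))
    return out


# --- continuum-strength normalisation, universal in scaled variables -------

_QS_GRID = np.concatenate([[0.0], np.logspace(-3, 2.5, 140)])
_FQ_CACHE = None


def _strength_curve():
    """F(q̃) = ∫ df/dE dE per electron at scaled momentum transfer q̃ = q/Z."""
    global _FQ_CACHE
    if _FQ_CACHE is None:
        e = 0.5 * (1.0 + np.logspace(-6, 5.2, 3000) ** 1)  # E from edge upward
        # integrate on a log grid in kappa^2 for accuracy near the edge
        vals = np.empty_like(_QS_GRID)
        for i, q in enumerate(_QS_GRID):
            f = _df_de_z1(q, e)
            vals[i] = np.trapezoid(f, e)
        _FQ_CACHE = vals
    return _FQ_CACHE


def continuum_strength(q_scaled):
    """Per-electron continuum oscillator-strength integral at scaled q."""
    vals = _strength_curve()
    return np.interp(np.asarray(q_scaled, dtype=float), _QS_GRID, vals)


def hydrogenic_df_de(q_au, e_au, binding_au, renormalised=True):
    """df/dE (per Ha, per electron) for a shell of binding energy B (Ha).

    Scaled hydrogenic 1s: Z_eff = sqrt(2B); df/dE scales as Z^-2 with
    q -> q/Z and E -> E/Z².  With ``renormalised`` the curve is divided by
    the continuum strength F(q/Z) so that ∫ df/dE dE = 1 per electron at
    every momentum transfer.
    """
    z = np.sqrt(2.0 * binding_au)
    q = np.asarray(q_au, dtype=float) / z
    e = np.asarray(e_au, dtype=float) / z**2
    df = _df_de_z1(q, e) / z**2
    if renormalised:
        df = df / np.clip(continuum_strength(q), 1e-12, None)
    return df
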