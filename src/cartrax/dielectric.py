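"""Energy-loss function (ELF) of liquid water over the Bethe surface.

The optical-data model used here expresses the outer-shell ELF as a weighted
sum of Mermin-type energy-loss functions fitted to the optical (k=0) spectrum,
and the oxygen K shell as a hydrogenic generalised oscillator strength (GOS).
The Mermin dielectric function extends the Lindhard (RPA) electron-gas
response with a finite plasmon lifetime, and automatically provides the
momentum dispersion of each oscillator without further assumptions.

Everything internal is in Hartree atomic units; public signatures take
momentum transfer in a.u. and energy transfer in eV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares

from .constants import (
    HARTREE_EV,
    WATER_DENSITY_NM3,
    WATER_EXC_THRESHOLD_EV,
    WATER_K_SHELL_EV,
    ev_to_au,
)
from . import gos

__all__ = [
    "MerminOscillator",
    "InnerShell",
    "ELFModel",
    "TabulatedELF",
    "drude_elf",
    "lindhard_epsilon",
    "mermin_epsilon",
    "mermin_elf",
    "total_elf",
    "f_sum_rule",
    "kk_sum_rule",
    "mean_excitation_energy",
    "fit_optical_elf",
    "load_optical_table",
]

_K_OPTICAL_LIMIT = 1e-8  # below this momentum transfer (a.u.) use the Drude form


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MerminOscillator:
    """One Mermin oscillator: amplitude, position ħω (eV), width ħγ (eV),
    threshold (eV).  The amplitude multiplies Im[-1/ε_M], which at k=0
    reduces to the Drude energy-loss function."""

    amplitude: float
    position_ev: float
    width_ev: float
    threshold_ev: float = WATER_EXC_THRESHOLD_EV

    def __post_init__(self):
        if not (np.isfinite(self.amplitude) and self.amplitude > 0):
            raise ValueError(f"oscillator amplitude must be > 0, got {self.amplitude}")
        if not (np.isfinite(self.position_ev) and self.position_ev > 0):
            raise ValueError(f"oscillator position must be > 0, got {self.position_ev}")
        if not (np.isfinite(self.width_ev) and self.width_ev > 0):
            raise ValueError(f"oscillator width must be > 0, got {self.width_ev}")
        if not (np.isfinite(self.threshold_ev) and self.threshold_ev >= 0):
            raise ValueError(f"oscillator threshold must be >= 0, got {self.threshold_ev}")


@dataclass(frozen=True)
class InnerShell:
    """Atomic-like inner shell described by a hydrogenic GOS."""

    element: str = "O"
    shell: str = "1s"
    binding_ev: float = WATER_K_SHELL_EV
    occupancy: float = 2.0
    stoichiometry: float = 1.0   # atoms per molecule

    def __post_init__(self):
        if self.binding_ev <= 0:
            raise ValueError("inner-shell binding energy must be positive")


@dataclass
class ELFModel:
    """Outer Mermin oscillators + inner hydrogenic shells for one material."""

    oscillators: list[MerminOscillator]
    inner_shells: list[InnerShell] = field(default_factory=lambda: [InnerShell()])
    density_nm3: float = WATER_DENSITY_NM3
    threshold_ev: float = WATER_EXC_THRESHOLD_EV
    refractive_index: float = 1.33

    @property
    def density_au(self) -> float:
        from .constants import BOHR_NM
        return self.density_nm3 * BOHR_NM**3

    # cached inner-shell GOS normalisation (set lazily)
    _gos_cache: dict = field(default_factory=dict, repr=False)

    def outer_elf(self, k, e_ev):
        """Outer-shell ELF, Σ_j A_j Im[-1/ε_M(k,E;ω_j,γ_j)] Θ(E−E_th,j)."""
        k = np.asarray(k, dtype=float)
        e_ev = np.asarray(e_ev, dtype=float)
        out = np.zeros(np.broadcast(k, e_ev).shape)
        for osc in self.oscillators:
            out += mermin_elf(k, e_ev, osc)
        return out

    def inner_elf(self, k, e_ev):
        """Inner-shell (K-shell) ELF from the hydrogenic GOS, Θ(E−B)."""
        k = np.asarray(k, dtype=float)
        e_ev = np.asarray(e_ev, dtype=float)
        out = np.zeros(np.broadcast(k, e_ev).shape)
        e_au = ev_to_au(e_ev)
        for sh in self.inner_shells:
            b_au = ev_to_au(sh.binding_ev)
            df = gos.hydrogenic_df_de(k, e_au, b_au, renormalised=True)
            out += (2.0 * np.pi**2 * self.density_au / np.maximum(e_au, 1e-30)) \
                * sh.stoichiometry * sh.occupancy * df
        return out

    def elf(self, k, e_ev):
        """Total ELF = outer + inner contributions."""
        _validate_ke(k, e_ev)
        return self.outer_elf(k, e_ev) + self.inner_elf(k, e_ev)

    def optical_elf(self, e_ev):
        return self.elf(0.0, e_ev)


def _validate_ke(k, e_ev):
    k = np.asarray(k, dtype=float)
    e = np.asarray(e_ev, dtype=float)
    if not (np.all(np.isfinite(k)) and np.all(np.isfinite(e))):
        raise ValueError("momentum/energy transfer must be finite")
    if np.any(k < 0):
        raise ValueError("momentum transfer must be >= 0")
    if np.any(e < 0):
        raise ValueError("energy transfer must be >= 0")


# ---------------------------------------------------------------------------
# Lindhard / Mermin / Drude building blocks
# ---------------------------------------------------------------------------

def drude_elf(e_ev, amplitude, position_ev, width_ev):
    """Drude-type ELF  A·E·ħγ·(ħω)² / {[(ħω)²−E²]² + (E·ħγ)²}  (eV inputs).

    This is the exact k=0 limit of the Mermin-type term A·Im[-1/ε_M].
    """
    e = np.asarray(e_ev, dtype=float)
    w2 = position_ev**2
    num = amplitude * w2 * e * width_ev
    den = (w2 - e**2) ** 2 + (e * width_ev) ** 2
    return num / den


def lindhard_epsilon(k_au, omega_au, kf_au):
    """Lindhard (RPA electron gas) dielectric function at complex frequency.

    Closed-form expression with principal-value complex logarithms:
        z = k/(2 k_F),  u = ω/(k v_F),  χ² = 1/(π k_F)
        ε = 1 + χ²/z² · { 1/2 + [1−(z−u)²]/(8z) L(z−u) + [1−(z+u)²]/(8z) L(z+u) }
    with L(x) = log((x+1)/(x−1)).  For Im ω > 0 the log arguments stay off the
    branch cut; the two terms carry opposite-sign imaginary offsets that cancel
    in the γ→0 static limit.
    """
    k = np.asarray(k_au, dtype=float)
    w = np.asarray(omega_au, dtype=complex)
    if np.any(k <= 0):
        raise ValueError("lindhard_epsilon requires k > 0 (use the Drude limit at k=0)")
    vf = kf_au
    z = k / (2.0 * kf_au)
    u = w / (k * vf)
    chi2 = 1.0 / (np.pi * kf_au)
    zm = z - u
    zp = z + u
    # The closed form cancels catastrophically when |z ± u| is large (small k
    # and/or large ω).  There, evaluate f through its Laurent expansion: with
    # g(x) = (1−x²)log((x+1)/(x−1)) = 2[−x + (2/3)/x + (2/15)/x³ + (2/35)/x⁵ + …],
    #   f = (1/3)/(z²−u²) + (1/30)(2z²+6u²)/(z²−u²)³
    #     + (1/70)(2z⁴+20z²u²+10u⁴)/(z²−u²)⁵ + …
    # whose leading term reproduces ε → 1 − ω_p²/ω².
    big = np.minimum(np.abs(zm), np.abs(zp)) > 40.0
    f = np.empty(np.broadcast(z, u).shape, dtype=complex)
    if np.any(~big):
        zmn = zm[~big] if zm.shape == f.shape else np.broadcast_to(zm, f.shape)[~big]
        zpn = zp[~big] if zp.shape == f.shape else np.broadcast_to(zp, f.shape)[~big]
        zn = np.broadcast_to(z, f.shape)[~big]
        lm = np.log((zmn + 1.0) / (zmn - 1.0))
        lp = np.log((zpn + 1.0) / (zpn - 1.0))
        f[~big] = (0.5 + (1.0 - zmn**2) / (8.0 * zn) * lm
                   + (1.0 - zpn**2) / (8.0 * zn) * lp)
    if np.any(big):
        zb = np.broadcast_to(z, f.shape)[big]
        ub = np.broadcast_to(u, f.shape)[big]
        d = zb**2 - ub**2
        f[big] = ((1.0 / 3.0) / d
                  + (2.0 * zb**2 + 6.0 * ub**2) / (30.0 * d**3)
                  + (2.0 * zb**4 + 20.0 * zb**2 * ub**2 + 10.0 * ub**4) / (70.0 * d**5))
    return 1.0 + chi2 / np.asarray(z) ** 2 * f


def lindhard_epsilon_static(k_au, kf_au):
    """Real static limit ε_L(k, 0)."""
    k = np.asarray(k_au, dtype=float)
    z = k / (2.0 * kf_au)
    chi2 = 1.0 / (np.pi * kf_au)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.log(np.abs((1.0 + z) / (1.0 - z)))
        f = 0.5 + (1.0 - z**2) / (4.0 * z) * log_term
    return 1.0 + chi2 / z**2 * f


def mermin_epsilon(k_au, e_ev, position_ev, width_ev):
    """Mermin dielectric function for one oscillator (position, width in eV).

    ε_M = 1 + (1 + iγ/ω)(ε_L(k, ω+iγ) − 1) /
              {1 + (iγ/ω)(ε_L(k, ω+iγ) − 1)/(ε_L(k,0) − 1)}

    The plasmon energy ħω_j fixes the electron-gas density via ω_p² = 4πn.
    """
    w = ev_to_au(e_ev)
    wp = ev_to_au(position_ev)
    g = ev_to_au(width_ev)
    n = wp**2 / (4.0 * np.pi)
    kf = (3.0 * np.pi**2 * n) ** (1.0 / 3.0)
    wc = w + 1j * g
    el = lindhard_epsilon(k_au, wc, kf)
    el0 = lindhard_epsilon_static(k_au, kf)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (1.0 + 1j * g / w) * (el - 1.0)
        den = 1.0 + (1j * g / w) * (el - 1.0) / (el0 - 1.0)
        eps = 1.0 + num / den
    # at very large k the static response el0 → 1 and the Mermin correction
    # degenerates; the loss function is vanishingly small there
    eps = np.where(np.isfinite(eps), eps, 1.0)
    return eps


def mermin_elf(k_au, e_ev, osc: MerminOscillator):
    """ELF contribution of one oscillator: A·Im[-1/ε_M]·Θ(E − E_th).

    k = 0 is routed to the analytic Drude limit (to which the Mermin term
    reduces exactly in the optical limit).
    """
    k = np.asarray(k_au, dtype=float)
    e = np.asarray(e_ev, dtype=float)
    _validate_ke(k, e)
    k, e = np.broadcast_arrays(k, e)
    out = np.zeros(k.shape)
    above = e > osc.threshold_ev
    small_k = k <= _K_OPTICAL_LIMIT
    m = above & small_k
    if np.any(m):
        out[m] = drude_elf(e[m], osc.amplitude, osc.position_ev, osc.width_ev)
    m = above & ~small_k
    if np.any(m):
        eps = mermin_epsilon(k[m], e[m], osc.position_ev, osc.width_ev)
        out[m] = osc.amplitude * np.imag(-1.0 / eps)
    return np.clip(out, 0.0, None) if out.ndim else float(max(out, 0.0))


def total_elf(model: ELFModel, k_au, e_ev):
    """Total ELF of the model (outer Mermin sum + inner GOS term)."""
    return model.elf(k_au, e_ev)


# ---------------------------------------------------------------------------
# sum rules and moments
# ---------------------------------------------------------------------------

def _optical_moment(model, weight, e_max_ev, rel_tol=1e-6):
    """∫ weight(E)·ELF(0,E) dE (energies in a.u.) split at shell edges."""
    e_th = ev_to_au(model.threshold_ev)
    e_max = ev_to_au(e_max_ev)
    edges = [e_th]
    for sh in model.inner_shells:
        b = ev_to_au(sh.binding_ev)
        if e_th < b < e_max:
            edges.append(b)
    edges.append(e_max)
    edges = sorted(edges)
    # geometric sub-panels: adaptive quadrature on one huge interval loses
    # the localised oscillator peaks
    panels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_sub = max(1, int(np.ceil(np.log(hi / max(lo, 1e-6)) / np.log(3.0))))
        panels.extend(np.geomspace(max(lo, 1e-6), hi, n_sub + 1)[:-1])
    panels.append(e_max)

    def f(e_au):
        return weight(e_au) * model.optical_elf(e_au * HARTREE_EV)

    total = 0.0
    for lo, hi in zip(panels[:-1], panels[1:]):
        val, _ = quad(f, lo, hi, epsrel=rel_tol, limit=200)
        total += val
    return total


def f_sum_rule(model: ELFModel, e_max_ev=1e5):
    """Effective number of electrons per molecule below E_max:

        Z_eff(E_max) = 1/(2π²N) ∫_0^{E_max} E·ELF(0,E) dE     (a.u.)
    """
    if e_max_ev <= model.threshold_ev:
        raise ValueError("E_max must exceed the excitation threshold")
    s = _optical_moment(model, lambda e: e, e_max_ev)
    return s / (2.0 * np.pi**2 * model.density_au)


def kk_sum_rule(model: ELFModel, e_max_ev=1e5):
    """Kramers–Kronig (perfect-screening) sum (2/π)∫ ELF(0,E)/E dE.

    For an insulator this should approach 1 − 1/n² with n the static
    refractive index.
    """
    s = _optical_moment(model, lambda e: 1.0 / e, e_max_ev)
    return 2.0 / np.pi * s


def mean_excitation_energy(model: ELFModel, e_max_ev=1e5):
    """Mean excitation energy I (eV) from the Bethe logarithmic moment

        ln I = ∫E·lnE·ELF(0,E) dE / ∫E·ELF(0,E) dE.
    """
    num = _optical_moment(model, lambda e: e * np.log(e), e_max_ev)
    den = _optical_moment(model, lambda e: e, e_max_ev)
    return float(np.exp(num / den) * HARTREE_EV)


# ---------------------------------------------------------------------------
# optical-table IO and Drude-sum fitting
# ---------------------------------------------------------------------------

def load_optical_table(path):
    """Read a 2-column (E_eV, ELF) delimited text table; '#' lines ignored."""
    arr = np.loadtxt(path, comments="#")
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("optical table must have two columns (E_eV, ELF)")
    return arr[:, 0], arr[:, 1]


def _drude_sum(e_ev, params, thresholds):
    """Drude-sum model with params = [A1,w1,g1, A2,w2,g2, ...]."""
    out = np.zeros_like(np.asarray(e_ev, dtype=float))
    for j in range(len(params) // 3):
        a, w, g = params[3 * j: 3 * j + 3]
        out += drude_elf(e_ev, a, w, g) * (np.asarray(e_ev) > thresholds[j])
    return out


def fit_optical_elf(energy_ev, elf, n_oscillators, thresholds=None,
                    initial=None, max_rel_residual=0.15):
    """Least-squares Drude-sum fit of an optical (k=0) ELF table.

    Returns a list of MerminOscillator.  The fit is performed in log-parameter
    space to keep amplitudes, positions and widths positive.  Non-convergence
    or a residual above ``max_rel_residual`` (relative to the table maximum)
    raises with residual diagnostics.
    """
    e = np.asarray(energy_ev, dtype=float)
    y = np.asarray(elf, dtype=float)
    if e.ndim != 1 or e.size < 3 * n_oscillators:
        raise ValueError("optical table too short for the requested fit")
    if np.any(np.diff(e) <= 0):
        raise ValueError("optical table energies must be strictly increasing")
    if np.any(y < 0):
        raise ValueError("optical ELF values must be non-negative")
    if thresholds is None:
        thresholds = [WATER_EXC_THRESHOLD_EV] * n_oscillators
    thresholds = list(np.broadcast_to(thresholds, (n_oscillators,)))

    if initial is None:
        initial = _initial_oscillator_guess(e, y, n_oscillators, thresholds)
    p0 = np.log(np.asarray(initial, dtype=float))

    scale = max(y.max(), 1e-12)

    def residuals(logp):
        return (_drude_sum(e, np.exp(logp), thresholds) - y) / scale

    sol = least_squares(residuals, p0, method="lm", xtol=1e-14, ftol=1e-14,
                        max_nfev=20000)
    res = np.abs(sol.fun)
    if not sol.success or res.max() > max_rel_residual:
        raise RuntimeError(
            "optical-ELF fit did not converge: status=%s, max residual %.3g "
            "(relative to table max), rms %.3g"
            % (sol.status, res.max(), np.sqrt(np.mean(res**2)))
        )
    p = np.exp(sol.x)
    oscs = [
        MerminOscillator(p[3 * j], p[3 * j + 1], p[3 * j + 2], thresholds[j])
        for j in range(n_oscillators)
    ]
    return sorted(oscs, key=lambda o: o.position_ev)


def _initial_oscillator_guess(e, y, n, thresholds):
    """Greedy peak-based starting point for the Drude-sum fit."""
    params = []
    resid = y.copy()
    for j in range(n):
        i = int(np.argmax(resid))
        w = max(e[i], thresholds[j] + 1.0)
        g = max(0.3 * w, 1.0)
        # at the peak, drude_elf(w; A, w, g) = A*w/g  ->  A = y_peak*g/w
        a = max(resid[i], 1e-3 * y.max()) * g / w
        params += [a, w, g]
        resid = np.clip(resid - _drude_sum(e, [a, w, g], [thresholds[j]]), 0.0, None)
    return params


# ---------------------------------------------------------------------------
# tabulated ELF (externally computed Bethe surfaces)
# ---------------------------------------------------------------------------

class TabulatedELF:
    """ELF given on a (k, E) grid, bilinear in (log k, E), zero outside.

    Allows externally computed excitation spectra (e.g. first-principles
    Bethe surfaces) to be used through the same interface as the oscillator
    model.  An optional inner-shell model supplies the high-E continuation.
    """

    def __init__(self, k_au, e_ev, elf_grid, density_nm3=WATER_DENSITY_NM3,
                 threshold_ev=WATER_EXC_THRESHOLD_EV, inner_shells=None,
                 refractive_index=1.33):
        k = np.asarray(k_au, dtype=float)
        e = np.asarray(e_ev, dtype=float)
        z = np.asarray(elf_grid, dtype=float)
        if z.shape != (k.size, e.size):
            raise ValueError("elf_grid shape must be (n_k, n_E)")
        if np.any(z < 0):
            raise ValueError("tabulated ELF must be non-negative")
        if np.any(k <= 0) or np.any(np.diff(k) <= 0) or np.any(np.diff(e) <= 0):
            raise ValueError("k and E axes must be positive and strictly increasing")
        self._logk = np.log(k)
        self._e = e
        self._z = z
        self.density_nm3 = density_nm3
        self.threshold_ev = threshold_ev
        self.refractive_index = refractive_index
        self.inner_shells = inner_shells or []
        self.oscillators = []

    @property
    def density_au(self):
        from .constants import BOHR_NM
        return self.density_nm3 * BOHR_NM**3

    def outer_elf(self, k, e_ev):
        k = np.atleast_1d(np.asarray(k, dtype=float))
        e = np.atleast_1d(np.asarray(e_ev, dtype=float))
        k, e = np.broadcast_arrays(k, e)
        lk = np.log(np.clip(k, np.exp(self._logk[0]), None))
        ik = np.clip(np.searchsorted(self._logk, lk) - 1, 0, self._logk.size - 2)
        ie = np.clip(np.searchsorted(self._e, e) - 1, 0, self._e.size - 2)
        tk = np.clip((lk - self._logk[ik]) / (self._logk[ik + 1] - self._logk[ik]), 0, 1)
        te = np.clip((e - self._e[ie]) / (self._e[ie + 1] - self._e[ie]), 0, 1)
        z = self._z
        val = ((1 - tk) * (1 - te) * z[ik, ie] + tk * (1 - te) * z[ik + 1, ie]
               + (1 - tk) * te * z[ik, ie + 1] + tk * te * z[ik + 1, ie + 1])
        val[(e < self.threshold_ev) | (e > self._e[-1])] = 0.0
        return val

    def inner_elf(self, k, e_ev):
        return ELFModel.inner_elf(self, k, e_ev) if self.inner_shells \
            else np.zeros(np.broadcast(np.asarray(k), np.asarray(e_ev)).shape)

    def elf(self, k, e_ev):
        _validate_ke(k, e_ev)
        return self.outer_elf(k, e_ev) + self.inner_elf(k, e_ev)

    def optical_elf(self, e_ev):
        return self.elf(np.exp(self._logk[0]), e_ev)
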