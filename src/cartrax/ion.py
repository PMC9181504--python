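"""Dielectric-formalism cross sections for swift carbon ions in liquid water.

The doubly differential interaction probability per unit path for an ion of
mass M, kinetic energy T and charge state q is

    P_q(T,k,E) = (1/π)(M/T) [Z − ρ_q(k)]² (1/k) Im[−1/ε(k,E)]      (a.u.)

with ρ_q(k) the Brandt–Kitagawa form factor of the partially stripped ion.
Statistical moments of order n give the inverse inelastic mean free path
(n=0), the stopping power (n=1) and the energy-loss straggling (n=2); for a
heavy projectile the integration limits simplify to k⁻ = E/v, k⁺ → ∞,
E⁺ → ∞.  Equilibrium charge-state fractions weight the per-state moments.

Kinematics are nonrelativistic throughout (documented approximation; the
Bohr straggling limit and the Bethe asymptote emerge from the sum rules of
the energy-loss function).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    AMU_ME,
    BOHR_NM,
    CARBON_A,
    CARBON_Z,
    HARTREE_EV,
    WATER_K_SHELL_EV,
    WATER_MEAN_BINDING_EV,
    au_to_ev,
    ev_to_au,
    mevu_to_ev,
)

__all__ = [
    "IonProjectile",
    "ChargeFractionModel",
    "bk_screening_length",
    "bk_form_factor",
    "IonCrossSections",
    "salin_factor",
]


@dataclass(frozen=True)
class IonProjectile:
    """Projectile nucleus; q=None means equilibrium charge-state mixture."""

    z: int = CARBON_Z
    mass_amu: float = CARBON_A
    energy_ev: float = 1e6 * CARBON_A
    q: int | None = None

    def __post_init__(self):
        if self.energy_ev <= 0:
            raise ValueError("kinetic energy must be positive")
        if self.q is not None and not (0 <= self.q <= self.z):
            raise ValueError(f"charge state must be in 0..{self.z}")

    @property
    def mass_me(self) -> float:
        return self.mass_amu * AMU_ME

    @property
    def energy_mevu(self) -> float:
        return self.energy_ev / (1e6 * self.mass_amu)

    @property
    def speed_au(self) -> float:
        return float(np.sqrt(2.0 * ev_to_au(self.energy_ev) / self.mass_me))

    @classmethod
    def carbon(cls, t_mevu, q=None):
        return cls(CARBON_Z, CARBON_A, mevu_to_ev(t_mevu), q)


class ChargeFractionModel:
    """Equilibrium charge-state fractions φ_q(T), log-T interpolated.

    Rows are renormalised after interpolation so Σ_q φ_q = 1 exactly.
    """

    def __init__(self, t_mevu, phi):
        t = np.asarray(t_mevu, dtype=float)
        p = np.asarray(phi, dtype=float)
        if p.ndim != 2 or p.shape[0] != t.size:
            raise ValueError("phi must be (nT, nQ)")
        if np.any(p < 0):
            raise ValueError("charge fractions must be non-negative")
        self._logt = np.log(t)
        self._phi = p / p.sum(axis=1, keepdims=True)
        self.n_states = p.shape[1]

    @classmethod
    def default(cls):
        from .fixtures import load_charge_fraction_table
        return cls(*load_charge_fraction_table())

    def fractions(self, t_mevu):
        lt = np.log(np.asarray(t_mevu, dtype=float))
        out = np.empty(np.atleast_1d(lt).shape + (self.n_states,))
        for q in range(self.n_states):
            out[..., q] = np.interp(lt, self._logt, self._phi[:, q])
        out /= out.sum(axis=-1, keepdims=True)
        return out.reshape(np.shape(lt) + (self.n_states,)) if np.ndim(lt) \
            else out[0]


def bk_screening_length(q, z=CARBON_Z):
    """Brandt–Kitagawa variational screening length Λ_q (a.u.):

        Λ = 2·0.48·ξ^{2/3} / [Z^{1/3}(1 − ξ/7)],   ξ = (Z−q)/Z.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > z)):
        raise ValueError(f"charge state must be in 0..{z}")
    xi = (z - q) / z
    with np.errstate(divide="ignore"):
        lam = 2.0 * 0.48 * xi ** (2.0 / 3.0) / (z ** (1.0 / 3.0) * (1.0 - xi / 7.0))
    return lam


def bk_form_factor(q, k_au, z=CARBON_Z):
    """Effective charge [Z − ρ_q(k)] seen at momentum transfer k:

        ρ_q(k) = (Z − q) / (1 + (kΛ_q)²)

    → q at k=0 (full screening) and Z as k→∞ (bare nucleus).
    """
    q = np.asarray(q, dtype=float)
    k = np.asarray(k_au, dtype=float)
    if np.any(k < 0):
        raise ValueError("momentum transfer must be >= 0")
    lam = bk_screening_length(q, z)
    rho = (z - q) / (1.0 + (k * lam) ** 2)
    return z - rho


def salin_factor(t_ev, w_ev, theta2, mass_me, binding_ev):
    """Two-centre (electron capture to the continuum) enhancement F_S = u/(1−e^{−u})

    with u = 2π√B [ (v_i²/2 + W − v_i v_e cosθ₂)^{−1/2} − (v_i²/2)^{−1/2} ]  (a.u.)
    """
    t = ev_to_au(t_ev)
    w = np.asarray(ev_to_au(w_ev), dtype=float)
    b = ev_to_au(binding_ev)
    tm = t / mass_me  # v_i²/2
    arg = tm + w - 2.0 * np.sqrt(tm * w) * np.cos(theta2)
    arg = np.maximum(arg, 1e-30)
    u = 2.0 * np.pi * np.sqrt(b) * (arg ** -0.5 - tm ** -0.5)
    out = np.where(np.abs(u) < 1e-8, 1.0, u / (1.0 - np.exp(-u)))
    return out


class IonCrossSections:
    """Precomputed Bethe-surface tables and the ion energy-loss quantities.

    The outer- and inner-shell ELF are evaluated once on a log (k, E) grid;
    the k-integral entering every moment is stored as a reversed cumulative
    table G_q(k*, E) = ∫_{k*} [Z−ρ_q(k)]² ELF(k,E) dk/k, so each moment
    reduces to a single E-quadrature with k* = E/v.
    """

    def __init__(self, elf_model, charge_fractions=None, z=CARBON_Z,
                 mass_amu=CARBON_A, n_k=336, n_e=512,
                 k_range_au=(1e-3, 600.0), e_max_ev=3.2e6):
        self.model = elf_model
        self.z = z
        self.mass_amu = mass_amu
        self.mass_me = mass_amu * AMU_ME
        self.charge_fractions = charge_fractions or ChargeFractionModel.default()
        self.density_au = elf_model.density_au

        e_th = elf_model.threshold_ev
        self._k = np.logspace(np.log10(k_range_au[0]), np.log10(k_range_au[1]), n_k)
        self._e_ev = np.logspace(np.log10(e_th * 1.0001), np.log10(e_max_ev), n_e)
        kk = self._k[:, None]
        ee = self._e_ev[None, :]
        outer = elf_model.outer_elf(np.broadcast_to(kk, (n_k, n_e)),
                                    np.broadcast_to(ee, (n_k, n_e)))
        inner = elf_model.inner_elf(np.broadcast_to(kk, (n_k, n_e)),
                                    np.broadcast_to(ee, (n_k, n_e)))
        self._g = {}  # (q, shell) -> G table (n_k, n_e)
        lnk = np.log(self._k)
        for q in range(z + 1):
            w2 = bk_form_factor(q, self._k, z) ** 2
            for shell, elf in (("outer", outer), ("inner", inner)):
                integ = w2[:, None] * elf  # already includes 1/k via d(ln k)
                # reversed cumulative trapezoid in ln k:  ∫ f dk/k = ∫ f dlnk
                seg = 0.5 * (integ[1:, :] + integ[:-1, :]) * np.diff(lnk)[:, None]
                g = np.zeros_like(integ)
                g[:-1, :] = seg[::-1].cumsum(axis=0)[::-1]
                self._g[(q, shell)] = g

    # -- low-level lookups --------------------------------------------------

    def _g_at(self, q, shell, k_star_au, e_ev):
        """G_q(k*, E) interpolated bilinearly in (ln k*, ln E)."""
        g = self._g[(q, shell)]
        lk = np.log(np.clip(k_star_au, self._k[0], self._k[-1]))
        le = np.log(np.clip(e_ev, self._e_ev[0], self._e_ev[-1]))
        lkg = np.log(self._k)
        leg = np.log(self._e_ev)
        ik = np.clip(np.searchsorted(lkg, lk) - 1, 0, lkg.size - 2)
        ie = np.clip(np.searchsorted(leg, le) - 1, 0, leg.size - 2)
        tk = (lk - lkg[ik]) / (lkg[ik + 1] - lkg[ik])
        te = (le - leg[ie]) / (leg[ie + 1] - leg[ie])
        val = ((1 - tk) * (1 - te) * g[ik, ie] + tk * (1 - te) * g[ik + 1, ie]
               + (1 - tk) * te * g[ik, ie + 1] + tk * te * g[ik + 1, ie + 1])
        # outside the tabulated E range the ELF is zero
        val = np.where(np.asarray(e_ev) > self._e_ev[-1], 0.0, val)
        val = np.where(np.asarray(e_ev) < self._e_ev[0], 0.0, val)
        return val

    # -- doubly differential probability ------------------------------------

    def iddcs(self, ion: IonProjectile, k_au, e_ev):
        """P_q(T,k,E) per unit path/energy/momentum (nm⁻¹ eV⁻¹ a.u.⁻¹).

        Zero outside the kinematic window ħk± = √(2M)(√T ± √(T−E)) and for
        E above 4(m/M)T or below the excitation threshold.
        """
        k = np.asarray(k_au, dtype=float)
        e = np.asarray(e_ev, dtype=float)
        if np.any(~np.isfinite(k)) or np.any(~np.isfinite(e)):
            raise ValueError("inputs must be finite")
        t = ev_to_au(ion.energy_ev)
        m = ion.mass_me
        e_au = ev_to_au(e)
        emax = 4.0 * (1.0 / m) * t  # 4(m/M)T with m_e = 1
        inside = (e_au > ev_to_au(self.model.threshold_ev)) & (e_au < emax) \
            & (e_au < t)
        root = np.sqrt(np.maximum(t - np.where(inside, e_au, 0.0), 0.0))
        kminus = np.sqrt(2.0 * m) * (np.sqrt(t) - root)
        kplus = np.sqrt(2.0 * m) * (np.sqrt(t) + root)
        inside &= (k >= kminus) & (k <= kplus) & (k > 0)
        elf = self.model.elf(np.where(k > 0, k, 1.0), e)
        if ion.q is None:
            phi = self.charge_fractions.fractions(ion.energy_mevu)
            w2 = sum(phi[q] * bk_form_factor(q, k, self.z) ** 2
                     for q in range(self.z + 1))
        else:
            w2 = bk_form_factor(ion.q, k, self.z) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (1.0 / np.pi) * (m / t) * w2 * elf / k
        p = np.where(inside, p, 0.0)
        # per a.u. path & per Ha → per nm & per eV
        return p / BOHR_NM / HARTREE_EV

    # -- statistical moments -------------------------------------------------

    def moment(self, t_mevu, n, q=None, shells=("outer", "inner")):
        """Charge-state moment M_qⁿ(T) or the charge-weighted Mⁿ(T).

        Units: n=0 → nm⁻¹; n=1 → eV/nm; n=2 → eV²/nm.
        """
        if n not in (0, 1, 2):
            raise ValueError("moment order must be 0, 1 or 2")
        t_ev = mevu_to_ev(np.asarray(t_mevu, dtype=float), self.mass_amu)
        t = ev_to_au(t_ev)
        v = np.sqrt(2.0 * t / self.mass_me)
        e_au = ev_to_au(self._e_ev)
        kstar = e_au[None, :] / np.atleast_1d(v)[:, None]   # (nT, nE)
        e_b = np.broadcast_to(self._e_ev[None, :], kstar.shape)
        if q is None:
            phi = np.atleast_2d(self.charge_fractions.fractions(
                np.atleast_1d(t_mevu)))
            gsum = np.zeros_like(kstar)
            for qq in range(self.z + 1):
                gq = sum(self._g_at(qq, sh, kstar, e_b) for sh in shells)
                gsum += phi[:, qq][:, None] * gq
        else:
            gsum = sum(self._g_at(q, sh, kstar, e_b) for sh in shells)
        integrand = e_au[None, :] ** n * gsum
        mom = np.trapezoid(integrand, e_au, axis=1)
        mom *= 2.0 / (np.pi * np.atleast_1d(v) ** 2)
        # a.u. (Haⁿ/a0) → eVⁿ/nm
        mom *= HARTREE_EV ** n / BOHR_NM
        return mom if np.ndim(t_mevu) else float(mom[0])

    def iimfp(self, t_mevu, q=None):
        """Inverse inelastic mean free path (nm⁻¹)."""
        return self.moment(t_mevu, 0, q)

    def stopping_power(self, t_mevu, q=None):
        """Electronic stopping power (eV/nm)."""
        return self.moment(t_mevu, 1, q)

    def straggling(self, t_mevu, q=None):
        """Energy-loss straggling Ω² (eV²/nm)."""
        return self.moment(t_mevu, 2, q)

    def bohr_straggling(self):
        """High-velocity Bohr limit Ω_B² = 4πe⁴NZ²Z_t (eV²/nm)."""
        from .constants import WATER_Z_PER_MOLECULE
        val = 4.0 * np.pi * self.density_au * self.z ** 2 * WATER_Z_PER_MOLECULE
        return val * HARTREE_EV ** 2 / BOHR_NM

    # -- secondary-electron spectra ------------------------------------------

    def _shell_binding(self, shell):
        return WATER_MEAN_BINDING_EV if shell == "outer" else WATER_K_SHELL_EV

    def sdcs(self, t_mevu, w_ev, q=None):
        """Ionisation SDCS dσ/dW (nm²/eV per molecule), charge-weighted if
        q is None.  Hard kinematic cutoff at E = 4(m/M)T."""
        t_ev = mevu_to_ev(t_mevu, self.mass_amu)
        t = ev_to_au(t_ev)
        v = np.sqrt(2.0 * t / self.mass_me)
        w = np.atleast_1d(np.asarray(w_ev, dtype=float))
        if np.any(w < 0):
            raise ValueError("ejected-electron energy must be >= 0")
        emax_ev = au_to_ev(4.0 * t / self.mass_me)
        out = np.zeros_like(w)
        qs = range(self.z + 1) if q is None else [q]
        phi = (self.charge_fractions.fractions(t_mevu) if q is None
               else np.ones(self.z + 1))
        for shell in ("outer", "inner"):
            e = w + self._shell_binding(shell)
            kstar = ev_to_au(e) / v
            ok = e < emax_ev
            for qq in qs:
                g = self._g_at(qq, shell, kstar, e)
                out += np.where(ok, phi[qq] * g, 0.0)
        out *= 2.0 / (np.pi * v ** 2) / self.density_au   # a.u. area per Ha
        out *= BOHR_NM ** 2 / HARTREE_EV
        return out if np.ndim(w_ev) else float(out[0])

    def ionisation_iimfp(self, t_mevu, q=None):
        """Zeroth moment restricted to ionising transfers (E > B_α), nm⁻¹.

        Integrates the SDCS over W; this is the collision density used to
        seed secondary electrons along the ion path.
        """
        t_ev = mevu_to_ev(t_mevu, self.mass_amu)
        emax = au_to_ev(4.0 * ev_to_au(t_ev) / self.mass_me)
        w = np.logspace(-2, np.log10(max(emax, 1.01e-2)), 400)
        s = self.sdcs(t_mevu, w, q)          # nm²/eV per molecule
        sigma = float(np.trapezoid(s, w))    # nm²
        return sigma * self.model.density_nm3

    # -- angular distributions ------------------------------------------------

    def _ddcs_theta1(self, t_au, e_au, theta1, q):
        """d²σ/dW dθ₁ (a.u. per molecule) at fixed energy transfer E:

            (2M²/πNT)·[Z−ρ(k)]²·ELF(k,E)·√(T(T−E))·sinθ₁ / k²

        with k(θ₁)² = 2M[2T − E − 2√(T(T−E)) cosθ₁].
        """
        root = np.sqrt(t_au * (t_au - e_au))
        k2 = 2.0 * self.mass_me * (2.0 * t_au - e_au - 2.0 * root * np.cos(theta1))
        k = np.sqrt(np.maximum(k2, 1e-30))
        elf = self.model.elf(k, au_to_ev(e_au))
        w2 = bk_form_factor(q, k, self.z) ** 2
        return (2.0 * self.mass_me ** 2 / (np.pi * self.density_au * t_au)
                * w2 * elf * root * np.sin(theta1) / np.maximum(k2, 1e-30))

    def theta1_max(self, t_mevu, w_ev, q, shell="outer"):
        """Locate the maximum of the DDCS in the ion scattering angle θ₁.

        The maximum sits at μrad scales (Bethe-ridge angle), so the search
        scans log-spaced θ₁ and refines locally.
        """
        t = ev_to_au(mevu_to_ev(t_mevu, self.mass_amu))
        e = ev_to_au(w_ev + self._shell_binding(shell))
        if e >= t:
            return np.nan
        th = np.logspace(-9, np.log10(np.pi / 2), 400)
        val = self._ddcs_theta1(t, e, th, q)
        i = int(np.argmax(val))
        lo, hi = th[max(i - 1, 0)], th[min(i + 1, th.size - 1)]
        fine = np.logspace(np.log10(lo), np.log10(hi), 200)
        val = self._ddcs_theta1(t, e, fine, q)
        return float(fine[np.argmax(val)])

    def binary_encounter_angle(self, t_mevu, w_ev):
        """θ₂ᴮᴱ = arccos √(MW/4mT); NaN if kinematically forbidden."""
        t = ev_to_au(mevu_to_ev(t_mevu, self.mass_amu))
        w = ev_to_au(np.asarray(w_ev, dtype=float))
        x = self.mass_me * w / (4.0 * t)
        return np.where(x <= 1.0, np.arccos(np.sqrt(np.minimum(x, 1.0))), np.nan)

    def ddcs(self, t_mevu, w_ev, theta2, q=None, salin=True,
             renormalise=False):
        """Ionisation DDCS d²σ/dW dΩ₂ (nm²/eV/sr per molecule).

        θ₁ = C·θ₂ with C = θ₁ᵐᵃˣ/θ₂ᴮᴱ; kinematically forbidden W gives 0.
        ``renormalise`` rescales the angular integral back to the SDCS.
        """
        th2 = np.atleast_1d(np.asarray(theta2, dtype=float))
        if np.any((th2 < 0) | (th2 > np.pi)):
            raise ValueError("emission angle must be in [0, π]")
        t = ev_to_au(mevu_to_ev(t_mevu, self.mass_amu))
        qs = range(self.z + 1) if q is None else [q]
        phi = (self.charge_fractions.fractions(t_mevu) if q is None
               else np.ones(self.z + 1))
        the_be = self.binary_encounter_angle(t_mevu, w_ev)
        if not np.isfinite(the_be):
            return np.zeros_like(th2) if np.ndim(theta2) else 0.0
        out = np.zeros_like(th2)
        for shell in ("outer", "inner"):
            b = self._shell_binding(shell)
            e = ev_to_au(w_ev + b)
            if e >= t:
                continue
            for qq in qs:
                if phi[qq] < 1e-6:
                    continue
                t1m = self.theta1_max(t_mevu, w_ev, qq, shell)
                if not np.isfinite(t1m):
                    continue
                c = t1m / the_be
                th1 = np.clip(c * th2, 0.0, np.pi)
                val = self._ddcs_theta1(t, e, th1, qq)
                with np.errstate(divide="ignore", invalid="ignore"):
                    dd = c * val / (2.0 * np.pi * np.sin(th2))
                dd = np.where(np.sin(th2) > 1e-12, dd, 0.0)
                if salin:
                    dd = dd * salin_factor(mevu_to_ev(t_mevu, self.mass_amu),
                                           w_ev, th2, self.mass_me, b)
                out += phi[qq] * dd
        out *= BOHR_NM ** 2 / HARTREE_EV
        if renormalise:
            mu = np.cos(th2)
            order = np.argsort(mu)
            integral = 2.0 * np.pi * np.trapezoid(out[order], mu[order])
            target = self.sdcs(t_mevu, w_ev, q)
            if integral > 0 and target > 0:
                out *= target / integral
        return out if np.ndim(theta2) else float(out[0])
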