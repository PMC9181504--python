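"""Physical constants and unit conversions.

Internal computations run in Hartree atomic units (ħ = m_e = e = 1);
public interfaces use eV, nm and Gy.  Liquid water at 1 g/cm³ is the
default target medium.
"""

import numpy as np

HARTREE_EV = 27.211386245988      # 1 Ha in eV
RYDBERG_EV = HARTREE_EV / 2.0
BOHR_NM = 0.052917721067          # 1 a0 in nm
BOHR_CM = BOHR_NM * 1e-7
C_AU = 137.035999084              # speed of light, a.u.
AMU_ME = 1822.888486209           # atomic mass unit in electron masses
EV_J = 1.602176634e-19

# Liquid water, 1 g/cm³
WATER_DENSITY_NM3 = 33.43         # molecules per nm³
WATER_DENSITY_AU = WATER_DENSITY_NM3 * BOHR_NM**3   # molecules per a0³
WATER_EXC_THRESHOLD_EV = 7.0      # electronic excitation threshold
WATER_MEAN_BINDING_EV = 13.7      # outer-shell mean binding (ion collisions)
WATER_K_SHELL_EV = 540.0          # oxygen K-shell binding
WATER_Z_PER_MOLECULE = 10         # electrons per H2O

# Water molecule geometry (equilibrium bond lengths)
R_OH_NM = 0.09572
R_HH_NM = 0.1514

# Carbon projectile
CARBON_Z = 6
CARBON_A = 12.0
CARBON_MASS_ME = CARBON_A * AMU_ME


def ev_to_au(e):
    return np.asarray(e, dtype=float) / HARTREE_EV


def au_to_ev(e):
    return np.asarray(e, dtype=float) * HARTREE_EV


def nm_to_au(x):
    return np.asarray(x, dtype=float) / BOHR_NM


def au_to_nm(x):
    return np.asarray(x, dtype=float) * BOHR_NM


def mevu_to_ev(t_mevu, mass_amu=CARBON_A):
    """Total kinetic energy in eV for a projectile given MeV per nucleon."""
    return np.asarray(t_mevu, dtype=float) * 1e6 * mass_amu


def ev_to_mevu(t_ev, mass_amu=CARBON_A):
    return np.asarray(t_ev, dtype=float) / (1e6 * mass_amu)


def ion_speed_au(t_ev, mass_me=CARBON_MASS_ME):
    """Nonrelativistic speed (a.u.) of an ion with total kinetic energy t_ev."""
    t = ev_to_au(t_ev)
    return np.sqrt(2.0 * t / mass_me)
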