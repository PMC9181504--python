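"""Numba event-by-event transport kernel.

Everything hot-path lives here: ion collision-site generation, secondary
electron cascades through the six channels (elastic, ionisation, excitation,
phonon, trapping, DEA), on-the-fly scoring (radial-dose histogram and
per-history cylinder counts) and optional event recording.

Event kinds follow cartrax.events; counts columns are
(ionisation, excitation, dissociative excitation, DEA, ion-impact ionisation).
Per-path reproducibility: the legacy numpy RNG is reseeded from the path's
own sub-seed at the start of each history.
"""

import numpy as np
from numba import njit

# mechanism columns in the counts array
MECH_IONIS, MECH_EXCIT, MECH_DISSOC, MECH_DEA, MECH_ION_SITE = 0, 1, 2, 3, 4


@njit(cache=False, inline="always")
def _interp_log(egrid_log0, egrid_dlog, n, table, w):
    """Linear interpolation on the log-uniform transport energy grid."""
    x = (np.log(w) - egrid_log0) / egrid_dlog
    if x <= 0.0:
        return table[0]
    if x >= n - 1:
        return table[n - 1]
    i = int(x)
    f = x - i
    return (1.0 - f) * table[i] + f * table[i + 1]


@njit(cache=False, inline="always")
def _grid_index(egrid_log0, egrid_dlog, n, w):
    x = (np.log(w) - egrid_log0) / egrid_dlog
    if x <= 0.0:
        return 0
    if x >= n - 1:
        return n - 1
    return int(x + 0.5)


@njit(cache=False, inline="always")
def _sample_row_cdf(xgrid, cdf_row):
    """Inverse-CDF draw from a tabulated row; linear between nodes."""
    u = np.random.random()
    j = np.searchsorted(cdf_row, u)
    if j <= 0:
        return xgrid[0]
    if j >= cdf_row.size:
        return xgrid[cdf_row.size - 1]
    c0 = cdf_row[j - 1]
    c1 = cdf_row[j]
    f = 0.0 if c1 <= c0 else (u - c0) / (c1 - c0)
    return xgrid[j - 1] + f * (xgrid[j] - xgrid[j - 1])


@njit(cache=False, inline="always")
def _sample_inverse(inv_rows, row):
    """Draw from a tabulated inverse CDF (equiprobable nodes, lerped)."""
    n = inv_rows.shape[1]
    p = np.random.random() * (n - 1)
    j = int(p)
    if j >= n - 1:
        return inv_rows[row, n - 1]
    f = p - j
    return inv_rows[row, j] + f * (inv_rows[row, j + 1] - inv_rows[row, j])


@njit(cache=False, inline="always")
def _rotate(ux, uy, uz, ct, phi):
    """Rotate unit vector by polar angle (cos ct) about itself."""
    st = np.sqrt(max(1.0 - ct * ct, 0.0))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.999999:
        sign = 1.0 if uz > 0.0 else -1.0
        return st * cp, sign * st * sp, sign * ct
    den = np.sqrt(1.0 - uz * uz)
    vx = ux * ct + st * (ux * uz * cp - uy * sp) / den
    vy = uy * ct + st * (uy * uz * cp + ux * sp) / den
    vz = uz * ct - den * st * cp
    norm = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


@njit(cache=False, inline="always")
def _score(x, y, z, kind, flag, edep, wt, hist,
           dr, n_r, zmid, cyl_r2, cyl_hh, cyl_x,
           dose, counts, deposited,
           record, ev_pos, ev_kind, ev_edep, ev_w, ev_hist, ev_flag, ev_count):
    if edep > 0.0:
        deposited[hist] += edep * wt
        if kind != 6:  # ion-site deposits excluded from the radial dose
            r = np.sqrt(x * x + y * y)
            ib = int(r / dr)
            if ib < n_r:
                dose[ib] += edep * wt
            else:
                dose[n_r] += edep * wt
    # cylinder counts for damaging mechanisms
    if kind == 1 or kind == 2 or kind == 5 or kind == 6:
        dz = z - zmid
        rho2 = y * y + dz * dz
        if rho2 <= cyl_r2:
            for c in range(cyl_x.size):
                if abs(x - cyl_x[c]) <= cyl_hh:
                    if kind == 1:
                        counts[hist, c, MECH_IONIS] += wt
                    elif kind == 2:
                        counts[hist, c, MECH_EXCIT] += wt
                        if flag == 1:
                            counts[hist, c, MECH_DISSOC] += wt
                    elif kind == 5:
                        counts[hist, c, MECH_DEA] += wt
                    else:
                        counts[hist, c, MECH_ION_SITE] += wt
    if record and ev_count[0] < ev_kind.size:
        i = ev_count[0]
        ev_pos[i, 0] = x
        ev_pos[i, 1] = y
        ev_pos[i, 2] = z
        ev_kind[i] = kind
        ev_edep[i] = edep
        ev_w[i] = wt
        ev_hist[i] = hist
        ev_flag[i] = flag
        ev_count[0] += 1


@njit(cache=False, fastmath=True)
def run_paths(path_seeds,
              lam_site, path_len, multiplier, b_outer_ion, gun_w,
              ion_w_grid, ion_w_cdf, ion_thw_grid, ion_thmu_grid, ion_th_cdf,
              egrid_log0, egrid_dlog,
              imfp_el, imfp_ion, imfp_exc, imfp_ph, imfp_trap, imfp_dea,
              b_of_t, wmax_rows,
              el_log0, el_dlog, el_n, el_inv,
              ion_inv, exc_inv, ewin_lo, ewin_hi,
              w_ph, cutoff, dissoc_frac,
              dr, n_r, zmid, cyl_r, cyl_hh, cyl_x,
              dose, counts, budget, deposited,
              record, ev_pos, ev_kind, ev_edep, ev_w, ev_hist, ev_flag,
              ev_count, max_steps, stack, diag):
    """Transport all ion paths; outputs accumulated in place.

    diag: [0] primaries, [1] secondaries, [2] total electron events,
          [3] step-limit kills, [4] ion collisions.
    """
    n_e = imfp_el.size
    cyl_r2 = cyl_r * cyl_r

    for hist in range(path_seeds.size):
        np.random.seed(path_seeds[hist])
        z_site = 0.0
        done_gun = False
        while True:
            if gun_w > 0.0:
                # electron-gun mode: one source point per history at z_mid,
                # monoenergetic isotropic electrons, no ion collision record
                if done_gun:
                    break
                z_site = zmid
                done_gun = True
            else:
                z_site += -np.log(1.0 - np.random.random()) / lam_site
                if z_site > path_len:
                    break
                diag[4] += 1.0
            wt = 1.0 / multiplier
            for _ in range(multiplier):
                if gun_w > 0.0:
                    w0 = gun_w
                    ct = 2.0 * np.random.random() - 1.0
                    phi = 2.0 * np.pi * np.random.random()
                    st = np.sqrt(max(1.0 - ct * ct, 0.0))
                    budget[hist] += wt * w0
                else:
                    w0 = _sample_row_cdf(ion_w_grid, ion_w_cdf)
                    # emission angle from the DDCS row nearest in W
                    jw = np.searchsorted(ion_thw_grid, w0)
                    if jw >= ion_th_cdf.shape[0]:
                        jw = ion_th_cdf.shape[0] - 1
                    ct = _sample_row_cdf(ion_thmu_grid, ion_th_cdf[jw])
                    phi = 2.0 * np.pi * np.random.random()
                    st = np.sqrt(max(1.0 - ct * ct, 0.0))
                    budget[hist] += wt * (w0 + b_outer_ion)
                    _score(0.0, 0.0, z_site, 6, 0, b_outer_ion, wt, hist,
                           dr, n_r, zmid, cyl_r2, cyl_hh, cyl_x,
                           dose, counts, deposited,
                           record, ev_pos, ev_kind, ev_edep, ev_w, ev_hist,
                           ev_flag, ev_count)
                # push the secondary electron
                ns = 0
                stack[ns, 0] = 0.0
                stack[ns, 1] = 0.0
                stack[ns, 2] = z_site
                stack[ns, 3] = st * np.cos(phi)
                stack[ns, 4] = st * np.sin(phi)
                stack[ns, 5] = ct
                stack[ns, 6] = w0
                stack[ns, 7] = wt
                ns += 1
                diag[0] += 1.0
                while ns > 0:
                    ns -= 1
                    x = stack[ns, 0]
                    y = stack[ns, 1]
                    z = stack[ns, 2]
                    ux = stack[ns, 3]
                    uy = stack[ns, 4]
                    uz = stack[ns, 5]
                    w = stack[ns, 6]
                    wgt = stack[ns, 7]
                    steps = 0
                    wcache = -1.0
                    l_el = l_io = l_ex = l_ph = l_tr = l_de = l_tot = 0.0
                    ig = 0
                    ie = 0
                    while True:
                        steps += 1
                        if steps > max_steps:
                            diag[3] += 1.0
                            _score(x, y, z, 7, 0, w, wgt, hist, dr, n_r, zmid,
                                   cyl_r2, cyl_hh, cyl_x, dose, counts,
                                   deposited, record, ev_pos, ev_kind,
                                   ev_edep, ev_w, ev_hist, ev_flag, ev_count)
                            break
                        if w < cutoff:
                            if w > 0.0:
                                _score(x, y, z, 7, 0, w, wgt, hist, dr, n_r,
                                       zmid, cyl_r2, cyl_hh, cyl_x, dose,
                                       counts, deposited, record, ev_pos,
                                       ev_kind, ev_edep, ev_w, ev_hist,
                                       ev_flag, ev_count)
                            break
                        if w != wcache:
                            # rates change only when the energy changes;
                            # elastic-dominated stretches reuse the cache
                            lw = np.log(w)
                            xg = (lw - egrid_log0) / egrid_dlog
                            if xg <= 0.0:
                                i0 = 0
                                fg = 0.0
                            elif xg >= n_e - 1:
                                i0 = n_e - 2
                                fg = 1.0
                            else:
                                i0 = int(xg)
                                fg = xg - i0
                            i1 = i0 + 1
                            l_el = (1.0 - fg) * imfp_el[i0] + fg * imfp_el[i1]
                            l_io = (1.0 - fg) * imfp_ion[i0] + fg * imfp_ion[i1]
                            l_ex = (1.0 - fg) * imfp_exc[i0] + fg * imfp_exc[i1]
                            l_ph = (1.0 - fg) * imfp_ph[i0] + fg * imfp_ph[i1]
                            l_tr = (1.0 - fg) * imfp_trap[i0] + fg * imfp_trap[i1]
                            l_de = (1.0 - fg) * imfp_dea[i0] + fg * imfp_dea[i1]
                            l_tot = l_el + l_io + l_ex + l_ph + l_tr + l_de
                            ig = i1 if fg > 0.5 else i0
                            ie = int((lw - el_log0) / el_dlog + 0.5)
                            if ie < 0:
                                ie = 0
                            if ie >= el_n:
                                ie = el_n - 1
                            wcache = w
                        if l_tot <= 0.0:
                            _score(x, y, z, 7, 0, w, wgt, hist, dr, n_r, zmid,
                                   cyl_r2, cyl_hh, cyl_x, dose, counts,
                                   deposited, record, ev_pos, ev_kind,
                                   ev_edep, ev_w, ev_hist, ev_flag, ev_count)
                            break
                        s = -np.log(1.0 - np.random.random()) / l_tot
                        x += s * ux
                        y += s * uy
                        z += s * uz
                        diag[2] += 1.0
                        u = np.random.random() * l_tot
                        if u < l_el:
                            # elastic deflection from the inverse-CDF table
                            ct = _sample_inverse(el_inv, ie)
                            phi2 = 2.0 * np.pi * np.random.random()
                            ux, uy, uz = _rotate(ux, uy, uz, ct, phi2)
                            _score(x, y, z, 0, 0, 0.0, wgt, hist, dr, n_r,
                                   zmid, cyl_r2, cyl_hh, cyl_x, dose, counts,
                                   deposited, record, ev_pos, ev_kind,
                                   ev_edep, ev_w, ev_hist, ev_flag, ev_count)
                        elif u < l_el + l_io:
                            wm = wmax_rows[ig]
                            if wm <= 0.0:
                                continue
                            b = b_of_t[ig]
                            wsec = _sample_inverse(ion_inv, ig) * wm
                            etr = wsec + b
                            if etr > w:
                                etr = w
                                wsec = max(w - b, 0.0)
                            _score(x, y, z, 1, 0, b, wgt, hist, dr, n_r, zmid,
                                   cyl_r2, cyl_hh, cyl_x, dose, counts,
                                   deposited, record, ev_pos, ev_kind,
                                   ev_edep, ev_w, ev_hist, ev_flag, ev_count)
                            # binary-kinematics deflections
                            ct1 = np.sqrt(max(1.0 - etr / w, 0.0))
                            ct2 = np.sqrt(min(etr / w, 1.0))
                            phi2 = 2.0 * np.pi * np.random.random()
                            if ns < stack.shape[0]:
                                sx, sy, sz = _rotate(ux, uy, uz, ct2,
                                                     phi2 + np.pi)
                                stack[ns, 0] = x
                                stack[ns, 1] = y
                                stack[ns, 2] = z
                                stack[ns, 3] = sx
                                stack[ns, 4] = sy
                                stack[ns, 5] = sz
                                stack[ns, 6] = wsec
                                stack[ns, 7] = wgt
                                ns += 1
                                diag[1] += 1.0
                            else:
                                # stack exhausted: deposit locally so the
                                # per-history energy ledger stays closed
                                diag[3] += 1.0
                                _score(x, y, z, 7, 0, wsec, wgt, hist, dr,
                                       n_r, zmid, cyl_r2, cyl_hh, cyl_x,
                                       dose, counts, deposited, record,
                                       ev_pos, ev_kind, ev_edep, ev_w,
                                       ev_hist, ev_flag, ev_count)
                            ux, uy, uz = _rotate(ux, uy, uz, ct1, phi2)
                            w -= etr
                        elif u < l_el + l_io + l_ex:
                            lo = ewin_lo[ig]
                            hi = ewin_hi[ig]
                            if hi <= lo:
                                continue
                            eloss = lo + _sample_inverse(exc_inv, ig) * (hi - lo)
                            if eloss > w:
                                eloss = w
                            fl = 1 if np.random.random() < dissoc_frac else 0
                            _score(x, y, z, 2, fl, eloss, wgt, hist, dr, n_r,
                                   zmid, cyl_r2, cyl_hh, cyl_x, dose, counts,
                                   deposited, record, ev_pos, ev_kind,
                                   ev_edep, ev_w, ev_hist, ev_flag, ev_count)
                            w -= eloss
                        elif u < l_el + l_io + l_ex + l_ph:
                            ep = w_ph if w_ph < w else w
                            _score(x, y, z, 3, 0, ep, wgt, hist, dr, n_r,
                                   zmid, cyl_r2, cyl_hh, cyl_x, dose, counts,
                                   deposited, record, ev_pos, ev_kind,
                                   ev_edep, ev_w, ev_hist, ev_flag, ev_count)
                            w -= ep
                        elif u < l_el + l_io + l_ex + l_ph + l_tr:
                            _score(x, y, z, 4, 0, w, wgt, hist, dr, n_r, zmid,
                                   cyl_r2, cyl_hh, cyl_x, dose, counts,
                                   deposited, record, ev_pos, ev_kind,
                                   ev_edep, ev_w, ev_hist, ev_flag, ev_count)
                            break
                        else:
                            _score(x, y, z, 5, 0, w, wgt, hist, dr, n_r, zmid,
                                   cyl_r2, cyl_hh, cyl_x, dose, counts,
                                   deposited, record, ev_pos, ev_kind,
                                   ev_edep, ev_w, ev_hist, ev_flag, ev_count)
                            break
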