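"""Numba kernels: force evaluation, BAOAB Langevin integration, metadynamics.

These are internal; the public surfaces live in :mod:`metadhs.energetics`
and :mod:`metadhs.metad`.  All kernels take flat parameter arrays prepared
by :class:`metadhs.energetics.EnergyModel` and are deterministic for a
given integer seed (one numpy legacy RNG stream per kernel invocation).

Status codes returned by the integrators:
0 = completed / CV dropped below the floor, 1 = censored at max steps,
2 = numerical failure (non-finite coordinate or CV).
"""
import math

import numpy as np
from numba import njit

# indices into the energy-term vector
E_BOND, E_LJ, E_COUL, E_RESTR, E_GATE, E_CONF = 0, 1, 2, 3, 4, 5
N_TERMS = 6


@njit(cache=True, fastmath=True)
def _pair_forces(pos, f, terms,
                 nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye):
    ok = True
    for p in range(nb_i.shape[0]):
        i, j = nb_i[p], nb_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = math.sqrt(r2)
        if r < 1e-8:
            ok = False
            continue
        # Lennard-Jones 12-6
        eps = nb_eps[p]
        if eps > 0.0:
            sr2 = (nb_sig[p] * nb_sig[p]) / r2
            sr6 = sr2 * sr2 * sr2
            terms[E_LJ] += 4.0 * eps * (sr6 * sr6 - sr6)
            fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2  # = -dE/dr / r
            f[i, 0] += fmag * dx
            f[i, 1] += fmag * dy
            f[i, 2] += fmag * dz
            f[j, 0] -= fmag * dx
            f[j, 1] -= fmag * dy
            f[j, 2] -= fmag * dz
        # Debye-screened Coulomb
        qq = nb_qq[p]
        if qq != 0.0:
            sc = math.exp(-r / debye)
            e = qq * sc / r
            terms[E_COUL] += e
            fmag = e * (1.0 / r + 1.0 / debye) / r  # = -dE/dr / r
            f[i, 0] += fmag * dx
            f[i, 1] += fmag * dy
            f[i, 2] += fmag * dz
            f[j, 0] -= fmag * dx
            f[j, 1] -= fmag * dy
            f[j, 2] -= fmag * dz
    return ok


@njit(cache=True, fastmath=True)
def _forces(pos, f,
            nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye,
            b_i, b_j, b_k, b_r0,
            restraint_k, native_pos, extra_k, extra_mask,
            lig_ids, lig_mfrac,
            ridge_z, ridge_h, ridge_w,
            sphere_r, sphere_k,
            cyl_r, cyl_k, cyl_z, cyl_s):
    """Fill forces in place; return (terms, ok)."""
    n = pos.shape[0]
    terms = np.zeros(N_TERMS)
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    ok = _pair_forces(pos, f, terms, nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye)
    # harmonic bonds
    for p in range(b_i.shape[0]):
        i, j = b_i[p], b_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-8:
            ok = False
            continue
        dr = r - b_r0[p]
        terms[E_BOND] += 0.5 * b_k[p] * dr * dr
        fmag = -b_k[p] * dr / r
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz
    # positional restraints (+ equilibration-ladder extra restraints)
    for i in range(n):
        k = restraint_k[i]
        if extra_mask[i]:
            k += extra_k
        if k > 0.0:
            dx = pos[i, 0] - native_pos[i, 0]
            dy = pos[i, 1] - native_pos[i, 1]
            dz = pos[i, 2] - native_pos[i, 2]
            terms[E_RESTR] += 0.5 * k * (dx * dx + dy * dy + dz * dz)
            f[i, 0] -= k * dx
            f[i, 1] -= k * dy
            f[i, 2] -= k * dz
    # gate ridges on the ligand COM z coordinate
    zc = 0.0
    for a in range(lig_ids.shape[0]):
        zc += lig_mfrac[a] * pos[lig_ids[a], 2]
    dEdz = 0.0
    for c in range(ridge_z.shape[0]):
        dz = zc - ridge_z[c]
        e = ridge_h[c] * math.exp(-dz * dz / (2.0 * ridge_w * ridge_w))
        terms[E_GATE] += e
        dEdz += -e * dz / (ridge_w * ridge_w)
    for a in range(lig_ids.shape[0]):
        f[lig_ids[a], 2] -= dEdz * lig_mfrac[a]
    # confinement: reflective sphere (all beads)
    for i in range(n):
        rr = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        if rr > sphere_r:
            exc = rr - sphere_r
            terms[E_CONF] += 0.5 * sphere_k * exc * exc
            fmag = -sphere_k * exc / rr
            f[i, 0] += fmag * pos[i, 0]
            f[i, 1] += fmag * pos[i, 1]
            f[i, 2] += fmag * pos[i, 2]
    # confinement: soft tunnel wall (ligand beads, smoothly off past the mouths)
    if cyl_k > 0.0:
        for a in range(lig_ids.shape[0]):
            i = lig_ids[a]
            x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
            rho = math.sqrt(x * x + y * y)
            exc = rho - cyl_r
            if exc > 0.0 and rho > 1e-10:
                w = 1.0 / (1.0 + math.exp((abs(z) - cyl_z) / cyl_s))
                terms[E_CONF] += 0.5 * cyl_k * exc * exc * w
                fmag = -cyl_k * exc * w / rho
                f[i, 0] += fmag * x
                f[i, 1] += fmag * y
                sgn = 1.0 if z >= 0.0 else -1.0
                dwdz = -w * (1.0 - w) * sgn / cyl_s
                f[i, 2] -= 0.5 * cyl_k * exc * exc * dwdz
    return terms, ok



@njit(cache=True, fastmath=True, inline="always")
def _ipow(x, e):
    out = 1.0
    for _ in range(e):
        out *= x
    return out


@njit(cache=True, fastmath=True)
def cv_and_grad(pos, cv_i, cv_j, r0, d0, n_exp, m_exp, grad):
    """Contacts CV and its gradient (gradient array filled in place)."""
    total = 0.0
    for i in range(grad.shape[0]):
        grad[i, 0] = 0.0
        grad[i, 1] = 0.0
        grad[i, 2] = 0.0
    for p in range(cv_i.shape[0]):
        i, j = cv_i[p], cv_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        x = (r - d0) / r0
        if x <= 0.0:
            total += 1.0
            continue
        if abs(x - 1.0) < 1e-6:
            s = n_exp / m_exp
            dsdx = n_exp * (n_exp - m_exp) / (2.0 * m_exp)
        else:
            xn1 = _ipow(x, n_exp - 1)
            xn = xn1 * x
            xm1 = _ipow(x, m_exp - 1)
            xm = xm1 * x
            s = (1.0 - xn) / (1.0 - xm)
            dsdx = (-n_exp * xn1 * (1.0 - xm)
                    + m_exp * xm1 * (1.0 - xn)) / ((1.0 - xm) ** 2)
        total += s
        c = dsdx / (r0 * max(r, 1e-12))
        grad[i, 0] += c * dx
        grad[i, 1] += c * dy
        grad[i, 2] += c * dz
        grad[j, 0] -= c * dx
        grad[j, 1] -= c * dy
        grad[j, 2] -= c * dz
    return total


@njit(cache=True, fastmath=True)
def cv_value_only(pos, cv_i, cv_j, r0, d0, n_exp, m_exp):
    total = 0.0
    for p in range(cv_i.shape[0]):
        i, j = cv_i[p], cv_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        x = (r - d0) / r0
        if x <= 0.0:
            total += 1.0
        elif abs(x - 1.0) < 1e-6:
            total += n_exp / m_exp
        else:
            xn = _ipow(x, n_exp)
            xm = _ipow(x, m_exp)
            total += (1.0 - xn) / (1.0 - xm)
    return total


@njit(cache=True, fastmath=True)
def bias_derivative(cv, hill_c, hill_h, n_hills, sigma):
    """dV_bias/dCV and V_bias at the current CV value."""
    v = 0.0
    dv = 0.0
    s2 = sigma * sigma
    for h in range(n_hills):
        d = cv - hill_c[h]
        e = hill_h[h] * math.exp(-d * d / (2.0 * s2))
        v += e
        dv += -e * d / s2
    return v, dv


@njit(cache=True, fastmath=True)
def _group_min_dist(pos, ids_a, ids_b):
    best = 1e30
    for a in range(ids_a.shape[0]):
        i = ids_a[a]
        for b in range(ids_b.shape[0]):
            j = ids_b[b]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < best:
                best = d
    return best


@njit(cache=True, fastmath=True)
def run_langevin(pos, vel, masses, dt, friction, kT, nsteps, seed,
                 record_stride, frames,
                 nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye,
                 b_i, b_j, b_k, b_r0,
                 restraint_k, native_pos, extra_k, extra_mask,
                 lig_ids, lig_mfrac,
                 ridge_z, ridge_h, ridge_w,
                 sphere_r, sphere_k,
                 cyl_r, cyl_k, cyl_z, cyl_s):
    """BAOAB Langevin integration; thinned frames recorded in place."""
    np.random.seed(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    terms, ok = _forces(pos, f,
                        nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye,
                        b_i, b_j, b_k, b_r0,
                        restraint_k, native_pos, extra_k, extra_mask,
                        lig_ids, lig_mfrac, ridge_z, ridge_h, ridge_w,
                        sphere_r, sphere_k, cyl_r, cyl_k, cyl_z, cyl_s)
    if not ok:
        return 2
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    frame = 0
    if frames.shape[0] > 0:
        frames[0] = pos
        frame = 1
    for step in range(1, nsteps + 1):
        for i in range(n):
            inv_m = dt * 0.5 / masses[i]
            for d in range(3):
                vel[i, d] += inv_m * f[i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
        noise = np.random.standard_normal(3 * n)
        for i in range(n):
            sd = c2 * math.sqrt(kT / masses[i])
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + sd * noise[3 * i + d]
        for i in range(n):
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
        terms, ok = _forces(pos, f,
                            nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye,
                            b_i, b_j, b_k, b_r0,
                            restraint_k, native_pos, extra_k, extra_mask,
                            lig_ids, lig_mfrac, ridge_z, ridge_h, ridge_w,
                            sphere_r, sphere_k, cyl_r, cyl_k, cyl_z, cyl_s)
        if not ok or not math.isfinite(pos[0, 0]):
            return 2
        for i in range(n):
            inv_m = dt * 0.5 / masses[i]
            for d in range(3):
                vel[i, d] += inv_m * f[i, d]
        if record_stride > 0 and step % record_stride == 0 and frame < frames.shape[0]:
            frames[frame] = pos
            frame += 1
    return 0


@njit(cache=True, fastmath=True)
def run_metad(pos, vel, masses, dt, friction, kT, nsteps, seed,
              pace_steps, hill_height, hill_sigma, floor_cv,
              cv_i, cv_j, sw_r0, sw_d0, sw_n, sw_m,
              hill_c, hill_h, hill_t,
              trace_t, trace_cv, trace_bias, trace_com,
              trace_dga, trace_dgb, trace_salt,
              gateA_ids, gateB_ids, gateA_anion_ids, amine_arr,
              nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye,
              b_i, b_j, b_k, b_r0,
              restraint_k, native_pos, extra_k, extra_mask,
              lig_ids, lig_mfrac,
              ridge_z, ridge_h, ridge_w,
              sphere_r, sphere_k,
              cyl_r, cyl_k, cyl_z, cyl_s):
    """Metadynamics on the contacts CV: BAOAB + Gaussian hill deposition.

    Records one trace row per deposition pace (plus the initial frame) and
    stops once the CV falls below ``floor_cv``.  Returns
    (status, n_frames, n_hills).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    grad = np.zeros((n, 3))
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    n_hills = 0

    terms, ok = _forces(pos, f,
                        nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye,
                        b_i, b_j, b_k, b_r0,
                        restraint_k, native_pos, extra_k, extra_mask,
                        lig_ids, lig_mfrac, ridge_z, ridge_h, ridge_w,
                        sphere_r, sphere_k, cyl_r, cyl_k, cyl_z, cyl_s)
    if not ok:
        return 2, 0, 0
    cv = cv_and_grad(pos, cv_i, cv_j, sw_r0, sw_d0, sw_n, sw_m, grad)
    vbias, dvdcv = bias_derivative(cv, hill_c, hill_h, n_hills, hill_sigma)
    for i in range(n):
        for d in range(3):
            f[i, d] -= dvdcv * grad[i, d]

    # frame 0: the initial state
    frame = 0
    trace_t[frame] = 0.0
    trace_cv[frame] = cv
    trace_bias[frame] = vbias
    for d in range(3):
        com = 0.0
        for a in range(lig_ids.shape[0]):
            com += lig_mfrac[a] * pos[lig_ids[a], d]
        trace_com[frame, d] = com
    trace_dga[frame] = _group_min_dist(pos, lig_ids, gateA_ids)
    trace_dgb[frame] = _group_min_dist(pos, lig_ids, gateB_ids)
    trace_salt[frame] = _group_min_dist(pos, amine_arr, gateA_anion_ids)
    frame = 1

    status = 1  # censored unless the CV reaches the floor
    for step in range(1, nsteps + 1):
        for i in range(n):
            inv_m = dt * 0.5 / masses[i]
            for d in range(3):
                vel[i, d] += inv_m * f[i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
        noise = np.random.standard_normal(3 * n)
        for i in range(n):
            sd = c2 * math.sqrt(kT / masses[i])
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + sd * noise[3 * i + d]
        for i in range(n):
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
        terms, ok = _forces(pos, f,
                            nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye,
                            b_i, b_j, b_k, b_r0,
                            restraint_k, native_pos, extra_k, extra_mask,
                            lig_ids, lig_mfrac, ridge_z, ridge_h, ridge_w,
                            sphere_r, sphere_k, cyl_r, cyl_k, cyl_z, cyl_s)
        cv = cv_and_grad(pos, cv_i, cv_j, sw_r0, sw_d0, sw_n, sw_m, grad)
        if not ok or not math.isfinite(cv):
            return 2, frame, n_hills
        vbias, dvdcv = bias_derivative(cv, hill_c, hill_h, n_hills, hill_sigma)
        for i in range(n):
            for d in range(3):
                f[i, d] -= dvdcv * grad[i, d]
        for i in range(n):
            inv_m = dt * 0.5 / masses[i]
            for d in range(3):
                vel[i, d] += inv_m * f[i, d]
        if step % pace_steps == 0:
            t = step * dt
            if frame < trace_t.shape[0]:
                trace_t[frame] = t
                trace_cv[frame] = cv
                trace_bias[frame] = vbias
                for d in range(3):
                    com = 0.0
                    for a in range(lig_ids.shape[0]):
                        com += lig_mfrac[a] * pos[lig_ids[a], d]
                    trace_com[frame, d] = com
                trace_dga[frame] = _group_min_dist(pos, lig_ids, gateA_ids)
                trace_dgb[frame] = _group_min_dist(pos, lig_ids, gateB_ids)
                trace_salt[frame] = _group_min_dist(pos, amine_arr, gateA_anion_ids)
                frame += 1
            if n_hills < hill_c.shape[0]:
                hill_c[n_hills] = cv
                hill_h[n_hills] = hill_height
                hill_t[n_hills] = t
                n_hills += 1
            if cv < floor_cv:
                status = 0
                break
    return status, frame, n_hills


@njit(cache=True, fastmath=True)
def minimize(pos, nsteps, tol,
             nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye,
             b_i, b_j, b_k, b_r0,
             restraint_k, native_pos, extra_k, extra_mask,
             lig_ids, lig_mfrac,
             ridge_z, ridge_h, ridge_w,
             sphere_r, sphere_k,
             cyl_r, cyl_k, cyl_z, cyl_s):
    """Steepest-descent energy minimisation with adaptive step."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    trial = np.zeros((n, 3))
    ft = np.zeros((n, 3))
    terms, ok = _forces(pos, f,
                        nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye,
                        b_i, b_j, b_k, b_r0,
                        restraint_k, native_pos, extra_k, extra_mask,
                        lig_ids, lig_mfrac, ridge_z, ridge_h, ridge_w,
                        sphere_r, sphere_k, cyl_r, cyl_k, cyl_z, cyl_s)
    e = terms.sum()
    h = 0.01
    for it in range(nsteps):
        fmax = 0.0
        for i in range(n):
            for d in range(3):
                a = abs(f[i, d])
                if a > fmax:
                    fmax = a
        if fmax < tol or h < 1e-9:
            break
        for i in range(n):
            for d in range(3):
                trial[i, d] = pos[i, d] + h * f[i, d] / fmax
        terms_t, ok = _forces(trial, ft,
                              nb_i, nb_j, nb_eps, nb_sig, nb_qq, debye,
                              b_i, b_j, b_k, b_r0,
                              restraint_k, native_pos, extra_k, extra_mask,
                              lig_ids, lig_mfrac, ridge_z, ridge_h, ridge_w,
                              sphere_r, sphere_k, cyl_r, cyl_k, cyl_z, cyl_s)
        e_t = terms_t.sum()
        if ok and e_t < e:
            for i in range(n):
                for d in range(3):
                    pos[i, d] = trial[i, d]
                    f[i, d] = ft[i, d]
            e = e_t
            h = min(h * 1.2, 0.2)
        else:
            h *= 0.5
    return e


@njit(cache=True, fastmath=True)
def dw_run(x0, dt, gamma, kT, mass, nsteps, seed,
           barrier, tilt, pace_steps, hill_height, hill_sigma,
           hill_c, hill_hh, rec_va, rec_vb, xa, xb, x_stop, use_stop):
    """1D tilted double-well Langevin/metadynamics validation stub.

    U(x) = barrier*(x^2-1)^2 + 0.5*tilt*x, the CV is x itself.  Records
    the bias potential evaluated at the two well minima at every pace.
    Returns (status, n_hills, n_records, first_passage_time or -1).
    """
    np.random.seed(seed)
    x = x0
    v = 0.0
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sd = math.sqrt(kT / mass)
    n_hills = 0
    n_rec = 0
    fpt = -1.0

    def _force(xx):
        return -(4.0 * barrier * xx * (xx * xx - 1.0) + 0.5 * tilt)

    f = _force(x)
    vb, dvb = bias_derivative(x, hill_c, hill_hh, n_hills, hill_sigma)
    f -= dvb
    for step in range(1, nsteps + 1):
        v += 0.5 * dt * f / mass
        x += 0.5 * dt * v
        v = c1 * v + c2 * sd * np.random.normal()
        x += 0.5 * dt * v
        f = _force(x)
        vb, dvb = bias_derivative(x, hill_c, hill_hh, n_hills, hill_sigma)
        f -= dvb
        v += 0.5 * dt * f / mass
        if use_stop and x > x_stop:
            fpt = step * dt
            return 0, n_hills, n_rec, fpt
        if pace_steps > 0 and step % pace_steps == 0:
            if hill_height > 0.0 and n_hills < hill_c.shape[0]:
                hill_c[n_hills] = x
                hill_hh[n_hills] = hill_height
                n_hills += 1
            if n_rec < rec_va.shape[0]:
                va, _ = bias_derivative(xa, hill_c, hill_hh, n_hills, hill_sigma)
                vbb, _ = bias_derivative(xb, hill_c, hill_hh, n_hills, hill_sigma)
                rec_va[n_rec] = va
                rec_vb[n_rec] = vbb
                n_rec += 1
    return 1, n_hills, n_rec, fpt
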