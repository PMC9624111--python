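"""Compiled inner loop: RHS evaluation, Dormand-Prince 4(5) stepping, and
in-step event localization.

Everything here operates on flat float64 arrays prepared by
:mod:`supertx.dynamics` and is jitted with numba; the Python layer applies
events and owns all stochastic bookkeeping.

State vector layout (n polymerases, G genes):
    y[0:n]        z    genomic positions, nm (ascending)
    y[n:2n]       x    nascent-RNA lengths, nm
    y[2n:3n]      phi  local excess twists, rad
    y[3n:4n]      theta polymerase rotations, rad
    y[4n:4n+G]    cumulative initiation hazards (reset to 0 per leg)

Physical-constant vector ``pc``:
    0 omega0  1 kBT  2 v0  3 tau_s  4 tau_w  5 chi  6 eta  7 n_drag
    8 c_s  9 sigma_s  10 sigma_p  11 tau0  12 p_plect  13 alpha
    14 sigma_hyper_neg  15 sigma_hyper_pos  16 nuc_lo  17 nuc_hi
    18 penalty_energy_kbt  19 log(max_enhancement)

Model codes: torque kind 0 = base Marko, 1 = nucleosome buffered;
initiation kind 0 = independent, 1 = first order, 2 = second order,
3 = second order with hyper penalty.

Leg return codes: 0 = reached the scheduled stop, 1 = initiation hazard
crossing (idx = gene), 2 = termination (idx = polymerase), 3 = footprint
clearance re-opening a promoter (idx = gene), -1 = polymerase order
inversion that persisted at the minimum step (degenerate segment).
"""

import math

import numpy as np
from numba import njit

_E_SC_TURNS = 1.2 * 2.0 * math.pi  # twist displaced by one bound polymerase


@njit(cache=True)
def torque_scalar(s, pc, tk):
    if tk == 1:
        lo = pc[16]
        hi = pc[17]
        if lo <= s <= hi:
            return 0.0
        if s > hi:
            s = s - (hi - lo)
    a = abs(s)
    if a < pc[9]:
        t = pc[1] * pc[8] * pc[0] * a
    elif a <= pc[10]:
        t = pc[11]
    else:
        t = pc[1] * pc[12] * pc[0] * a
    return t if s >= 0.0 else -t


@njit(cache=True)
def stall_factor(tau, pc):
    u = (abs(tau) - pc[3]) / pc[4]
    if u > 500.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(u))


@njit(cache=True)
def initiation_rate_scalar(sigma, base, pc, ik, tk):
    if ik == 0 or base <= 0.0:
        return base
    e = _E_SC_TURNS * torque_scalar(sigma, pc, tk)
    if ik >= 2:
        e += pc[13] * pc[11] * sigma * sigma
    if ik == 3 and (sigma < pc[14] or sigma > pc[15]):
        e = pc[18] * pc[1]
    f = -e / pc[1]
    if f > pc[19]:
        f = pc[19]
    elif f < -700.0:
        f = -700.0
    return base * math.exp(f)


@njit(cache=True)
def rhs(y, out, n, G, direction, probe, base, gate,
        circular, wall_lo, wall_hi, circ, pc, ik, tk, fp):
    """Time derivatives of the full state vector (returns min segment gap).

    ``fp`` is the steric footprint of a polymerase, nm: translocation is
    throttled linearly to zero as the gap to the neighbor ahead closes
    from 2*fp down to fp, so polymerases can neither overlap nor drive
    segment lengths to zero."""
    w0 = pc[0]
    chi = pc[5]
    eta = pc[6]
    nd = pc[7]
    min_gap = 1.0e300
    if n == 0:
        for g in range(G):
            out[g] = base[g] if gate[g] == 1 else 0.0
        return min_gap
    if circular == 1 and n == 1:
        v = pc[2]
        d = direction[0]
        out[0] = d * v
        out[1] = v
        dth = (chi * w0 * d * v) / (eta * (y[1] ** nd) + chi)
        out[3] = dth
        out[2] = w0 * d * v - dth
        for g in range(G):
            out[4 + g] = base[g] if gate[g] == 1 else 0.0
        return min_gap
    # segment densities; linear: n+1 segments, circular: n segments (+wrap)
    if circular == 1:
        nseg = n
    else:
        nseg = n + 1
    sigma = np.empty(nseg)
    for k in range(nseg):
        if circular == 1:
            if k < n - 1:
                z0 = y[k]
                z1 = y[k + 1]
                p0 = y[2 * n + k]
                p1 = y[2 * n + k + 1]
            else:
                z0 = y[n - 1]
                z1 = y[0] + circ
                p0 = y[2 * n + n - 1]
                p1 = y[2 * n]
        else:
            if k == 0:
                z0 = wall_lo
                p0 = 0.0
            else:
                z0 = y[k - 1]
                p0 = y[2 * n + k - 1]
            if k == n:
                z1 = wall_hi
                p1 = 0.0
            else:
                z1 = y[k]
                p1 = y[2 * n + k]
        seg = z1 - z0
        if seg < min_gap:
            min_gap = seg
        if seg < 1.0e-9:
            seg = 1.0e-9
        sigma[k] = (p0 - p1) / (w0 * seg)
    for i in range(n):
        if circular == 1:
            sl = sigma[(i - 1) % n]
            sr = sigma[i]
        else:
            sl = sigma[i]
            sr = sigma[i + 1]
        tl = torque_scalar(sl, pc, tk)
        tr = torque_scalar(sr, pc, tk)
        d = direction[i]
        if d > 0:
            tf = tr
            tb = tl
        else:
            tf = tl
            tb = tr
        v = pc[2] * stall_factor(tf, pc) * stall_factor(tb, pc)
        # steric exclusion against the neighbor ahead
        if d > 0:
            if i < n - 1:
                gap = y[i + 1] - y[i]
            elif circular == 1:
                gap = y[0] + circ - y[i]
            else:
                gap = wall_hi - y[i] + 2.0 * fp  # walls do not obstruct
        else:
            if i > 0:
                gap = y[i] - y[i - 1]
            elif circular == 1:
                gap = y[i] + circ - y[n - 1]
            else:
                gap = y[i] - wall_lo + 2.0 * fp
        if gap < 2.0 * fp:
            frac = (gap - fp) / fp
            if frac < 0.0:
                frac = 0.0
            v *= frac
        dz = d * v
        x = y[n + i]
        if x < 0.0:
            x = 0.0
        dth = (tr - tl + chi * w0 * dz) / (eta * (x ** nd) + chi)
        out[i] = dz
        out[n + i] = v
        out[2 * n + i] = w0 * dz - dth
        out[3 * n + i] = dth
    for g in range(G):
        if gate[g] == 1 and base[g] > 0.0:
            p = probe[g]
            if circular == 1:
                pm = wall_lo + (p - wall_lo) % circ
                k = np.searchsorted(y[:n], pm) - 1
                if k < 0:
                    k = n - 1
            else:
                k = np.searchsorted(y[:n], p)
            out[4 * n + g] = initiation_rate_scalar(sigma[k], base[g], pc, ik, tk)
        else:
            out[4 * n + g] = 0.0
    return min_gap


@njit(cache=True)
def _hermite(th, h, y0, f0, y1, f1):
    t2 = th * th
    t3 = t2 * th
    return ((2.0 * t3 - 3.0 * t2 + 1.0) * y0
            + (t3 - 2.0 * t2 + th) * h * f0
            + (-2.0 * t3 + 3.0 * t2) * y1
            + (t3 - t2) * h * f1)


@njit(cache=True)
def integrate_leg(t0, y, h0, t_stop, max_step, rtol, atol,
                  n, G, direction, tes_pol, probe, base, gate,
                  blocker, tss_g, fp,
                  rem_init,
                  circular, wall_lo, wall_hi, circ, pc, ik, tk,
                  method, fixed_dt):
    """Integrate until the scheduled stop or the first internal event.

    Mutates ``y`` to the state at the returned time.  Returns
    (code, idx, t_end, h_next, n_steps, n_rejected).
    """
    ndim = 4 * n + G
    f0 = np.empty(ndim)
    rhs(y, f0, n, G, direction, probe, base, gate,
        circular, wall_lo, wall_hi, circ, pc, ik, tk, fp)
    h = h0
    t = t0
    nsteps = 0
    nrej = 0
    y1 = np.empty(ndim)
    f1 = np.empty(ndim)
    k2 = np.empty(ndim)
    k3 = np.empty(ndim)
    k4 = np.empty(ndim)
    k5 = np.empty(ndim)
    k6 = np.empty(ndim)
    ys = np.empty(ndim)
    while True:
        h_cap = t_stop - t
        if h_cap <= 1.0e-9:
            return 0, -1, t_stop, h, nsteps, nrej
        if h > h_cap:
            h = h_cap
        if h > max_step:
            h = max_step
        if method == 1:
            # classical RK4, fixed step (reference integrator)
            for i in range(ndim):
                ys[i] = y[i] + 0.5 * h * f0[i]
            rhs(ys, k2, n, G, direction, probe, base, gate,
                circular, wall_lo, wall_hi, circ, pc, ik, tk, fp)
            for i in range(ndim):
                ys[i] = y[i] + 0.5 * h * k2[i]
            rhs(ys, k3, n, G, direction, probe, base, gate,
                circular, wall_lo, wall_hi, circ, pc, ik, tk, fp)
            for i in range(ndim):
                ys[i] = y[i] + h * k3[i]
            rhs(ys, k4, n, G, direction, probe, base, gate,
                circular, wall_lo, wall_hi, circ, pc, ik, tk, fp)
            for i in range(ndim):
                y1[i] = y[i] + (h / 6.0) * (f0[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            rhs(y1, f1, n, G, direction, probe, base, gate,
                circular, wall_lo, wall_hi, circ, pc, ik, tk, fp)
            accepted = True
            h_next = fixed_dt
            nsteps += 1
        else:
            # Dormand-Prince 4(5)
            for i in range(ndim):
                ys[i] = y[i] + h * 0.2 * f0[i]
            rhs(ys, k2, n, G, direction, probe, base, gate,
                circular, wall_lo, wall_hi, circ, pc, ik, tk, fp)
            for i in range(ndim):
                ys[i] = y[i] + h * (0.075 * f0[i] + 0.225 * k2[i])
            rhs(ys, k3, n, G, direction, probe, base, gate,
                circular, wall_lo, wall_hi, circ, pc, ik, tk, fp)
            for i in range(ndim):
                ys[i] = y[i] + h * (44.0 / 45.0 * f0[i] - 56.0 / 15.0 * k2[i]
                                    + 32.0 / 9.0 * k3[i])
            rhs(ys, k4, n, G, direction, probe, base, gate,
                circular, wall_lo, wall_hi, circ, pc, ik, tk, fp)
            for i in range(ndim):
                ys[i] = y[i] + h * (19372.0 / 6561.0 * f0[i]
                                    - 25360.0 / 2187.0 * k2[i]
                                    + 64448.0 / 6561.0 * k3[i]
                                    - 212.0 / 729.0 * k4[i])
            rhs(ys, k5, n, G, direction, probe, base, gate,
                circular, wall_lo, wall_hi, circ, pc, ik, tk, fp)
            for i in range(ndim):
                ys[i] = y[i] + h * (9017.0 / 3168.0 * f0[i]
                                    - 355.0 / 33.0 * k2[i]
                                    + 46732.0 / 5247.0 * k3[i]
                                    + 49.0 / 176.0 * k4[i]
                                    - 5103.0 / 18656.0 * k5[i])
            rhs(ys, k6, n, G, direction, probe, base, gate,
                circular, wall_lo, wall_hi, circ, pc, ik, tk, fp)
            for i in range(ndim):
                y1[i] = y[i] + h * (35.0 / 384.0 * f0[i]
                                    + 500.0 / 1113.0 * k3[i]
                                    + 125.0 / 192.0 * k4[i]
                                    - 2187.0 / 6784.0 * k5[i]
                                    + 11.0 / 84.0 * k6[i])
            min_gap = rhs(y1, f1, n, G, direction, probe, base, gate,
                          circular, wall_lo, wall_hi, circ, pc, ik, tk, fp)
            err = 0.0
            for i in range(ndim):
                ei = h * (71.0 / 57600.0 * f0[i]
                          - 71.0 / 16695.0 * k3[i]
                          + 71.0 / 1920.0 * k4[i]
                          - 17253.0 / 339200.0 * k5[i]
                          + 22.0 / 525.0 * k6[i]
                          - 1.0 / 40.0 * f1[i])
            # scale by tolerance
                a0 = abs(y[i])
                a1 = abs(y1[i])
                sc = atol + rtol * (a0 if a0 > a1 else a1)
                err += (ei / sc) ** 2
            err = math.sqrt(err / ndim)
            accepted = err <= 1.0 or h <= 1.0e-10
            # reject steps that invert polymerase order
            order_ok = True
            if accepted and n >= 2:
                for i in range(n - 1):
                    if y1[i + 1] - y1[i] <= 0.0:
                        order_ok = False
                        break
            if accepted and not order_ok:
                if h <= 1.0e-10:
                    return -1, -1, t, h, nsteps, nrej
                nrej += 1
                h *= 0.25
                continue
            if accepted:
                nsteps += 1
                fac = 5.0 if err == 0.0 else 0.9 * err ** (-0.2)
                if fac > 5.0:
                    fac = 5.0
                if fac < 0.2:
                    fac = 0.2
                h_next = h * fac
                if h_next > max_step:
                    h_next = max_step
            else:
                nrej += 1
                fac = 0.9 * err ** (-0.2)
                if fac > 1.0:
                    fac = 1.0
                if fac < 0.1:
                    fac = 0.1
                h *= fac
                continue
        # ------- event scan on the accepted step [t, t+h] -------------------
        best_th = 2.0
        best_code = 0
        best_idx = -1
        for g in range(G):
            j = 4 * n + g
            thr = rem_init[g]
            if y1[j] >= thr:
                if y[j] >= thr:
                    th = 0.0
                else:
                    lo = 0.0
                    hi = 1.0
                    flo = y[j] - thr
                    for _ in range(60):
                        mid = 0.5 * (lo + hi)
                        fm = _hermite(mid, h, y[j], f0[j], y1[j], f1[j]) - thr
                        if (flo < 0.0) == (fm < 0.0):
                            lo = mid
                            flo = fm
                        else:
                            hi = mid
                        if hi - lo < 1.0e-12:
                            break
                    th = 0.5 * (lo + hi)
                if th < best_th:
                    best_th = th
                    best_code = 1
                    best_idx = g
        for i in range(n):
            d = direction[i]
            s0 = (y[i] - tes_pol[i]) * d
            s1 = (y1[i] - tes_pol[i]) * d
            if s1 >= 0.0:
                if s0 >= 0.0:
                    th = 0.0
                else:
                    lo = 0.0
                    hi = 1.0
                    flo = s0
                    for _ in range(60):
                        mid = 0.5 * (lo + hi)
                        fm = (_hermite(mid, h, y[i], f0[i], y1[i], f1[i])
                              - tes_pol[i]) * d
                        if (flo < 0.0) == (fm < 0.0):
                            lo = mid
                            flo = fm
                        else:
                            hi = mid
                        if hi - lo < 1.0e-12:
                            break
                    th = 0.5 * (lo + hi)
                if th < best_th:
                    best_th = th
                    best_code = 2
                    best_idx = i
        for g in range(G):
            if gate[g] == 1 or blocker[g] < 0:
                continue
            b = blocker[g]
            s0 = abs(y[b] - tss_g[g]) - fp
            s1 = abs(y1[b] - tss_g[g]) - fp
            if s1 >= 0.0 > s0:
                lo = 0.0
                hi = 1.0
                flo = s0
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    fm = abs(_hermite(mid, h, y[b], f0[b], y1[b], f1[b])
                             - tss_g[g]) - fp
                    if (flo < 0.0) == (fm < 0.0):
                        lo = mid
                        flo = fm
                    else:
                        hi = mid
                    if hi - lo < 1.0e-12:
                        break
                th = 0.5 * (lo + hi)
                if th < best_th:
                    best_th = th
                    best_code = 3
                    best_idx = g
        if best_code != 0:
            te = t + best_th * h
            for i in range(ndim):
                y[i] = _hermite(best_th, h, y[i], f0[i], y1[i], f1[i])
            return best_code, best_idx, te, h_next, nsteps, nrej
        t = t + h
        for i in range(ndim):
            y[i] = y1[i]
            f0[i] = f1[i]
        h = h_next
        if t >= t_stop - 1.0e-9:
            return 0, -1, t, h, nsteps, nrej
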