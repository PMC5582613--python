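"""Compiled numerical kernels for the MeIQx metabolism ODE.

Everything here works on a flat 24-element parameter vector (molar / hour
units) so it can be jitted and called millions of times from the multistart
optimiser:

====  =========================  ====
idx   parameter                  unit
====  =========================  ====
0-3   k1..k4                     1/h
4-7   km1..km4                   M
8-10  vm_so3h, vm_oxo, vm_pgc    M/h
11-13 km_so3h, km_oxo, km_pgc    M
14    e_cyp1a2_total             M
15    e_ugt_total                M
16-19 a1, b1, theta1, n1         CYP1A2 partition sigmoid
20-23 a2, b2, theta2, n2         UGT partition sigmoid
====  =========================  ====

The saturation hypothesis is encoded as a degenerate sigmoid (a=0, b=const).

State ordering: MeIQx, C-Hydroxy-MeIQx, MeIQx-N2-Gl, MeIQx-N2-SO3H,
oxo-MeIQx, HONH-MeIQx, HON-MeIQx-N2-Gl, Potential-Genotoxic-Compound.

The fixed-grid integrator is TR-BDF2 (one trapezoidal stage followed by a
variable-coefficient BDF2 stage, gamma = 2 - sqrt(2)); it is L-stable, which
matters because the multistart search space includes strongly stiff corners
(Vmax/Km ratios up to 1e7 per hour).  The Jacobian of the system is sparse:
every flux depends only on [MeIQx] and [HONH-MeIQx], so each Newton solve
reduces to a 2x2 system plus back-substitution.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_SPECIES = 8
N_PARAMS = 24

_GAMMA = 2.0 - np.sqrt(2.0)


@njit(cache=True, fastmath=False)
def phi_kernel(a, b, theta, n, s):
    """Decreasing Hill-type sigmoid a*theta^n/(theta^n + s^n) + b."""
    if s <= 0.0:
        return a + b
    # compute in log space to dodge overflow for extreme s/theta ratios
    r = n * (np.log(s) - np.log(theta))
    if r > 500.0:
        return b
    if r < -500.0:
        return a + b
    return a / (1.0 + np.exp(r)) + b


@njit(cache=True, fastmath=False)
def dphi_ds_kernel(a, b, theta, n, s):
    if s <= 0.0 or a == 0.0:
        return 0.0
    r = n * (np.log(s) - np.log(theta))
    if r > 500.0 or r < -500.0:
        return 0.0
    e = np.exp(r)
    return -a * n * e / (s * (1.0 + e) ** 2)


@njit(cache=True, fastmath=False)
def rhs_kernel(x, p, dx):
    """Time derivative of the 8 species; negative states are clipped to zero
    for the Michaelis-Menten evaluation only."""
    s = x[0] if x[0] > 0.0 else 0.0
    h = x[5] if x[5] > 0.0 else 0.0

    alpha = phi_kernel(p[16], p[17], p[18], p[19], s)
    beta = phi_kernel(p[20], p[21], p[22], p[23], s)

    v1 = p[0] * alpha * p[14] * s / (p[4] + s)
    v2 = p[1] * (1.0 - alpha) * p[14] * s / (p[5] + s)
    v3 = p[2] * beta * p[15] * s / (p[6] + s)
    v4 = p[3] * (1.0 - beta) * p[15] * h / (p[7] + h)
    v5 = p[8] * s / (p[11] + s)
    v6 = p[9] * s / (p[12] + s)
    v7 = p[10] * h / (p[13] + h)

    dx[0] = -(v1 + v2 + v3 + v5 + v6)
    dx[1] = v1
    dx[2] = v3
    dx[3] = v5
    dx[4] = v6
    dx[5] = v2 - v4 - v7
    dx[6] = v4
    dx[7] = v7


@njit(cache=True, fastmath=False)
def fluxes_kernel(x, p, v):
    s = x[0] if x[0] > 0.0 else 0.0
    h = x[5] if x[5] > 0.0 else 0.0
    alpha = phi_kernel(p[16], p[17], p[18], p[19], s)
    beta = phi_kernel(p[20], p[21], p[22], p[23], s)
    v[0] = p[0] * alpha * p[14] * s / (p[4] + s)
    v[1] = p[1] * (1.0 - alpha) * p[14] * s / (p[5] + s)
    v[2] = p[2] * beta * p[15] * s / (p[6] + s)
    v[3] = p[3] * (1.0 - beta) * p[15] * h / (p[7] + h)
    v[4] = p[8] * s / (p[11] + s)
    v[5] = p[9] * s / (p[12] + s)
    v[6] = p[10] * h / (p[13] + h)


@njit(cache=True, fastmath=False)
def jac_cols_kernel(x, p, c0, c5):
    """Nonzero Jacobian columns d(dx)/d[MeIQx] (c0) and d(dx)/d[HONH] (c5)."""
    s = x[0] if x[0] > 0.0 else 0.0
    h = x[5] if x[5] > 0.0 else 0.0

    alpha = phi_kernel(p[16], p[17], p[18], p[19], s)
    beta = phi_kernel(p[20], p[21], p[22], p[23], s)
    da = dphi_ds_kernel(p[16], p[17], p[18], p[19], s)
    db = dphi_ds_kernel(p[20], p[21], p[22], p[23], s)

    f1 = s / (p[4] + s)
    f2 = s / (p[5] + s)
    f3 = s / (p[6] + s)
    f4 = h / (p[7] + h)

    dv1 = p[0] * p[14] * (da * f1 + alpha * p[4] / (p[4] + s) ** 2)
    dv2 = p[1] * p[14] * (-da * f2 + (1.0 - alpha) * p[5] / (p[5] + s) ** 2)
    dv3 = p[2] * p[15] * (db * f3 + beta * p[6] / (p[6] + s) ** 2)
    dv4_s = p[3] * p[15] * (-db) * f4
    dv4_h = p[3] * (1.0 - beta) * p[15] * p[7] / (p[7] + h) ** 2
    dv5 = p[8] * p[11] / (p[11] + s) ** 2
    dv6 = p[9] * p[12] / (p[12] + s) ** 2
    dv7_h = p[10] * p[13] / (p[13] + h) ** 2

    if x[0] <= 0.0:
        dv1 = dv2 = dv3 = dv4_s = dv5 = dv6 = 0.0
    if x[5] <= 0.0:
        dv4_h = dv7_h = 0.0

    c0[0] = -(dv1 + dv2 + dv3 + dv5 + dv6)
    c0[1] = dv1
    c0[2] = dv3
    c0[3] = dv5
    c0[4] = dv6
    c0[5] = dv2 - dv4_s
    c0[6] = dv4_s
    c0[7] = 0.0

    c5[0] = 0.0
    c5[1] = 0.0
    c5[2] = 0.0
    c5[3] = 0.0
    c5[4] = 0.0
    c5[5] = -(dv4_h + dv7_h)
    c5[6] = dv4_h
    c5[7] = dv7_h


@njit(cache=True, fastmath=False)
def _solve_newton_lin(c, c0, c5, b, y):
    """Solve (I - c*J) y = b exploiting that J has nonzero columns 0 and 5."""
    a00 = 1.0 - c * c0[0]
    a05 = -c * c5[0]
    a50 = -c * c0[5]
    a55 = 1.0 - c * c5[5]
    det = a00 * a55 - a05 * a50
    if det == 0.0:
        return False
    y0 = (b[0] * a55 - a05 * b[5]) / det
    y5 = (a00 * b[5] - a50 * b[0]) / det
    y[0] = y0
    y[5] = y5
    for i in range(N_SPECIES):
        if i != 0 and i != 5:
            y[i] = b[i] + c * (c0[i] * y0 + c5[i] * y5)
    return True


@njit(cache=True, fastmath=False)
def _implicit_stage(y_guess, rconst, c, p, scale, y_out):
    """Newton iteration for y - c*f(y) = rconst; chord Jacobian refreshed
    each iteration (it is nearly free here)."""
    c0 = np.empty(N_SPECIES)
    c5 = np.empty(N_SPECIES)
    g = np.empty(N_SPECIES)
    d = np.empty(N_SPECIES)
    f = np.empty(N_SPECIES)
    y = y_out
    for i in range(N_SPECIES):
        y[i] = y_guess[i]
    for _ in range(12):
        rhs_kernel(y, p, f)
        ok = True
        for i in range(N_SPECIES):
            g[i] = rconst[i] + c * f[i] - y[i]
            if not np.isfinite(g[i]):
                return False
        jac_cols_kernel(y, p, c0, c5)
        if not _solve_newton_lin(c, c0, c5, g, d):
            return False
        conv = True
        for i in range(N_SPECIES):
            y[i] += d[i]
            if abs(d[i]) > 1e-10 * (1e-4 * scale + abs(y[i])):
                conv = False
        if conv:
            return True
    return False


@njit(cache=True, fastmath=False)
def _trbdf2_step(y, t, h, p, scale, y_new):
    """One TR-BDF2 step from t to t+h.  Returns True on Newton success."""
    gam = _GAMMA
    f0 = np.empty(N_SPECIES)
    rhs_kernel(y, p, f0)

    # trapezoidal stage to t + gamma*h
    c1 = 0.5 * gam * h
    rconst = np.empty(N_SPECIES)
    guess = np.empty(N_SPECIES)
    yg = np.empty(N_SPECIES)
    for i in range(N_SPECIES):
        rconst[i] = y[i] + c1 * f0[i]
        guess[i] = y[i] + gam * h * f0[i]
    if not _implicit_stage(guess, rconst, c1, p, scale, yg):
        return False

    # BDF2 stage on the nonuniform pair (gamma*h, (1-gamma)*h)
    w1 = 1.0 / (gam * (2.0 - gam))
    w0 = (1.0 - gam) ** 2 / (gam * (2.0 - gam))
    c2 = (1.0 - gam) * h / (2.0 - gam)
    for i in range(N_SPECIES):
        rconst[i] = w1 * yg[i] - w0 * y[i]
        guess[i] = yg[i]
    return _implicit_stage(guess, rconst, c2, p, scale, y_new)


@njit(cache=True, fastmath=False)
def integrate_fixed(p, dose, t_out, n_steps):
    """Integrate from (dose, 0, ..., 0) on a logarithmically graded grid and
    return the states at the requested output times (must be sorted, > 0).

    The grid is deterministic in (t_out, n_steps), which keeps the map
    params -> states smooth: essential for finite-difference trust-region
    optimisation.  Failed Newton steps fall back to local bisection.
    Returns (states, ok_flag).
    """
    n_out = t_out.shape[0]
    out = np.zeros((n_out, N_SPECIES))
    t_end = t_out[n_out - 1]
    if dose <= 0.0 or t_end <= 0.0:
        return out, True

    # graded grid: log-spaced from t_end*1e-6 to t_end/10 (resolves initial
    # transients), then uniform to t_end (resolves late sigmoid fronts);
    # merged with t_out
    n_log = n_steps // 2
    n_lin = n_steps - n_log
    t_min = t_end * 1e-6
    t_mid = t_end * 0.1
    grid = np.empty(n_steps + n_out)
    lg0 = np.log(t_min)
    lg1 = np.log(t_mid)
    for i in range(n_log):
        grid[i] = np.exp(lg0 + (lg1 - lg0) * i / (n_log - 1.0))
    for i in range(n_lin):
        grid[n_log + i] = t_mid + (t_end - t_mid) * (i + 1.0) / n_lin
    for j in range(n_out):
        grid[n_steps + j] = t_out[j]
    grid = np.sort(grid)

    y = np.zeros(N_SPECIES)
    y[0] = dose
    y_new = np.empty(N_SPECIES)
    t = 0.0
    iout = 0
    for k in range(grid.shape[0]):
        t_next = grid[k]
        if t_next <= t:
            if iout < n_out and abs(t - t_out[iout]) <= 1e-12 * t_end:
                for i in range(N_SPECIES):
                    out[iout, i] = y[i]
                iout += 1
            continue
        # advance t -> t_next, bisecting on Newton failure
        while t < t_next - 1e-15 * t_end:
            h = t_next - t
            n_halve = 0
            while not _trbdf2_step(y, t, h, p, dose, y_new):
                h *= 0.5
                n_halve += 1
                if n_halve > 48:
                    return out, False
            for i in range(N_SPECIES):
                y[i] = y_new[i]
            t += h
        t = t_next
        if iout < n_out and abs(t - t_out[iout]) <= 1e-12 * t_end:
            for i in range(N_SPECIES):
                out[iout, i] = y[i]
            iout += 1
    # clip solver noise
    for j in range(n_out):
        for i in range(N_SPECIES):
            if out[j, i] < 0.0:
                out[j, i] = 0.0
    return out, True


@njit(cache=True, fastmath=False)
def jac_full_kernel(x, p):
    """Dense 8x8 Jacobian (for the scipy Radau path)."""
    J = np.zeros((N_SPECIES, N_SPECIES))
    c0 = np.empty(N_SPECIES)
    c5 = np.empty(N_SPECIES)
    jac_cols_kernel(x, p, c0, c5)
    for i in range(N_SPECIES):
        J[i, 0] = c0[i]
        J[i, 5] = c5[i]
    return J
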