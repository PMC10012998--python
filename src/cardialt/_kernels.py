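"""Compiled numerical core: minimal-model right-hand side and steppers.

Single-cell (0D) integration uses the exact rate expressions.  The 2D tissue
stepper replaces the three voltage-dependent tanh shape functions by linear
interpolation in precomputed tables; the shapes do not depend on any of the
spatially heterogeneous time constants, so per-pixel parameter fields remain
exact.  Table resolution is chosen so the interpolation error (<1e-6 relative)
is far below the explicit-Euler discretization error.

Heaviside convention: Theta(0) = 1 (right-continuous), used everywhere.

Parameter vector layout is fixed by ``cardialt.parameters.PARAM_NAMES``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Indices into the packed parameter vector (see parameters.PARAM_NAMES).
(I_U_O, I_U_U, I_U_S, I_U_SO, I_U_WM, I_U_WP, I_W_INF_STAR,
 I_TH_V, I_TH_VM, I_TH_W, I_TH_O,
 I_TAU_VP, I_TAU_V1M, I_TAU_V2M,
 I_TAU_W1P, I_TAU_W2P, I_TAU_W1M, I_TAU_W2M,
 I_TAU_WINF, I_TAU_FI, I_TAU_SI, I_TAU_S1, I_TAU_S2,
 I_TAU_SO1, I_TAU_SO2, I_TAU_O1, I_TAU_O2,
 I_K_WP, I_K_WM, I_K_S, I_K_SO,
 I_D_PAR, I_D_PERP) = range(33)

TABLE_U_MIN = -2.0
TABLE_U_MAX = 3.0
TABLE_N = 16384


@njit(cache=True, inline="always")
def heaviside(x):
    return 1.0 if x >= 0.0 else 0.0


@njit(cache=True)
def rate_functions(u, P):
    """tau_v-, tau_w+, tau_w-, tau_so, tau_s, tau_o, v_inf, w_inf at voltage u."""
    hv_m = heaviside(u - P[I_TH_VM])
    hw = heaviside(u - P[I_TH_W])
    ho = heaviside(u - P[I_TH_O])
    tau_vm = (1.0 - hv_m) * P[I_TAU_V1M] + hv_m * P[I_TAU_V2M]
    tau_wp = P[I_TAU_W1P] + (P[I_TAU_W2P] - P[I_TAU_W1P]) * (
        1.0 + math.tanh(P[I_K_WP] * (u - P[I_U_WP]))) / 2.0
    tau_wm = P[I_TAU_W1M] + (P[I_TAU_W2M] - P[I_TAU_W1M]) * (
        1.0 + math.tanh(P[I_K_WM] * (u - P[I_U_WM]))) / 2.0
    tau_so = P[I_TAU_SO1] + (P[I_TAU_SO2] - P[I_TAU_SO1]) * (
        1.0 + math.tanh(P[I_K_SO] * (u - P[I_U_SO]))) / 2.0
    tau_s = (1.0 - hw) * P[I_TAU_S1] + hw * P[I_TAU_S2]
    tau_o = (1.0 - ho) * P[I_TAU_O1] + ho * P[I_TAU_O2]
    v_inf = 1.0 - hv_m
    w_inf = (1.0 - ho) * (1.0 - u / P[I_TAU_WINF]) + ho * P[I_W_INF_STAR]
    return tau_vm, tau_wp, tau_wm, tau_so, tau_s, tau_o, v_inf, w_inf


@njit(cache=True)
def currents(u, v, w, s, P):
    """Fast-inward, slow-outward and slow-inward current densities (1/ms)."""
    hv = heaviside(u - P[I_TH_V])
    hw = heaviside(u - P[I_TH_W])
    tau_so = P[I_TAU_SO1] + (P[I_TAU_SO2] - P[I_TAU_SO1]) * (
        1.0 + math.tanh(P[I_K_SO] * (u - P[I_U_SO]))) / 2.0
    ho = heaviside(u - P[I_TH_O])
    tau_o = (1.0 - ho) * P[I_TAU_O1] + ho * P[I_TAU_O2]
    j_fi = -hv * (u - P[I_TH_V]) * (P[I_U_U] - u) * v / P[I_TAU_FI]
    j_so = (1.0 - hw) * (u - P[I_U_O]) / tau_o + hw / tau_so
    j_si = -hw * w * s / P[I_TAU_SI]
    return j_fi, j_so, j_si


@njit(cache=True)
def derivatives(u, v, w, s, P, i_ext):
    """du/dt, dv/dt, dw/dt, ds/dt for a space-clamped cell."""
    tau_vm, tau_wp, tau_wm, tau_so, tau_s, tau_o, v_inf, w_inf = rate_functions(u, P)
    hv = heaviside(u - P[I_TH_V])
    hw = heaviside(u - P[I_TH_W])
    j_fi = -hv * (u - P[I_TH_V]) * (P[I_U_U] - u) * v / P[I_TAU_FI]
    j_so = (1.0 - hw) * (u - P[I_U_O]) / tau_o + hw / tau_so
    j_si = -hw * w * s / P[I_TAU_SI]
    du = -(j_fi + j_so + j_si) + i_ext
    dv = (1.0 - hv) * (v_inf - v) / tau_vm - hv * v / P[I_TAU_VP]
    dw = (1.0 - hw) * (w_inf - w) / tau_wm - hw * w / tau_wp
    ds = ((1.0 + math.tanh(P[I_K_S] * (u - P[I_U_S]))) / 2.0 - s) / tau_s
    return du, dv, dw, ds


@njit(cache=True)
def integrate_cell(P, state0, dt, n_steps, stim_period_ms, stim_dur_ms,
                   stim_amp, record_every):
    """Explicit-Euler 0D integration under periodic rectangular stimulation.

    Stimulation pulses start at t = 0, stim_period, 2*stim_period, ...
    Returns (trace of u sampled every ``record_every`` steps, final state).
    """
    u, v, w, s = state0[0], state0[1], state0[2], state0[3]
    n_rec = n_steps // record_every + 1
    trace = np.empty(n_rec, dtype=np.float64)
    trace[0] = u
    k = 1
    for step in range(n_steps):
        t = step * dt
        i_ext = 0.0
        if stim_amp != 0.0 and stim_period_ms > 0.0:
            phase = t % stim_period_ms
            if phase < stim_dur_ms:
                i_ext = stim_amp
        du, dv, dw, ds = derivatives(u, v, w, s, P, i_ext)
        u += dt * du
        v += dt * dv
        w += dt * dw
        s += dt * ds
        if (step + 1) % record_every == 0 and k < n_rec:
            trace[k] = u
            k += 1
    out_state = np.array([u, v, w, s])
    return trace[:k], out_state


def build_shape_tables():
    """Tabulate the parameter-separable voltage shape functions.

    Returns (u0, inv_du, Wp, Wm, Tso, Sinf) where e.g.
    tau_so(u) = tau_so1 + (tau_so2 - tau_so1) * Tso(u).
    The shapes use the default slopes/offsets; heterogeneity never touches
    them (only the additive/multiplicative time constants vary in space).
    """
    from .parameters import ModelParameters

    p = ModelParameters()
    u = np.linspace(TABLE_U_MIN, TABLE_U_MAX, TABLE_N)
    wp = (1.0 + np.tanh(p.k_w_plus * (u - p.u_w_plus))) / 2.0
    wm = (1.0 + np.tanh(p.k_w_minus * (u - p.u_w_minus))) / 2.0
    tso = (1.0 + np.tanh(p.k_so * (u - p.u_so))) / 2.0
    sinf = (1.0 + np.tanh(p.k_s * (u - p.u_s))) / 2.0
    inv_du = (TABLE_N - 1) / (TABLE_U_MAX - TABLE_U_MIN)
    return u[0], inv_du, wp, wm, tso, sinf


@njit(cache=True, inline="always")
def _lerp(table, x, x0, inv_dx):
    pos = (x - x0) * inv_dx
    if pos <= 0.0:
        return table[0]
    n = table.shape[0]
    if pos >= n - 1:
        return table[n - 1]
    i = int(pos)
    frac = pos - i
    return table[i] * (1.0 - frac) + table[i + 1] * frac


@njit(cache=True)
def step_tissue_kernel(u, v, w, s, un, vn, wn, sn,
                       phi, inv_phi, pd11, pd12, pd22,
                       tw1p, tw2p, tso1, tso2, tsi,
                       P, dt, dx, stim_grid, stim_on,
                       tab_u0, tab_inv_du, tab_wp, tab_wm, tab_tso, tab_sinf):
    """One explicit-Euler step of the monodomain equations on a 2D grid.

    ``pd11`` etc. are the diffusion tensor entries pre-multiplied by the
    phase field phi; ``inv_phi`` is 1/max(phi, phi_min).  Face diffusivities
    for the normal terms use the harmonic mean of phi*D, which vanishes at
    tissue boundaries and so enforces zero flux on arbitrary shapes.  The
    cross term (phi*D12) uses centred differences and is dropped on the
    outermost frame of the grid.
    """
    ny, nx = u.shape
    inv_dx2 = 1.0 / (dx * dx)
    inv_4dx2 = 0.25 * inv_dx2
    th_v = P[I_TH_V]
    th_vm = P[I_TH_VM]
    th_w = P[I_TH_W]
    th_o = P[I_TH_O]
    u_o = P[I_U_O]
    u_u = P[I_U_U]
    tau_fi = P[I_TAU_FI]
    tau_vp = P[I_TAU_VP]
    tau_v1m = P[I_TAU_V1M]
    tau_v2m = P[I_TAU_V2M]
    tau_w1m = P[I_TAU_W1M]
    tau_w2m = P[I_TAU_W2M]
    tau_winf = P[I_TAU_WINF]
    w_star = P[I_W_INF_STAR]
    tau_s1 = P[I_TAU_S1]
    tau_s2 = P[I_TAU_S2]
    tau_o1 = P[I_TAU_O1]
    tau_o2 = P[I_TAU_O2]
    for i in range(ny):
        for j in range(nx):
            uc = u[i, j]
            # --- diffusion: normal terms, harmonic face mean of phi*D ---
            lap = 0.0
            ac = pd11[i, j]
            if j + 1 < nx:
                an = pd11[i, j + 1]
                den = ac + an
                if den > 0.0:
                    lap += (2.0 * ac * an / den) * (u[i, j + 1] - uc)
            if j - 1 >= 0:
                an = pd11[i, j - 1]
                den = ac + an
                if den > 0.0:
                    lap += (2.0 * ac * an / den) * (u[i, j - 1] - uc)
            ac = pd22[i, j]
            if i + 1 < ny:
                an = pd22[i + 1, j]
                den = ac + an
                if den > 0.0:
                    lap += (2.0 * ac * an / den) * (u[i + 1, j] - uc)
            if i - 1 >= 0:
                an = pd22[i - 1, j]
                den = ac + an
                if den > 0.0:
                    lap += (2.0 * ac * an / den) * (u[i - 1, j] - uc)
            lap *= inv_dx2
            # --- cross terms d/dx(phi D12 du/dy) + d/dy(phi D12 du/dx) ---
            if 0 < i < ny - 1 and 0 < j < nx - 1:
                cross = (pd12[i, j + 1] * (u[i + 1, j + 1] - u[i - 1, j + 1])
                         - pd12[i, j - 1] * (u[i + 1, j - 1] - u[i - 1, j - 1])
                         + pd12[i + 1, j] * (u[i + 1, j + 1] - u[i + 1, j - 1])
                         - pd12[i - 1, j] * (u[i - 1, j + 1] - u[i - 1, j - 1]))
                lap += cross * inv_4dx2
            diff = lap * inv_phi[i, j]
            # --- reaction (tabulated tanh shapes, exact Heaviside branches) ---
            vv = v[i, j]
            ww = w[i, j]
            ss = s[i, j]
            hv = 1.0 if uc >= th_v else 0.0
            hw = 1.0 if uc >= th_w else 0.0
            ho = 1.0 if uc >= th_o else 0.0
            hvm = 1.0 if uc >= th_vm else 0.0
            f_tso = _lerp(tab_tso, uc, tab_u0, tab_inv_du)
            tau_so = tso1[i, j] + (tso2[i, j] - tso1[i, j]) * f_tso
            tau_o = tau_o1 if ho == 0.0 else tau_o2
            j_fi = -hv * (uc - th_v) * (u_u - uc) * vv / tau_fi
            j_so = (1.0 - hw) * (uc - u_o) / tau_o + hw / tau_so
            j_si = -hw * ww * ss / tsi[i, j]
            i_ext = stim_on * stim_grid[i, j]
            du = diff - (j_fi + j_so + j_si) + i_ext
            # gates
            tau_vm = tau_v1m if hvm == 0.0 else tau_v2m
            v_inf = 1.0 - hvm
            dv = (1.0 - hv) * (v_inf - vv) / tau_vm - hv * vv / tau_vp
            f_wp = _lerp(tab_wp, uc, tab_u0, tab_inv_du)
            tau_wp = tw1p[i, j] + (tw2p[i, j] - tw1p[i, j]) * f_wp
            f_wm = _lerp(tab_wm, uc, tab_u0, tab_inv_du)
            tau_wm = tau_w1m + (tau_w2m - tau_w1m) * f_wm
            w_inf = (1.0 - uc / tau_winf) if ho == 0.0 else w_star
            dw = (1.0 - hw) * (w_inf - ww) / tau_wm - hw * ww / tau_wp
            s_inf = _lerp(tab_sinf, uc, tab_u0, tab_inv_du)
            tau_s = tau_s1 if hw == 0.0 else tau_s2
            ds = (s_inf - ss) / tau_s
            un[i, j] = uc + dt * du
            vn[i, j] = vv + dt * dv
            wn[i, j] = ww + dt * dw
            sn[i, j] = ss + dt * ds


@njit(cache=True)
def diffusion_rhs_kernel(u, out, inv_phi, pd11, pd12, pd22, dx):
    """div(phi D grad u)/phi alone (no reaction) -- used for operator tests."""
    ny, nx = u.shape
    inv_dx2 = 1.0 / (dx * dx)
    inv_4dx2 = 0.25 * inv_dx2
    for i in range(ny):
        for j in range(nx):
            uc = u[i, j]
            lap = 0.0
            ac = pd11[i, j]
            if j + 1 < nx:
                an = pd11[i, j + 1]
                den = ac + an
                if den > 0.0:
                    lap += (2.0 * ac * an / den) * (u[i, j + 1] - uc)
            if j - 1 >= 0:
                an = pd11[i, j - 1]
                den = ac + an
                if den > 0.0:
                    lap += (2.0 * ac * an / den) * (u[i, j - 1] - uc)
            ac = pd22[i, j]
            if i + 1 < ny:
                an = pd22[i + 1, j]
                den = ac + an
                if den > 0.0:
                    lap += (2.0 * ac * an / den) * (u[i + 1, j] - uc)
            if i - 1 >= 0:
                an = pd22[i - 1, j]
                den = ac + an
                if den > 0.0:
                    lap += (2.0 * ac * an / den) * (u[i - 1, j] - uc)
            lap *= inv_dx2
            if 0 < i < ny - 1 and 0 < j < nx - 1:
                cross = (pd12[i, j + 1] * (u[i + 1, j + 1] - u[i - 1, j + 1])
                         - pd12[i, j - 1] * (u[i + 1, j - 1] - u[i - 1, j - 1])
                         + pd12[i + 1, j] * (u[i + 1, j + 1] - u[i + 1, j - 1])
                         - pd12[i - 1, j] * (u[i - 1, j + 1] - u[i - 1, j - 1]))
                lap += cross * inv_4dx2
            out[i, j] = lap * inv_phi[i, j]
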