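"""Numba kernels for the backward-Euler cable solver.

Units follow the NEURON convention throughout: mV, ms, µm, nA, nF, µS, MΩ,
S/cm² for densities, mA/cm² for current densities, mM for concentrations.
With capacitance in nF and conductance in µS, nF·mV/ms = µS·mV = nA, so the
membrane equation needs no extra unit factors.

Channel registry order (fixed): Ih, Im, NaT, Kd, Kv2, Kv3, SK, CaLVA, CaHVA.
Rate functions are standard HH-style kinetics in the style of cortical
pyramidal-cell models (Hay-type); temperature enters as a Q10 factor on the
gating time constants.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# channel indices
ICH_IH, ICH_IM, ICH_NAT, ICH_KD, ICH_KV2, ICH_KV3, ICH_SK, ICH_CALVA, ICH_CAHVA = range(9)

E_NA = 50.0
E_K = -85.0
E_H = -45.0
E_CA = 132.0
FARADAY = 96485.332  # C/mol


@njit(cache=True, fastmath=True)
def _vtrap(x, y):
    # x / (exp(x/y) - 1) with the removable singularity handled
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (np.exp(x / y) - 1.0)


@njit(cache=True, fastmath=True)
def rates_ih(v):
    a = 0.00643 * _vtrap(v + 154.9, 11.9)  # alpha in 1/ms
    b = 0.193 * np.exp(v / 33.1)
    tau = 1.0 / (a + b)
    inf = a / (a + b)
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_im(v, qt):
    a = 0.0033 * np.exp(0.1 * (v + 35.0))
    b = 0.0033 * np.exp(-0.1 * (v + 35.0))
    tau = 1.0 / (a + b) / qt
    inf = a / (a + b)
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_nat_m(v, qt):
    a = 0.182 * _vtrap(-(v + 38.0), 6.0)
    b = 0.124 * _vtrap(v + 38.0, 6.0)
    tau = 1.0 / (a + b) / qt
    inf = a / (a + b)
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_nat_h(v, qt):
    a = 0.015 * _vtrap(v + 66.0, 6.0)
    b = 0.015 * _vtrap(-(v + 66.0), 6.0)
    tau = 1.0 / (a + b) / qt
    inf = a / (a + b)
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_kd_m(v, qt):
    # persistent K+, activation
    inf = 1.0 / (1.0 + np.exp(-(v + 11.0) / 12.0))
    if v < -50.0:
        tau = (1.25 + 175.03 * np.exp(0.026 * v)) / qt
    else:
        tau = (1.25 + 13.0 * np.exp(-0.026 * v)) / qt
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_kd_h(v, qt):
    inf = 1.0 / (1.0 + np.exp((v + 64.0) / 11.0))
    tau = (360.0 + (1010.0 + 24.0 * (v + 65.0)) * np.exp(-(((v + 85.0) / 48.0) ** 2))) / qt
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_kv2_m(v, qt):
    # transient K+, activation
    inf = 1.0 / (1.0 + np.exp(-(v + 10.0) / 19.0))
    tau = (0.34 + 0.92 * np.exp(-(((v + 81.0) / 59.0) ** 2))) / qt
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_kv2_h(v, qt):
    inf = 1.0 / (1.0 + np.exp((v + 76.0) / 10.0))
    tau = (8.0 + 49.0 * np.exp(-(((v + 83.0) / 23.0) ** 2))) / qt
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_kv3_m(v):
    inf = 1.0 / (1.0 + np.exp(-(v - 18.7) / 9.7))
    tau = 4.0 / (1.0 + np.exp(-(v + 46.56) / 44.14))
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_calva_m(v, qt):
    inf = 1.0 / (1.0 + np.exp(-(v + 40.0) / 6.0))
    tau = (5.0 + 20.0 / (1.0 + np.exp((v + 35.0) / 5.0))) / qt
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_calva_h(v, qt):
    inf = 1.0 / (1.0 + np.exp((v + 90.0) / 6.4))
    tau = (20.0 + 50.0 / (1.0 + np.exp((v + 50.0) / 7.0))) / qt
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_cahva_m(v):
    a = 0.055 * _vtrap(-27.0 - v, 3.8)
    b = 0.94 * np.exp((-75.0 - v) / 17.0)
    tau = 1.0 / (a + b)
    inf = a / (a + b)
    return inf, tau


@njit(cache=True, fastmath=True)
def rates_cahva_h(v):
    a = 0.000457 * np.exp((-13.0 - v) / 50.0)
    b = 0.0065 / (np.exp((-v - 15.0) / 28.0) + 1.0)
    tau = 1.0 / (a + b)
    inf = a / (a + b)
    return inf, tau


@njit(cache=True, fastmath=True)
def sk_open(ca):
    c = ca if ca > 1e-12 else 1e-12
    return 1.0 / (1.0 + (0.00043 / c) ** 4.8)


@njit(cache=True, fastmath=True)
def init_gates(v, n, qt):
    """Steady-state gate values at voltage v; (12, n) array.

    Rows: ih.m, im.m, nat.m, nat.h, kd.m, kd.h, kv2.m, kv2.h, kv3.m,
    calva.m, calva.h, cahva.m (cahva.h is row 12 -> stored as 13 rows).
    """
    g = np.empty((13, n))
    for i in range(n):
        g[0, i] = rates_ih(v)[0]
        g[1, i] = rates_im(v, qt)[0]
        g[2, i] = rates_nat_m(v, qt)[0]
        g[3, i] = rates_nat_h(v, qt)[0]
        g[4, i] = rates_kd_m(v, qt)[0]
        g[5, i] = rates_kd_h(v, qt)[0]
        g[6, i] = rates_kv2_m(v, qt)[0]
        g[7, i] = rates_kv2_h(v, qt)[0]
        g[8, i] = rates_kv3_m(v)[0]
        g[9, i] = rates_calva_m(v, qt)[0]
        g[10, i] = rates_calva_h(v, qt)[0]
        g[11, i] = rates_cahva_m(v)[0]
        g[12, i] = rates_cahva_h(v)[0]
    return g


@njit(cache=True, fastmath=True)
def _gate_step(x, inf, tau, dt):
    # exponential Euler; unconditionally stable
    return inf + (x - inf) * np.exp(-dt / tau)


@njit(cache=True)
def simulate(
    parent,  # (N,) int64, parent[0] == -1, parent[i] < i
    cap,  # (N,) nF
    g_ax,  # (N,) µS conductance to parent (g_ax[0] unused)
    g_pas_u,  # (N,) µS
    e_pas,  # (N,) mV
    gbar,  # (9, N) µS
    inv_area,  # (N,) 1/cm² (for Ca current density)
    ca_mask,  # (N,) bool
    efield,  # (N,) mV static extracellular offsets
    sigma,  # mV per-step noise SD
    noise_mean,  # mV
    i_inj,  # (N,) nA constant injected current
    dt,
    n_steps,
    v0,
    qt,
    ca_gamma,
    ca_tau,
    ca_shell,
    ca_base,
    rec_idx,  # (R,) int64
    rng,  # np.random.Generator
):
    """Backward-Euler integration of the compartmental cable equation.

    Extracellular offsets enter the axial terms as
    Σ_k ((v_k + e_k) − (v_j + e_j)) g_jk, so a constant offset added to every
    compartment has no effect (gauge invariance).  Per-step noise ξ_j ~
    N(noise_mean, sigma²) is redrawn i.i.d. for each compartment and step and
    held piecewise-constant over the step.

    Returns (vrec, v, ca): recorded traces (R, n_steps+1), final voltages and
    final Ca.  Diverged states propagate NaN into vrec.
    """
    n = parent.shape[0]
    v = np.full(n, v0)
    active = gbar.sum() > 0.0
    gates = init_gates(v0, n, qt)
    ca = np.full(n, ca_base)

    nrec = rec_idx.shape[0]
    vrec = np.empty((nrec, n_steps + 1))
    for r in range(nrec):
        vrec[r, 0] = v0

    D = np.empty(n)
    rhs = np.empty(n)
    e = np.empty(n)
    inv_dt = 1.0 / dt

    for step in range(n_steps):
        # extracellular offsets for this step
        if sigma > 0.0:
            for i in range(n):
                e[i] = efield[i] + noise_mean + sigma * rng.standard_normal()
        else:
            for i in range(n):
                e[i] = efield[i] + noise_mean

        # membrane conductances and reversal-weighted sums
        for i in range(n):
            gsum = g_pas_u[i]
            gesum = g_pas_u[i] * e_pas[i]
            if active:
                vi = v[i]
                # Ih
                if gbar[0, i] > 0.0:
                    inf, tau = rates_ih(vi)
                    gates[0, i] = _gate_step(gates[0, i], inf, tau, dt)
                    g = gbar[0, i] * gates[0, i]
                    gsum += g
                    gesum += g * E_H
                # Im
                if gbar[1, i] > 0.0:
                    inf, tau = rates_im(vi, qt)
                    gates[1, i] = _gate_step(gates[1, i], inf, tau, dt)
                    g = gbar[1, i] * gates[1, i]
                    gsum += g
                    gesum += g * E_K
                # NaT (m³h)
                if gbar[2, i] > 0.0:
                    inf, tau = rates_nat_m(vi, qt)
                    gates[2, i] = _gate_step(gates[2, i], inf, tau, dt)
                    inf, tau = rates_nat_h(vi, qt)
                    gates[3, i] = _gate_step(gates[3, i], inf, tau, dt)
                    g = gbar[2, i] * gates[2, i] ** 3 * gates[3, i]
                    gsum += g
                    gesum += g * E_NA
                # Kd (m²h persistent)
                if gbar[3, i] > 0.0:
                    inf, tau = rates_kd_m(vi, qt)
                    gates[4, i] = _gate_step(gates[4, i], inf, tau, dt)
                    inf, tau = rates_kd_h(vi, qt)
                    gates[5, i] = _gate_step(gates[5, i], inf, tau, dt)
                    g = gbar[3, i] * gates[4, i] ** 2 * gates[5, i]
                    gsum += g
                    gesum += g * E_K
                # Kv2-like (m⁴h transient)
                if gbar[4, i] > 0.0:
                    inf, tau = rates_kv2_m(vi, qt)
                    gates[6, i] = _gate_step(gates[6, i], inf, tau, dt)
                    inf, tau = rates_kv2_h(vi, qt)
                    gates[7, i] = _gate_step(gates[7, i], inf, tau, dt)
                    g = gbar[4, i] * gates[6, i] ** 4 * gates[7, i]
                    gsum += g
                    gesum += g * E_K
                # Kv3-like (m)
                if gbar[5, i] > 0.0:
                    inf, tau = rates_kv3_m(vi)
                    gates[8, i] = _gate_step(gates[8, i], inf, tau, dt)
                    g = gbar[5, i] * gates[8, i]
                    gsum += g
                    gesum += g * E_K
                # SK (Ca-gated, instantaneous)
                if gbar[6, i] > 0.0:
                    g = gbar[6, i] * sk_open(ca[i])
                    gsum += g
                    gesum += g * E_K
                # CaLVA (m²h)
                if gbar[7, i] > 0.0:
                    inf, tau = rates_calva_m(vi, qt)
                    gates[9, i] = _gate_step(gates[9, i], inf, tau, dt)
                    inf, tau = rates_calva_h(vi, qt)
                    gates[10, i] = _gate_step(gates[10, i], inf, tau, dt)
                    g = gbar[7, i] * gates[9, i] ** 2 * gates[10, i]
                    gsum += g
                    gesum += g * E_CA
                # CaHVA (m²h)
                if gbar[8, i] > 0.0:
                    inf, tau = rates_cahva_m(vi)
                    gates[11, i] = _gate_step(gates[11, i], inf, tau, dt)
                    inf, tau = rates_cahva_h(vi)
                    gates[12, i] = _gate_step(gates[12, i], inf, tau, dt)
                    g = gbar[8, i] * gates[11, i] ** 2 * gates[12, i]
                    gsum += g
                    gesum += g * E_CA

            D[i] = cap[i] * inv_dt + gsum
            rhs[i] = cap[i] * inv_dt * v[i] + gesum + i_inj[i]

        # axial coupling (tree edges i -- parent[i])
        for i in range(1, n):
            p = parent[i]
            D[i] += g_ax[i]
            D[p] += g_ax[i]
            de = e[p] - e[i]
            rhs[i] += g_ax[i] * de
            rhs[p] -= g_ax[i] * de

        # Hines elimination, leaves to root
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / D[i]
            D[p] -= f * g_ax[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / D[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / D[i]

        # calcium shell dynamics (exponential update, exact for frozen i_Ca)
        if active:
            for i in range(n):
                if ca_mask[i]:
                    g_lva = gbar[7, i] * gates[9, i] ** 2 * gates[10, i]
                    g_hva = gbar[8, i] * gates[11, i] ** 2 * gates[12, i]
                    # µS·mV / cm² → nA/cm²; ×1e-6 → mA/cm²
                    i_ca = (g_lva + g_hva) * (v[i] - E_CA) * inv_area[i] * 1e-6
                    drive = -10000.0 * i_ca * ca_gamma / (2.0 * FARADAY * ca_shell)
                    ca_ss = ca_base + drive * ca_tau
                    ca[i] = ca_ss + (ca[i] - ca_ss) * np.exp(-dt / ca_tau)
                    if ca[i] < 0.0:
                        ca[i] = 0.0

        if not np.isfinite(v[0]):
            for r in range(nrec):
                for s in range(step + 1, n_steps + 1):
                    vrec[r, s] = np.nan
            return vrec, v, ca

        for r in range(nrec):
            vrec[r, step + 1] = v[rec_idx[r]]

    return vrec, v, ca
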