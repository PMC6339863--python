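"""Compiled scalar engine for the fixed-step RK4 integration.

This module duplicates the gating formulas of :mod:`chayenergy.model` as
scalar numba functions so the 3e6-step production runs compile to machine
code.  A test pins the scalar right-hand side to the vectorized public
implementation; any edit here must keep the two in lockstep.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SINGULAR_TOL = 1e-7


@njit(cache=False)
def _ratio_rate(u: float, a: float, b: float) -> float:
    if abs(b * u) < _SINGULAR_TOL:
        return (a / b) * (1.0 + 0.5 * b * u)
    return a * u / (-np.expm1(-b * u))


@njit(cache=False)
def _rhs(V, n, C, I_stim, p):
    """(dV/dt, dn/dt, dC/dt); p is the 11-vector in PARAM_FIELDS order."""
    V_i, V_k, V_l, V_c = p[0], p[1], p[2], p[3]
    g_i, g_kv, g_kc, g_l = p[4], p[5], p[6], p[7]
    lambda_n, rho, k_C = p[8], p[9], p[10]

    a_m = _ratio_rate(V + 25.0, 0.1, 0.1)
    b_m = 4.0 * np.exp(-(V + 50.0) / 18.0)
    a_h = 0.07 * np.exp(-0.05 * (V + 50.0))
    b_h = 1.0 / (1.0 + np.exp(-0.1 * (V + 20.0)))
    a_n = _ratio_rate(V + 20.0, 0.01, 0.1)
    b_n = 0.125 * np.exp(-(V + 30.0) / 80.0)

    minf = a_m / (a_m + b_m)
    hinf = a_h / (a_h + b_h)
    ninf = a_n / (a_n + b_n)
    minf3h = minf * minf * minf * hinf

    caf = C / (1.0 + C)
    dV = (
        g_i * minf3h * (V_i - V)
        + g_kv * n * n * n * n * (V_k - V)
        + g_kc * caf * (V_k - V)
        + g_l * (V_l - V)
        + I_stim
    )
    dn = (ninf - n) * lambda_n * (a_n + b_n)
    dC = rho * (minf3h * (V_c - V) - k_C * C)
    return dV, dn, dC


@njit(cache=False)
def _stim_at(t: float, s) -> float:
    """s = (kind_code, amplitude, t_on, t_off, period, pulse_len)."""
    kind = int(s[0])
    if kind == 0:
        return 0.0
    if kind == 1:
        if s[2] <= t < s[3]:
            return s[1]
        return 0.0
    if (t % s[4]) < s[5]:
        return s[1]
    return 0.0


@njit(cache=False)
def integrate_rk4(V0, n0, C0, p, s, n_steps, dt, stride, out_V, out_n, out_C, out_I):
    """Classic RK4 advance, recording every ``stride`` steps.

    Returns -1 on success, or the (1-based) step index at which |V|
    exceeded 500 mV.
    """
    V, n, C = V0, n0, C0
    out_V[0], out_n[0], out_C[0] = V, n, C
    out_I[0] = _stim_at(0.0, s)
    rec = 1
    for k in range(n_steps):
        t = k * dt
        I1 = _stim_at(t, s)
        Ih = _stim_at(t + 0.5 * dt, s)
        I2 = _stim_at(t + dt, s)

        k1V, k1n, k1C = _rhs(V, n, C, I1, p)
        k2V, k2n, k2C = _rhs(V + 0.5 * dt * k1V, n + 0.5 * dt * k1n, C + 0.5 * dt * k1C, Ih, p)
        k3V, k3n, k3C = _rhs(V + 0.5 * dt * k2V, n + 0.5 * dt * k2n, C + 0.5 * dt * k2C, Ih, p)
        k4V, k4n, k4C = _rhs(V + dt * k3V, n + dt * k3n, C + dt * k3C, I2, p)

        V += dt / 6.0 * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
        n += dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
        C += dt / 6.0 * (k1C + 2.0 * k2C + 2.0 * k3C + k4C)

        if abs(V) > 500.0 or not np.isfinite(V):
            return k + 1
        if (k + 1) % stride == 0:
            out_V[rec], out_n[rec], out_C[rec] = V, n, C
            out_I[rec] = I2
            rec += 1
    return -1
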