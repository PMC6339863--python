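"""Gating kinetics, ionic currents and the ODE right-hand side.

The membrane equation balances four currents:

    dV/dt = g_i m_inf^3 h_inf (V_i - V) + g_kv n^4 (V_k - V)
          + g_kc C/(1+C) (V_k - V) + g_l (V_l - V) + I_stim

with Hodgkin-Huxley-style rate functions for the instantaneous activation
m_inf and inactivation h_inf of the mixed Na+/Ca2+ channel and for the
relaxing K+ gate n.  The K+ gate relaxes toward n_inf with time constant
tau_n = 1 / (lambda_n (alpha_n + beta_n)), and the Ca2+ variable follows

    dC/dt = rho (m_inf^3 h_inf (V_c - V) - k_C C).

Two of the rate functions, alpha_m and alpha_n, have removable 0/0
singularities (at V = -25 mV and V = -20 mV); they are evaluated by their
analytic limit with a first-order series in a narrow window around the
singular point to avoid catastrophic cancellation.

All functions accept scalars or numpy arrays of membrane potential.
Currents use the outward-positive convention I = g * (V - V_rev), so the
membrane equation reads dV/dt = -(I_i + I_kv + I_kc + I_l) + I_stim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .params import ChayParameters, ChayState

__all__ = [
    "GateValues",
    "IonCurrents",
    "gate_rates",
    "steady_gates",
    "ionic_currents",
    "currents_from_arrays",
    "derivatives",
]

# Half-width of the series window around the removable singularities.
_SINGULAR_TOL = 1e-7


@dataclass(frozen=True)
class GateValues:
    """Transition rates and (optionally) steady-state gate values at one V."""

    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float
    m_inf: float | None = None
    h_inf: float | None = None
    n_inf: float | None = None
    tau_n: float | None = None


@dataclass(frozen=True)
class IonCurrents:
    """The four ionic currents, outward positive, in the model's nominal nA."""

    I_i: float
    I_kv: float
    I_kc: float
    I_l: float

    def total(self) -> float:
        return self.I_i + self.I_kv + self.I_kc + self.I_l


def _check_finite_V(V) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise InputError("membrane potential must be finite")
    return V


def _ratio_rate(u, a: float, b: float):
    """a*u / (1 - exp(-b*u)) with the u -> 0 limit a/b handled analytically."""
    u = np.asarray(u, dtype=float)
    near = np.abs(b * u) < _SINGULAR_TOL
    denom = -np.expm1(-b * np.where(near, 1.0, u))
    return np.where(near, (a / b) * (1.0 + 0.5 * b * u), a * u / denom)


def alpha_m(V):
    return _ratio_rate(np.asarray(V, dtype=float) + 25.0, 0.1, 0.1)


def beta_m(V):
    return 4.0 * np.exp(-(np.asarray(V, dtype=float) + 50.0) / 18.0)


def alpha_h(V):
    return 0.07 * np.exp(-0.05 * (np.asarray(V, dtype=float) + 50.0))


def beta_h(V):
    return 1.0 / (1.0 + np.exp(-0.1 * (np.asarray(V, dtype=float) + 20.0)))


def alpha_n(V):
    return _ratio_rate(np.asarray(V, dtype=float) + 20.0, 0.01, 0.1)


def beta_n(V):
    return 0.125 * np.exp(-(np.asarray(V, dtype=float) + 30.0) / 80.0)


def m_inf(V):
    a, b = alpha_m(V), beta_m(V)
    return a / (a + b)


def h_inf(V):
    a, b = alpha_h(V), beta_h(V)
    return a / (a + b)


def n_inf(V):
    a, b = alpha_n(V), beta_n(V)
    return a / (a + b)


def gate_rates(V: float) -> GateValues:
    """Evaluate the six transition rates at membrane potential V (mV)."""
    V = float(_check_finite_V(V))
    return GateValues(
        alpha_m=float(alpha_m(V)),
        beta_m=float(beta_m(V)),
        alpha_h=float(alpha_h(V)),
        beta_h=float(beta_h(V)),
        alpha_n=float(alpha_n(V)),
        beta_n=float(beta_n(V)),
    )


def steady_gates(V: float, params: ChayParameters) -> GateValues:
    """Rates plus steady-state gate values and the K+ gate time constant.

    tau_n = 1 / (lambda_n * (alpha_n + beta_n)), in seconds.
    """
    g = gate_rates(V)
    return GateValues(
        alpha_m=g.alpha_m,
        beta_m=g.beta_m,
        alpha_h=g.alpha_h,
        beta_h=g.beta_h,
        alpha_n=g.alpha_n,
        beta_n=g.beta_n,
        m_inf=g.alpha_m / (g.alpha_m + g.beta_m),
        h_inf=g.alpha_h / (g.alpha_h + g.beta_h),
        n_inf=g.alpha_n / (g.alpha_n + g.beta_n),
        tau_n=1.0 / (params.lambda_n * (g.alpha_n + g.beta_n)),
    )


def currents_from_arrays(V, n, C, params: ChayParameters):
    """Vectorized ionic currents (I_i, I_kv, I_kc, I_l), outward positive."""
    V = np.asarray(V, dtype=float)
    n = np.asarray(n, dtype=float)
    C = np.asarray(C, dtype=float)
    minf3h = m_inf(V) ** 3 * h_inf(V)
    I_i = params.g_i * minf3h * (V - params.V_i)
    I_kv = params.g_kv * n**4 * (V - params.V_k)
    I_kc = params.g_kc * (C / (1.0 + C)) * (V - params.V_k)
    I_l = params.g_l * (V - params.V_l)
    return I_i, I_kv, I_kc, I_l


def ionic_currents(state: ChayState, params: ChayParameters) -> IonCurrents:
    """The four ionic currents at one state, outward positive."""
    I_i, I_kv, I_kc, I_l = currents_from_arrays(state.V, state.n, state.C, params)
    return IonCurrents(float(I_i), float(I_kv), float(I_kc), float(I_l))


def derivatives(
    state: ChayState, I_stim: float, params: ChayParameters
) -> tuple[float, float, float]:
    """Right-hand side (dV/dt, dn/dt, dC/dt) of the model ODEs."""
    if not np.isfinite(I_stim):
        raise InputError("stimulus current must be finite")
    V, n, C = state.as_tuple()
    g = steady_gates(V, params)
    minf3h = g.m_inf**3 * g.h_inf
    dV = (
        params.g_i * minf3h * (params.V_i - V)
        + params.g_kv * n**4 * (params.V_k - V)
        + params.g_kc * (C / (1.0 + C)) * (params.V_k - V)
        + params.g_l * (params.V_l - V)
        + I_stim
    )
    dn = (g.n_inf - n) / g.tau_n
    dC = params.rho * (minf3h * (params.V_c - V) - params.k_C * C)
    return (float(dV), float(dn), float(dC))
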