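"""Instantaneous power and total energy of transmembrane potential change.

The power accounting treats the reversal potentials as voltage sources in
the membrane's equivalent circuit.  Outward K+ and leakage currents absorb
electrical potential energy from their concentration gradients, while the
inward mixed Na+/Ca2+ current releases it, so the net power is

    P = |I_kv * V_k| + |I_kc * V_k| + |I_l * V_l| - |I_i * V_i|

in nA*mV, rescaled by 1e-3 to nW (the scaling under which the model's
printed conductances, currents and ~215 nJ / 30 s totals are mutually
consistent; pass ``rescale=False`` for unit-agnostic use).  Negative P is a
net release of stored electrical potential energy, positive P a net
absorption.  The total energy over a window integrates both signs:

    E = int P_positive dt + int |P_negative| dt = int |P| dt

a proxy for the ATP consumed by the Na/K-ATPase pump to rebuild the
gradients.  Note the caveat inherent to this accounting: charge carried
simultaneously by cancelling inward and outward currents costs ATP that P
does not see, so E is a lower bound on the pump's true consumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import InputError
from .params import ChayParameters

if TYPE_CHECKING:  # pragma: no cover
    from .integrator import Trajectory
    from .model import IonCurrents

__all__ = [
    "EnergyReport",
    "instantaneous_power",
    "power_from_currents",
    "power_decompose",
    "total_energy",
    "cumulative_energy",
]

#: nA*mV -> nW rescaling of the power formula.
POWER_SCALE = 1e-3


@dataclass(frozen=True)
class EnergyReport:
    """Integrated energy quantities over a window of length T seconds.

    E_absorb integrates the positive part of P, E_release the magnitude of
    the negative part; E_total = E_absorb + E_release, all in nJ.
    """

    E_absorb: float
    E_release: float
    E_total: float
    T: float

    def to_dict(self) -> dict[str, float]:
        return {
            "E_absorb_nJ": self.E_absorb,
            "E_release_nJ": self.E_release,
            "E_total_nJ": self.E_total,
            "T_s": self.T,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv_row(self, protocol=None) -> str:
        """One-row CSV (header + values), optionally tagging the protocol."""
        d = self.to_dict()
        if protocol is not None:
            d["protocol"] = protocol.kind
            d["amplitude_nA"] = protocol.amplitude
        header = ",".join(d)
        values = ",".join(f"{v:.10g}" if isinstance(v, float) else str(v) for v in d.values())
        return f"{header}\n{values}\n"


def power_from_currents(I_i, I_kv, I_kc, I_l, params: ChayParameters, rescale: bool = True):
    """Instantaneous power from current arrays (vectorized), nW."""
    P = (
        np.abs(np.asarray(I_kv) * params.V_k)
        + np.abs(np.asarray(I_kc) * params.V_k)
        + np.abs(np.asarray(I_l) * params.V_l)
        - np.abs(np.asarray(I_i) * params.V_i)
    )
    return P * POWER_SCALE if rescale else P


def instantaneous_power(
    currents: "IonCurrents", params: ChayParameters, rescale: bool = True
) -> float:
    """Net power of electrical-potential-energy change at one instant, nW."""
    vals = (currents.I_i, currents.I_kv, currents.I_kc, currents.I_l)
    if not np.all(np.isfinite(vals)):
        raise InputError("currents must be finite")
    return float(
        power_from_currents(
            currents.I_i, currents.I_kv, currents.I_kc, currents.I_l, params, rescale
        )
    )


def power_decompose(P):
    """Split P into (P_positive, P_negative_mag), both >= 0.

    P_positive - P_negative_mag == P and P_positive + P_negative_mag == |P|
    hold exactly; at most one of the pair is nonzero at each sample.
    """
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)):
        raise InputError("power must be finite")
    pos = np.maximum(P, 0.0)
    neg = np.maximum(-P, 0.0)
    if P.ndim == 0:
        return float(pos), float(neg)
    return pos, neg


def _window_slice(traj: "Trajectory", window) -> slice:
    t = traj.t
    if window is None:
        return slice(0, t.size)
    t0, t1 = window
    if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12 or t1 <= t0:
        raise InputError(
            f"window [{t0}, {t1}] must be non-empty and lie within "
            f"[{t[0]}, {t[-1]}]"
        )
    i0 = int(np.searchsorted(t, t0 - 1e-12, side="left"))
    i1 = int(np.searchsorted(t, t1 + 1e-12, side="right"))
    if i1 - i0 < 2:
        raise InputError("window contains fewer than two samples")
    return slice(i0, i1)


def total_energy(traj: "Trajectory", window=None) -> EnergyReport:
    """Trapezoidal energy integrals of the recorded power over a window.

    ``window`` is an optional (t0, t1) pair; default is the full span.
    """
    sl = _window_slice(traj, window)
    t = traj.t[sl]
    pos, neg = power_decompose(traj.P[sl])
    E_absorb = float(np.trapezoid(pos, t))
    E_release = float(np.trapezoid(neg, t))
    return EnergyReport(
        E_absorb=E_absorb,
        E_release=E_release,
        E_total=E_absorb + E_release,
        T=float(t[-1] - t[0]),
    )


@dataclass(frozen=True)
class CumulativeEnergy:
    """Running energy integrals on the trajectory's time grid, nJ."""

    t: np.ndarray
    E_absorb: np.ndarray
    E_release: np.ndarray
    E_total: np.ndarray


def cumulative_energy(traj: "Trajectory") -> CumulativeEnergy:
    """Running E_absorb / E_release / E_total series; non-decreasing."""
    if len(traj) == 0:
        raise InputError("trajectory is empty")
    pos, neg = power_decompose(traj.P)
    Ea = cumulative_trapezoid(pos, traj.t, initial=0.0)
    Er = cumulative_trapezoid(neg, traj.t, initial=0.0)
    return CumulativeEnergy(t=traj.t, E_absorb=Ea, E_release=Er, E_total=Ea + Er)
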