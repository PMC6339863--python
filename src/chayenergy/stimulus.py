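"""Injected-current stimulus protocols.

Three protocol families are supported: no stimulus, a single rectangular
pulse over [t_on, t_off), and an intermittent train delivering the
amplitude for the first ``pulse_len`` seconds of every ``period`` seconds
(the first on-window starts at t = 0).  All windows are half-open so the
current at a switch instant is unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["StimulusProtocol", "stimulus_current", "none", "pulse", "intermittent"]

_KIND_CODES = {"none": 0, "pulse": 1, "intermittent": 2}


@dataclass(frozen=True)
class StimulusProtocol:
    """Description of a time-dependent injected current.

    kind: "none", "pulse" or "intermittent"; amplitude in nA.
    Pulse protocols are active on [t_on, t_off); intermittent protocols are
    active whenever (t mod period) < pulse_len.
    """

    kind: str = "none"
    amplitude: float = 0.0
    t_on: float = 0.0
    t_off: float = 0.0
    period: float = 0.0
    pulse_len: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise ConfigurationError(
                f"protocol kind must be one of {sorted(_KIND_CODES)}, got {self.kind!r}"
            )
        if not math.isfinite(self.amplitude):
            raise ConfigurationError("stimulus amplitude must be finite")
        if self.kind == "pulse" and not self.t_on < self.t_off:
            raise ConfigurationError(
                f"pulse protocol requires t_on < t_off (got {self.t_on}, {self.t_off})"
            )
        if self.kind == "intermittent" and not 0.0 < self.pulse_len < self.period:
            raise ConfigurationError(
                "intermittent protocol requires 0 < pulse_len < period "
                f"(got pulse_len={self.pulse_len}, period={self.period})"
            )

    def kind_code(self) -> int:
        return _KIND_CODES[self.kind]

    def as_vector(self) -> tuple[float, ...]:
        """(kind_code, amplitude, t_on, t_off, period, pulse_len) for the engine."""
        return (
            float(self.kind_code()),
            self.amplitude,
            self.t_on,
            self.t_off,
            self.period,
            self.pulse_len,
        )

    def describe(self) -> str:
        if self.kind == "none":
            return "no stimulus"
        if self.kind == "pulse":
            return f"pulse {self.amplitude:g} nA over [{self.t_on:g}, {self.t_off:g}) s"
        return (
            f"intermittent {self.amplitude:g} nA, {self.pulse_len:g} s "
            f"in every {self.period:g} s"
        )


def none() -> StimulusProtocol:
    return StimulusProtocol(kind="none")


def pulse(amplitude: float, t_on: float, t_off: float) -> StimulusProtocol:
    return StimulusProtocol(kind="pulse", amplitude=amplitude, t_on=t_on, t_off=t_off)


def intermittent(
    amplitude: float, period: float, pulse_len: float
) -> StimulusProtocol:
    return StimulusProtocol(
        kind="intermittent", amplitude=amplitude, period=period, pulse_len=pulse_len
    )


def stimulus_current(protocol: StimulusProtocol, t):
    """Injected current (nA) at time(s) t >= 0; accepts scalars or arrays."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigurationError("stimulus time must be >= 0")
    if protocol.kind == "none":
        out = np.zeros_like(t)
    elif protocol.kind == "pulse":
        out = np.where(
            (t >= protocol.t_on) & (t < protocol.t_off), protocol.amplitude, 0.0
        )
    else:
        out = np.where(
            np.mod(t, protocol.period) < protocol.pulse_len, protocol.amplitude, 0.0
        )
    return float(out) if out.ndim == 0 else out
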