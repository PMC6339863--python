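"""Model parameters for the Chay bursting-neuron model.

The model has four conductance pathways (mixed Na+/Ca2+, voltage-dependent
K+, Ca2+-dependent K+, leakage), each with a reversal potential, plus three
kinetic constants governing the K+ gate relaxation and the intracellular
Ca2+ balance.  Voltages are in mV, time in s; conductances and currents use
the model's nominal units (conductance numbers as conventionally printed for
this model, currents g*(V - V_rev) reported as "nA").
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError

__all__ = ["ChayParameters", "ChayState", "fig1_defaults", "PARAM_FIELDS"]

PARAM_FIELDS = (
    "V_i", "V_k", "V_l", "V_c",
    "g_i", "g_kv", "g_kc", "g_l",
    "lambda_n", "rho", "k_C",
)


@dataclass(frozen=True)
class ChayParameters:
    """Full parameter set of the Chay model.

    Attributes
    ----------
    V_i, V_k, V_l, V_c:
        Reversal potentials (mV) of the mixed Na+/Ca2+ channel, the K+
        channels, the leakage channel and the Ca2+ driving term.
    g_i, g_kv, g_kc, g_l:
        Maximum conductances of the four pathways (model units).
    lambda_n:
        Rate scale of the voltage-dependent K+ gate, 1/s.
    rho:
        Proportionality constant of the intracellular Ca2+ balance.
    k_C:
        Rate constant for Ca2+ efflux.
    """

    V_i: float = 100.0
    V_k: float = -75.0
    V_l: float = -40.0
    V_c: float = 100.0
    g_i: float = 1800.0
    g_kv: float = 1700.0
    g_kc: float = 11.5
    g_l: float = 7.0
    lambda_n: float = 230.0
    rho: float = 0.27
    k_C: float = 3.3 / 18.0

    def __post_init__(self) -> None:
        for name in PARAM_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ConfigurationError(f"parameter {name!r} must be finite, got {v!r}")
        for name in ("g_i", "g_kv", "g_kc", "g_l", "lambda_n", "rho", "k_C"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"parameter {name!r} must be > 0")
        if not (self.V_k < self.V_l < 0.0 < self.V_i):
            raise ConfigurationError(
                "reversal potentials must satisfy V_k < V_l < 0 < V_i "
                f"(got V_k={self.V_k}, V_l={self.V_l}, V_i={self.V_i})"
            )
        if self.V_c <= 0:
            raise ConfigurationError("V_c must be > 0")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "ChayParameters":
        unknown = set(d) - set(PARAM_FIELDS)
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ChayParameters":
        """Load a flat key/value parameter file (.json or .toml)."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib

            d = tomllib.loads(path.read_text())
        else:
            d = json.loads(path.read_text())
        return cls.from_dict(d)

    def replace(self, **kwargs) -> "ChayParameters":
        return dataclasses.replace(self, **kwargs)

    def as_vector(self) -> tuple[float, ...]:
        """Parameters in the fixed PARAM_FIELDS order (engine interface)."""
        return tuple(float(getattr(self, name)) for name in PARAM_FIELDS)


def fig1_defaults() -> ChayParameters:
    """The packaged default profile: the standard bursting parameter set.

    V_i = V_c = 100 mV, V_k = -75 mV, V_l = -40 mV; g_i = 1800,
    g_kv = 1700, g_kc = 11.5, g_l = 7; lambda_n = 230 1/s, rho = 0.27,
    k_C = 3.3/18.  This set produces second-scale bursts of spikes with the
    membrane potential confined to roughly [-55, -15] mV.
    """
    return ChayParameters()


@dataclass(frozen=True)
class ChayState:
    """Instantaneous model state.

    V: membrane potential (mV); n: opening probability of the
    voltage-dependent K+ channels; C: intracellular Ca2+ variable
    (dimensionless, enters the equations only through C/(1+C)).
    """

    V: float
    n: float
    C: float

    def __post_init__(self) -> None:
        from .errors import InputError

        if not all(math.isfinite(x) for x in (self.V, self.n, self.C)):
            raise InputError(f"state components must be finite: {self}")
        if not 0.0 <= self.n <= 1.0:
            raise InputError(f"gate variable n must lie in [0, 1], got {self.n}")
        if self.C < 0.0:
            raise InputError(f"Ca variable C must be >= 0, got {self.C}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.V, self.n, self.C)
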