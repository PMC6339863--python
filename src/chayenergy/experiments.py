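"""Drivers for the headline stimulus experiments.

Two experiment families are provided: a 10-row grid of 30 s total-energy
runs (no stimulus, plus amplitudes {-30, 40, 100} nA under each of the
three protocol families) and amplitude sweeps of E_total over -50..150 nA
for each family.  Every cell starts from the same cached attractor state so
rows are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import stimulus as stim
from .energy import EnergyReport, total_energy
from .errors import ChayError, ConfigurationError
from .integrator import DEFAULT_DT, simulate, standard_initial_state
from .params import ChayParameters, ChayState
from .stimulus import StimulusProtocol

__all__ = [
    "FAMILIES",
    "protocol_for",
    "GridRow",
    "ExperimentGridResult",
    "run_table2",
    "SweepPoint",
    "SweepResult",
    "run_sweep",
    "DEFAULT_SWEEP_AMPLITUDES",
]

log = logging.getLogger(__name__)

#: Protocol families of the stimulus experiments.
FAMILIES = ("none", "pulse_1s", "pulse_5s", "intermittent")

GRID_AMPLITUDES = (-30.0, 40.0, 100.0)
DEFAULT_SWEEP_AMPLITUDES = tuple(float(a) for a in range(-50, 151, 10))
DEFAULT_DURATION = 30.0


def protocol_for(family: str, amplitude: float) -> StimulusProtocol:
    """Build the protocol of a family: 1 s pulse, 5 s pulse, or 1 s per 5 s."""
    if family == "none" or amplitude == 0.0:
        return stim.none()
    if family == "pulse_1s":
        return stim.pulse(amplitude, 0.0, 1.0)
    if family == "pulse_5s":
        return stim.pulse(amplitude, 0.0, 5.0)
    if family == "intermittent":
        return stim.intermittent(amplitude, period=5.0, pulse_len=1.0)
    raise ConfigurationError(f"unknown protocol family {family!r}; use one of {FAMILIES}")


def _run_energy(
    params: ChayParameters,
    family: str,
    amplitude: float,
    duration: float,
    dt: float,
    init: ChayState,
) -> EnergyReport:
    protocol = protocol_for(family, amplitude)
    traj = simulate(params, protocol, duration=duration, dt=dt, init=init)
    report = total_energy(traj)
    log.info(
        "%s | dt=%g s | E_absorb=%.4f E_release=%.4f E_total=%.4f nJ",
        protocol.describe(), dt, report.E_absorb, report.E_release, report.E_total,
    )
    return report


@dataclass
class GridRow:
    family: str
    amplitude: float
    report: EnergyReport | None
    error: str | None = None


@dataclass
class ExperimentGridResult:
    """Rows of the total-energy grid, one per (family, amplitude) pair."""

    rows: list[GridRow] = field(default_factory=list)

    def lookup(self, family: str, amplitude: float) -> EnergyReport:
        for r in self.rows:
            if r.family == family and r.amplitude == amplitude:
                if r.report is None:
                    raise ChayError(f"grid cell ({family}, {amplitude}) failed: {r.error}")
                return r.report
        raise KeyError(f"no grid cell ({family}, {amplitude})")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "family": r.family,
                    "amplitude_nA": r.amplitude,
                    **(r.report.to_dict() if r.report else {}),
                    "error": r.error,
                }
                for r in self.rows
            ]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_table2(
    params: ChayParameters | None = None,
    dt: float = DEFAULT_DT,
    duration: float = DEFAULT_DURATION,
    init: ChayState | None = None,
) -> ExperimentGridResult:
    """The 10-cell total-energy grid over the three protocol families.

    Each cell is a fresh ``duration``-second run from the cached attractor
    state.  Failures in one cell are recorded and do not stop the grid.
    """
    params = params or ChayParameters()
    init = init or standard_initial_state(params)
    cells = [("none", 0.0)] + [
        (fam, amp) for fam in ("pulse_1s", "pulse_5s", "intermittent")
        for amp in GRID_AMPLITUDES
    ]
    result = ExperimentGridResult()
    for family, amplitude in cells:
        try:
            report = _run_energy(params, family, amplitude, duration, dt, init)
            result.rows.append(GridRow(family, amplitude, report))
        except ChayError as exc:  # keep going; record the failure
            log.warning("grid cell (%s, %g) failed: %s", family, amplitude, exc)
            result.rows.append(GridRow(family, amplitude, None, error=str(exc)))
    return result


@dataclass
class SweepPoint:
    amplitude: float
    E_total: float | None
    error: str | None = None


@dataclass
class SweepResult:
    """E_total as a function of stimulus amplitude for one protocol family."""

    family: str
    points: list[SweepPoint] = field(default_factory=list)

    def amplitudes(self):
        return [p.amplitude for p in self.points if p.E_total is not None]

    def energies(self):
        return [p.E_total for p in self.points if p.E_total is not None]

    def max_energy(self) -> float:
        return max(self.energies())

    def min_energy(self) -> float:
        return min(self.energies())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"family": self.family, "amplitude_nA": p.amplitude,
                 "E_total_nJ": p.E_total, "error": p.error}
                for p in self.points
            ]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_sweep(
    family: str,
    amplitudes=DEFAULT_SWEEP_AMPLITUDES,
    params: ChayParameters | None = None,
    dt: float = DEFAULT_DT,
    duration: float = DEFAULT_DURATION,
    init: ChayState | None = None,
) -> SweepResult:
    """E_total(amplitude) for one family; one 30 s run per amplitude."""
    amplitudes = list(amplitudes)
    if not amplitudes:
        raise ConfigurationError("amplitude list must be nonempty")
    params = params or ChayParameters()
    init = init or standard_initial_state(params)
    result = SweepResult(family=family)
    for amp in amplitudes:
        try:
            report = _run_energy(params, family, float(amp), duration, dt, init)
            result.points.append(SweepPoint(float(amp), report.E_total))
        except ChayError as exc:
            log.warning("sweep point (%s, %g) failed: %s", family, amp, exc)
            result.points.append(SweepPoint(float(amp), None, error=str(exc)))
    return result
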