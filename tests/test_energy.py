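"""Power formula, sign decomposition, quadrature and energy identities."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chayenergy import (
    InputError,
    cumulative_energy,
    instantaneous_power,
    power_decompose,
    total_energy,
)
from chayenergy.model import IonCurrents


def _power_only_trajectory(t, P):
    """Minimal trajectory stand-in for quadrature tests (synthetic)."""
    from chayenergy.integrator import Trajectory

    z = np.zeros_like(t)
    return Trajectory(
        t=t, V=z, n=z, C=z, I_stim=z, I_i=z, I_kv=z, I_kc=z, I_l=z,
        P=np.asarray(P, dtype=float), record_dt=float(t[1] - t[0]),
    )


def test_zero_currents_zero_power(params):
    assert instantaneous_power(IonCurrents(0, 0, 0, 0), params) == 0.0


def test_single_term_power_rescaling(params):
    # I_kv = 1000 against V_k = -75 gives 75000 nA*mV = 75 nW
    assert instantaneous_power(IonCurrents(0, 1000.0, 0, 0), params) == pytest.approx(75.0)
    # rescaling can be switched off for unit-agnostic use
    assert instantaneous_power(
        IonCurrents(0, 1000.0, 0, 0), params, rescale=False
    ) == pytest.approx(75000.0)


def test_power_at_tabulated_peak_currents(params):
    """The tabulated point-C currents give P = -48.7745 nW (net release)."""
    P = instantaneous_power(IonCurrents(-1619.0, 1249.0, 182.7, 143.7), params)
    assert P == pytest.approx(-48.7745, abs=1e-6)
    assert P < 0.0


@pytest.mark.parametrize("P, expected", [(5.0, (5.0, 0.0)), (-3.0, (0.0, 3.0)), (0.0, (0.0, 0.0))])
def test_power_decompose_scalars(P, expected):
    assert power_decompose(P) == expected


@given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=1, max_size=50))
def test_power_decompose_identities(values):
    P = np.asarray(values)
    pos, neg = power_decompose(P)
    assert np.all(pos >= 0.0) and np.all(neg >= 0.0)
    np.testing.assert_allclose(pos - neg, P, atol=0.0)
    np.testing.assert_allclose(pos + neg, np.abs(P), atol=0.0)
    assert not np.any((pos > 0) & (neg > 0))


def test_constant_power_energy():
    t = np.linspace(0.0, 10.0, 1001)
    rep = total_energy(_power_only_trajectory(t, np.full_like(t, 2.0)))
    assert rep.E_total == pytest.approx(20.0)
    assert rep.E_absorb == pytest.approx(20.0)
    assert rep.E_release == 0.0


def test_sine_power_against_closed_form():
    """Quadrature of sin(2 pi t) over [0,1] at 1e-4 s sampling: 1/pi each way."""
    t = np.arange(0.0, 1.0 + 1e-4, 1e-4)
    rep = total_energy(_power_only_trajectory(t, np.sin(2 * np.pi * t)))
    assert rep.E_absorb == pytest.approx(1.0 / np.pi, abs=1e-6)
    assert rep.E_release == pytest.approx(1.0 / np.pi, abs=1e-6)


def test_energy_additivity_and_report_identity(spont_traj):
    full = total_energy(spont_traj)
    first = total_energy(spont_traj, (0.0, 15.0))
    second = total_energy(spont_traj, (15.0, 30.0))
    assert full.E_total == pytest.approx(first.E_total + second.E_total, rel=1e-12)
    assert full.E_total == full.E_absorb + full.E_release  # exact by construction


def test_empty_window_rejected(spont_traj):
    with pytest.raises(InputError):
        total_energy(spont_traj, (10.0, 10.0))
    with pytest.raises(InputError):
        total_energy(spont_traj, (0.0, 31.0))


def test_cumulative_energy_consistency(spont_traj):
    cum = cumulative_energy(spont_traj)
    rep = total_energy(spont_traj)
    assert cum.E_total[-1] == pytest.approx(rep.E_total, rel=1e-12)
    assert cum.E_absorb[-1] == pytest.approx(rep.E_absorb, rel=1e-12)
    for series in (cum.E_absorb, cum.E_release, cum.E_total):
        assert np.all(np.diff(series) >= 0.0)
    # zero-power trajectory integrates to an all-zero series
    t = np.linspace(0.0, 1.0, 101)
    zero = cumulative_energy(_power_only_trajectory(t, np.zeros_like(t)))
    assert np.all(zero.E_total == 0.0)


def test_resting_stage_power_is_small(spont_traj):
    """On the resting plateau preceding each depolarization onset, P is
    positive but below 5% of the peak |P| of the cycle."""
    from chayenergy import annotate_phases

    ann = annotate_phases(spont_traj)
    peak_absP = np.max(np.abs(spont_traj.P))
    checked = 0
    for s in ann.spikes:
        if not s.complete:
            continue
        i1 = spont_traj.index_at_time(s.t_B)
        i0 = i1 - int(round(0.05 / spont_traj.record_dt))
        if i0 < 0:
            continue
        plateau_P = spont_traj.P[i0:i1]
        assert np.all(plateau_P > 0.0)
        assert np.max(np.abs(plateau_P)) < 0.05 * peak_absP
        checked += 1
    assert checked > 10


def test_report_serialization(tmp_path, spont_traj):
    import json

    rep = total_energy(spont_traj)
    path = tmp_path / "report.json"
    rep.to_json(path)
    d = json.loads(path.read_text())
    assert d["E_total_nJ"] == pytest.approx(rep.E_total)
    csv = rep.to_csv_row(spont_traj.protocol)
    header, values = csv.strip().splitlines()
    assert header.split(",")[:4] == ["E_absorb_nJ", "E_release_nJ", "E_total_nJ", "T_s"]
    assert len(values.split(",")) == len(header.split(","))
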