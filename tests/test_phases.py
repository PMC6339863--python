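"""Spike detection, burst segmentation and the B-C-D-E landmark analysis."""

import numpy as np
import pytest

from chayenergy import (
    InputError,
    annotate_phases,
    currents_at_peak,
    detect_spikes,
    first_spike_of_steady_burst,
    peak_to_power_zero_delay,
    segment_bursts,
)
from chayenergy.integrator import Trajectory
from chayenergy.params import ChayParameters


def _synthetic_trajectory(t, V, P=None):
    """Hand-built trace for detector tests (synthetic stand-in)."""
    z = np.zeros_like(t)
    return Trajectory(
        t=t, V=np.asarray(V, float), n=z, C=z, I_stim=z,
        I_i=z, I_kv=z, I_kc=z, I_l=z,
        P=z if P is None else np.asarray(P, float),
        record_dt=float(t[1] - t[0]),
    )


def test_flat_trace_has_no_spikes():
    t = np.arange(0.0, 1.0, 1e-4)
    traj = _synthetic_trajectory(t, np.full_like(t, -48.0))
    assert detect_spikes(traj).size == 0


def test_three_bumps_detected_at_constructed_times():
    t = np.arange(0.0, 3.0, 1e-4)
    V = np.full_like(t, -48.0)
    centers = (0.5, 1.5, 2.5)
    for c in centers:
        V += 30.0 * np.exp(-((t - c) ** 2) / (2 * 0.01**2))
    traj = _synthetic_trajectory(t, V)
    peaks = detect_spikes(traj)
    assert peaks == pytest.approx(centers, abs=2e-4)


@pytest.mark.parametrize(
    "peaks, gap, expected",
    [
        ([1.0, 1.1, 1.2, 3.0, 3.1], 0.5, [(1.0, 1.2), (3.0, 3.1)]),
        ([2.0], 0.5, [(2.0, 2.0)]),
        ([], 0.5, []),
    ],
)
def test_segment_bursts(peaks, gap, expected):
    assert segment_bursts(np.asarray(peaks), gap) == expected


def test_constructed_peak_to_power_zero_delay():
    t = np.arange(0.0, 1.0, 1e-4)
    V = np.full_like(t, -48.0) + 30.0 * np.exp(-((t - 0.3) ** 2) / (2 * 0.01**2))
    P = np.where(t >= 0.31, 1.0, -1.0)  # crosses zero 0.01 s after the peak
    traj = _synthetic_trajectory(t, V, P)
    peaks = detect_spikes(traj)
    assert peak_to_power_zero_delay(traj, peaks, 0) == pytest.approx(0.01, abs=2e-4)
    with pytest.raises(InputError):
        peak_to_power_zero_delay(traj, peaks, 5)


def test_no_zero_crossing_raises():
    t = np.arange(0.0, 1.0, 1e-4)
    V = np.full_like(t, -48.0) + 30.0 * np.exp(-((t - 0.3) ** 2) / (2 * 0.01**2))
    traj = _synthetic_trajectory(t, V, np.full_like(t, -1.0))
    peaks = detect_spikes(traj)
    with pytest.raises(InputError):
        peak_to_power_zero_delay(traj, peaks, 0)


# ---- spontaneous-run analyses ---------------------------------------------


def test_detected_peaks_below_minus_15(spont_traj):
    peaks = detect_spikes(spont_traj)
    idx = [spont_traj.index_at_time(t) for t in peaks]
    assert peaks.size > 10
    assert np.all(spont_traj.V[idx] <= -15.0)


def test_landmark_ordering_and_tiling(spont_traj):
    ann = annotate_phases(spont_traj)
    complete = [s for s in ann.spikes if s.complete]
    assert len(complete) > 10
    for s in complete:
        assert s.t_B < s.t_C < s.t_D < s.t_E
    # steady-state bursts all carry the same number of spikes
    counts = {len(b.spike_ids) for b in ann.bursts[1:-1]}
    assert len(counts) == 1


def test_power_negative_through_upstroke(spont_traj):
    """P turns negative at depolarization onset B and stays negative
    through the whole upstroke, recrossing zero only after the V peak."""
    ann = annotate_phases(spont_traj)
    for s in ann.spikes:
        if not s.complete:
            continue
        i_B = spont_traj.index_at_time(s.t_B)
        i_C = spont_traj.index_at_time(s.t_C)
        neg = np.nonzero(spont_traj.P[i_B:] < 0.0)[0]
        assert neg.size > 0
        j = i_B + neg[0]
        assert j < i_C  # the sign flip happens during the depolarization stage
        cross = j + np.nonzero(spont_traj.P[j:] >= 0.0)[0][0]
        assert np.all(spont_traj.P[j:cross] < 0.0)
        assert cross > i_C  # zero-crossing comes after the peak


def test_hyperpolarization_only_after_final_spike(spont_traj):
    ann = annotate_phases(spont_traj)
    steady = ann.bursts[1:-1]
    assert all(b.hyperpolarized for b in steady)
    # between intra-burst spikes the dip stays within the margin of the plateau
    for b in steady:
        for s0, s1 in zip(b.spike_ids[:-1], b.spike_ids[1:]):
            i0 = spont_traj.index_at_time(ann.spikes[s0].t_C)
            i1 = spont_traj.index_at_time(ann.spikes[s1].t_C)
            assert spont_traj.V[i0:i1].min() >= b.plateau_V - 1.0


def test_currents_at_peak_definitions(fine_traj):
    peaks = detect_spikes(fine_traj)
    ann = annotate_phases(fine_traj)
    s = first_spike_of_steady_burst(ann)
    cur, P = currents_at_peak(fine_traj, peaks, s)
    i = fine_traj.index_at_time(peaks[s])
    p = fine_traj.params
    # leakage current follows its definition exactly
    assert cur.I_l == pytest.approx(p.g_l * (fine_traj.V[i] - p.V_l), rel=1e-12)
    # net release at the peak, inward marginally above outward
    assert P < 0.0
    assert abs(cur.I_i) > cur.I_kv + cur.I_kc + cur.I_l
    with pytest.raises(InputError):
        currents_at_peak(fine_traj, peaks, peaks.size)


def test_steady_burst_delay_near_6ms(spont_traj):
    peaks = detect_spikes(spont_traj)
    ann = annotate_phases(spont_traj)
    s = first_spike_of_steady_burst(ann)
    delay = peak_to_power_zero_delay(spont_traj, peaks, s)
    assert 0.0 <= delay < 0.02


def test_annotation_csv_writer(tmp_path, spont_traj):
    import pandas as pd

    ann = annotate_phases(spont_traj)
    sp, bp = tmp_path / "spikes.csv", tmp_path / "bursts.csv"
    ann.write_csv(sp, bp, spont_traj)
    spikes = pd.read_csv(sp)
    bursts = pd.read_csv(bp)
    assert {"burst_id", "spike_id", "t_B", "t_C", "t_D", "t_E", "V_peak",
            "I_i", "I_kv", "I_kc", "I_l", "P_at_C"} <= set(spikes.columns)
    assert {"burst_id", "hyperpolarized", "v_min"} <= set(bursts.columns)
    assert len(spikes) == len(ann.spikes)
    assert len(bursts) == len(ann.bursts)


def test_truncated_spike_flagged():
    """A spike whose power never settles back to zero before the record
    ends is annotated partially."""
    t = np.arange(0.0, 0.305, 1e-4)
    V = np.full_like(t, -48.0) + 30.0 * np.exp(-((t - 0.3) ** 2) / (2 * 0.01**2))
    traj = _synthetic_trajectory(t, V, np.full_like(t, 5.0))
    ann = annotate_phases(traj)
    assert len(ann.spikes) == 1
    assert not ann.spikes[0].complete
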