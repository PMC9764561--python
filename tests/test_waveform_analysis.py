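"""Feature extraction and discharge-class rules."""

import numpy as np
import pytest

from memtc import (ClassifierThresholds, StateKind, StateLabel,
                   classify_state, classify_trajectory, dominant_frequency,
                   local_extrema, spikes_per_period)
from memtc.integrator import Trajectory
from memtc.synthetic_waveforms import WaveformSpec, generate_waveform
from memtc.waveform_analysis import analyze_trajectory, slow_wave_split


def _trace(y, dt=1e-3, cutoff=0.0):
    y = np.asarray(y, dtype=float)
    return Trajectory(np.arange(len(y)) * dt, y[:, None], dt, 1,
                      transient_cutoff=cutoff, channels=("PY1",))


def _sine(freq, duration=10.0, amp=1.0, dt=1e-3, phase=0.0, offset=0.0):
    t = np.arange(int(duration / dt) + 1) * dt
    return _trace(offset + amp * np.sin(2 * np.pi * freq * t + phase), dt)


def test_constant_trace_has_no_extrema_and_zero_frequency():
    traj = _trace(np.full(10001, 0.3))
    maxima, minima = local_extrema(traj, "PY1")
    assert len(maxima) == 0 and len(minima) == 0
    assert dominant_frequency(traj, "PY1") == 0.0


def test_sine_extrema_and_frequency():
    traj = _sine(5.0)
    maxima, minima = local_extrema(traj, "PY1")
    assert np.allclose(maxima, 1.0, atol=1e-3)
    assert np.allclose(minima, -1.0, atol=1e-3)
    f = dominant_frequency(traj, "PY1")
    assert f == pytest.approx(5.0, abs=0.125)
    assert spikes_per_period(traj, "PY1", f) == 1


def test_unknown_channel_and_short_segment_errors():
    traj = _sine(5.0)
    with pytest.raises(KeyError):
        local_extrema(traj, "nope")
    short = _sine(5.0, duration=4.0)
    with pytest.raises(ValueError):
        dominant_frequency(short, "PY1")
    with pytest.raises(ValueError):
        spikes_per_period(traj, "PY1", 0.0)


@pytest.mark.parametrize("n", [1, 2, 3, 4])
def test_swd_template_spike_count_and_label(n):
    spec = WaveformSpec(StateLabel.swd(n), fundamental_freq=2.5, n_spikes=n)
    traj, _ = generate_waveform(spec)
    f = dominant_frequency(traj, "PY1")
    assert f == pytest.approx(2.5, abs=0.125)
    assert spikes_per_period(traj, "PY1", f) == n
    label, _ = classify_trajectory(traj)
    assert label == StateLabel.swd(n)


def test_two_spike_template_recovers_two_distinct_maxima():
    spec = WaveformSpec(StateLabel.swd(2), fundamental_freq=3.0, n_spikes=2,
                        wave_amplitude=0.5, spike_amplitude=1.0)
    traj, _ = generate_waveform(spec)
    maxima, _ = local_extrema(traj, "PY1")
    # spike maxima near 1.0 and wave maxima near 0.5, both present
    assert (maxima > 0.75).any() and (maxima < 0.75).any()


@pytest.mark.parametrize("freq, kind", [
    (15.0, StateKind.TONIC),
    (5.0, StateKind.CLONIC),
    (2.5, StateKind.SLOW_WAVE),
])
def test_simple_oscillation_bands(freq, kind):
    label, _ = classify_trajectory(_sine(freq))
    assert label.kind is kind


@pytest.mark.parametrize("level, kind", [
    (-0.3, StateKind.LOW_SATURATED),
    (0.17, StateKind.LOW_SATURATED),
    (0.38, StateKind.HIGH_SATURATED),
    (0.9, StateKind.HIGH_SATURATED),
])
def test_saturated_levels(level, kind, rng):
    y = level + rng.normal(0, 1e-5, 12001)
    label, _ = classify_trajectory(_trace(y))
    assert label.kind is kind


def test_label_invariant_to_time_shift():
    a, _ = classify_trajectory(_sine(5.0, phase=0.0))
    b, _ = classify_trajectory(_sine(5.0, phase=2.1))
    assert a == b


@pytest.mark.parametrize("stride", [10, 20, 40])
def test_label_invariant_to_record_stride(default_params, stride):
    from memtc import settle_to_attractor

    traj = settle_to_attractor(default_params.replace(k7=2.0),
                               record_stride=stride)
    label, feats = classify_trajectory(traj)
    assert label == StateLabel.swd(1)
    assert feats.dominant_freq == pytest.approx(2.8, abs=0.15)


def test_slow_wave_split_rule():
    assert slow_wave_split(np.array([0.3, 0.3, 0.9, 0.9]), amplitude=1.0)
    assert not slow_wave_split(np.array([0.5, 0.5001, 0.4999, 0.5]), amplitude=1.0)
    assert not slow_wave_split(np.array([0.5]), amplitude=1.0)


def test_swd_labels_from_model(swd_trajectory):
    """The k7 = 2 discharge is a classic one-spike SWD in the 2-4 Hz band."""
    label, feats = classify_trajectory(swd_trajectory)
    assert label == StateLabel.swd(1)
    assert 2.0 <= feats.dominant_freq <= 4.0
    assert feats.slow_wave_flag


def test_tonic_label_from_model(tonic_trajectory):
    label, feats = classify_trajectory(tonic_trajectory)
    assert label.kind is StateKind.TONIC
    assert feats.dominant_freq > 10


def test_classifier_threshold_override():
    """Band edges are configurable: moving the tonic edge reclassifies."""
    th = ClassifierThresholds(theta_tonic=4.0)
    traj = _sine(5.0)
    feats = analyze_trajectory(traj, "PY1", th)
    assert classify_state(feats, th).kind is StateKind.TONIC


def test_n_swd_label_validation():
    with pytest.raises(ValueError):
        StateLabel(StateKind.N_SWD, 1)
    assert StateLabel.swd(3).n_spikes == 3
    assert str(StateLabel.swd(3)) == "3-SWD"
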