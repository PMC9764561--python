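"""Post-transient waveform features and discharge-state classification.

The sweep diagrams characterize each parameter point by the extreme
values of the pyramidal signal together with its dominant frequency; the
classifier turns those features into one of the discharge classes seen in
this family of models:

* ``LOW_SATURATED`` / ``HIGH_SATURATED`` — steady (fixed-point) responses
  at a low / high pyramidal level;
* ``SWD`` — spike-and-wave discharge, one spike maximum riding a slow
  wave per period (the 2–4 Hz absence-seizure rhythm);
* ``N_SWD`` — poly-spike variant with n >= 2 spikes per period;
* ``TONIC`` (>= ~10 Hz), ``CLONIC`` (~5 Hz) and ``SLOW_WAVE`` (<= ~3 Hz)
  simple oscillations;
* ``UNCLASSIFIED`` fallback when the rules conflict.

The class boundaries are operational choices (the waveform taxonomy is
qualitative in the literature); every threshold lives in
:class:`ClassifierThresholds` and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .integrator import Trajectory

__all__ = [
    "StateKind",
    "StateLabel",
    "ClassifierThresholds",
    "WaveformFeatures",
    "local_extrema",
    "dominant_frequency",
    "spikes_per_period",
    "slow_wave_split",
    "analyze_trajectory",
    "classify_state",
    "classify_trajectory",
]


class StateKind(Enum):
    LOW_SATURATED = "low_saturated"
    HIGH_SATURATED = "high_saturated"
    SWD = "swd"
    N_SWD = "n_swd"
    TONIC = "tonic"
    CLONIC = "clonic"
    SLOW_WAVE = "slow_wave"
    UNCLASSIFIED = "unclassified"
    DIVERGENT = "divergent"


@dataclass(frozen=True)
class StateLabel:
    """Discharge class; ``n_spikes`` >= 2 only for the poly-spike family."""

    kind: StateKind
    n_spikes: int = 0

    def __post_init__(self):
        if self.kind is StateKind.N_SWD and self.n_spikes < 2:
            raise ValueError("N_SWD requires n_spikes >= 2")

    @classmethod
    def swd(cls, n: int) -> "StateLabel":
        if n <= 0:
            raise ValueError("spike count must be positive")
        return cls(StateKind.SWD, 1) if n == 1 else cls(StateKind.N_SWD, n)

    def __str__(self) -> str:
        if self.kind is StateKind.N_SWD:
            return f"{self.n_spikes}-SWD"
        return self.kind.name


@dataclass(frozen=True)
class ClassifierThresholds:
    """Numeric rules behind the qualitative state taxonomy.

    delta_amp      steady-vs-oscillatory amplitude floor
    theta_sat      low/high saturated split on the mean pyramidal level;
                   the model's saturated plateaus at default parameters sit
                   near 0.17 (low) and 0.38 (high), so the split is their
                   midpoint
    theta_tonic    lower frequency edge of the tonic band (Hz)
    theta_slow     upper frequency edge of the slow-wave band (Hz)
    delta_prom     peak-prominence floor, as a fraction of amplitude
    delta_pow      AC-power floor below which dominant frequency is 0
    split_gap      spike/wave separation accepted when the gap between the
                   two maxima clusters exceeds this fraction of amplitude
    """

    delta_amp: float = 1e-3
    theta_sat: float = 0.28
    theta_tonic: float = 10.0
    theta_slow: float = 3.5
    delta_prom: float = 0.01
    delta_pow: float = 1e-8
    split_gap: float = 0.1


DEFAULT_THRESHOLDS = ClassifierThresholds()


@dataclass
class WaveformFeatures:
    local_maxima: np.ndarray
    local_minima: np.ndarray
    amplitude: float
    mean_level: float
    dominant_freq: float
    spikes_per_period: int
    slow_wave_flag: bool = False
    periodic_stable: bool = True

    def __post_init__(self):
        if self.amplitude < 0 or self.dominant_freq < 0:
            raise ValueError("amplitude and dominant_freq must be non-negative")


def _post_transient(traj: Trajectory, channel: str, min_span: float):
    t, y = traj.post_transient(channel)
    if t[-1] - t[0] < min_span:
        raise ValueError(
            f"need >= {min_span} s of post-transient signal, have {t[-1] - t[0]:.3g} s")
    return t, y


def _peak_indices(y: np.ndarray, thresholds: ClassifierThresholds):
    amp = float(y.max() - y.min())
    if amp < thresholds.delta_amp:
        empty = np.array([], dtype=int)
        return empty, empty, amp
    # robust noise floor: for smooth traces the median successive
    # difference is tiny, for noisy ones it estimates the noise scale, so
    # measurement ripple never registers as discharge spikes
    sigma = float(np.median(np.abs(np.diff(y)))) / 0.9539
    prom = max(thresholds.delta_prom * amp, 5.0 * sigma)
    imax, _ = find_peaks(y, prominence=prom)
    imin, _ = find_peaks(-y, prominence=prom)
    return imax, imin, amp


def local_extrema(traj: Trajectory, channel: str,
                  thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS):
    """Interior local maxima/minima values of the post-transient signal.

    Extrema are filtered by a prominence floor so that numerical ripple on
    a steady trace does not register; a steady trace yields two empty lists.
    """
    _, y = _post_transient(traj, channel, 2.0)
    imax, imin, _ = _peak_indices(y, thresholds)
    return y[imax], y[imin]


def dominant_frequency(traj: Trajectory, channel: str,
                       thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> float:
    """Largest non-DC peak of the Hann-windowed spectrum, in Hz.

    Returns 0 for signals whose AC power is below the power floor
    (steady responses).  Requires >= 8 s so the FFT bin is <= 0.125 Hz.
    """
    t, y = _post_transient(traj, channel, 8.0)
    y = y - y.mean()
    if float(np.mean(y ** 2)) < thresholds.delta_pow:
        return 0.0
    w = np.hanning(len(y))
    spectrum = np.abs(np.fft.rfft(y * w))
    freqs = np.fft.rfftfreq(len(y), t[1] - t[0])
    return float(freqs[1:][np.argmax(spectrum[1:])])


def slow_wave_split(maxima: np.ndarray, amplitude: float,
                    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Detect a distinct slow-wave maximum among the per-period maxima.

    Two-cluster split of the maxima values (optimal 1-D two-means);
    accepted when the cluster-mean gap exceeds ``split_gap * amplitude``.
    """
    v = np.sort(np.asarray(maxima, dtype=float))
    if len(v) < 2 or amplitude <= 0:
        return False
    best_gap = 0.0
    best_sse = np.inf
    for i in range(1, len(v)):
        lo, hi = v[:i], v[i:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse:
            best_sse = sse
            best_gap = hi.mean() - lo.mean()
    return bool(best_gap > thresholds.split_gap * amplitude)


def _per_period_counts(t: np.ndarray, peak_times: np.ndarray, freq: float) -> np.ndarray:
    period = 1.0 / freq
    n_full = int(np.floor((t[-1] - t[0]) / period))
    counts = []
    for j in range(n_full):
        lo = t[0] + j * period
        counts.append(int(np.sum((peak_times >= lo) & (peak_times < lo + period))))
    return np.asarray(counts, dtype=int)


def spikes_per_period(traj: Trajectory, channel: str, dominant_freq: float,
                      thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
                      with_stability: bool = False):
    """Spike maxima per fundamental period.

    Counts prominent local maxima in each complete fundamental period and
    takes the modal count M; when the maxima values split into a spike
    cluster and a distinct slow-wave cluster, the wave maximum is excluded
    (M - 1).  For an aperiodic segment the modal count is still returned,
    flagged unstable when ``with_stability`` is requested.
    """
    if dominant_freq <= 0:
        raise ValueError("dominant_freq must be positive")
    t, y = _post_transient(traj, channel, 2.0)
    imax, _, amp = _peak_indices(y, thresholds)
    if len(imax) == 0:
        return (0, True) if with_stability else 0
    counts = _per_period_counts(t, t[imax], dominant_freq)
    if len(counts) == 0:
        return (0, False) if with_stability else 0
    vals, freq_counts = np.unique(counts, return_counts=True)
    modal = int(vals[np.argmax(freq_counts)])
    stable = bool(np.all(counts == modal))
    n = modal - 1 if slow_wave_split(y[imax], amp, thresholds) and modal >= 2 else modal
    return (n, stable) if with_stability else n


def analyze_trajectory(traj: Trajectory, channel: str = "PY1",
                       thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS
                       ) -> WaveformFeatures:
    """Full feature record for one channel of a settled trajectory."""
    t, y = _post_transient(traj, channel, 8.0)
    imax, imin, amp = _peak_indices(y, thresholds)
    freq = dominant_frequency(traj, channel, thresholds)
    slow_flag = False
    spikes = 0
    stable = True
    if freq > 0 and len(imax) > 0:
        counts = _per_period_counts(t, t[imax], freq)
        modal = 0
        if len(counts):
            vals, freq_counts = np.unique(counts, return_counts=True)
            modal = int(vals[np.argmax(freq_counts)])
        # a slow-wave maximum only makes sense alongside at least one spike
        slow_flag = modal >= 2 and slow_wave_split(y[imax], amp, thresholds)
        spikes, stable = spikes_per_period(traj, channel, freq, thresholds,
                                           with_stability=True)
    return WaveformFeatures(
        local_maxima=y[imax],
        local_minima=y[imin],
        amplitude=amp,
        mean_level=float(y.mean()),
        dominant_freq=freq,
        spikes_per_period=spikes,
        slow_wave_flag=slow_flag,
        periodic_stable=stable,
    )


def classify_state(features: WaveformFeatures,
                   thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> StateLabel:
    """Rule cascade from features to a discharge class."""
    th = thresholds
    if features.amplitude < th.delta_amp:
        if features.mean_level < th.theta_sat:
            return StateLabel(StateKind.LOW_SATURATED)
        return StateLabel(StateKind.HIGH_SATURATED)
    f = features.dominant_freq
    if f <= 0:
        return StateLabel(StateKind.UNCLASSIFIED)
    if features.slow_wave_flag:
        if features.spikes_per_period >= 1:
            return StateLabel.swd(features.spikes_per_period)
        return StateLabel(StateKind.UNCLASSIFIED)
    if f >= th.theta_tonic:
        return StateLabel(StateKind.TONIC)
    if f > th.theta_slow:
        return StateLabel(StateKind.CLONIC)
    return StateLabel(StateKind.SLOW_WAVE)


def classify_trajectory(traj: Trajectory, channel: str = "PY1",
                        thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS
                        ) -> Tuple[StateLabel, WaveformFeatures]:
    feats = analyze_trajectory(traj, channel, thresholds)
    return classify_state(feats, thresholds), feats
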