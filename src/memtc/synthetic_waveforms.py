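"""Labeled surrogate waveforms for testing the feature extractors and the
discharge classifier independently of the model dynamics.

Morphologies (deliberately simple — surrogates, not biophysics):

* spike-and-wave family: per period, one slow half-sine "wave" followed
  by n narrow Gaussian "spikes" (n = 1 is the classic SWD);
* tonic / clonic / slow-wave: single sinusoids at class frequencies;
* saturated classes: constant baseline.

All randomness comes from one seeded generator per waveform, so every
surrogate is bit-reproducible from its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .integrator import Trajectory
from .waveform_analysis import StateKind, StateLabel

__all__ = ["WaveformSpec", "SuiteItem", "generate_waveform",
           "generate_test_suite", "DEFAULT_CLASS_SPECS"]

# frequency bands consistent with the discharge-class taxonomy (Hz)
_BANDS = {
    StateKind.SWD: (1.5, 4.5),
    StateKind.N_SWD: (1.5, 4.5),
    StateKind.TONIC: (10.0, 30.0),
    StateKind.CLONIC: (3.5, 10.0),
    StateKind.SLOW_WAVE: (0.1, 3.5),
}
_STEADY = (StateKind.LOW_SATURATED, StateKind.HIGH_SATURATED)


@dataclass(frozen=True)
class WaveformSpec:
    label: StateLabel
    fundamental_freq: float = 0.0      # Hz; 0 for steady classes
    n_spikes: int = 1                  # SWD family only
    spike_width: Optional[float] = None  # Gaussian sigma (s); default 0.005/f
    wave_amplitude: float = 0.5
    spike_amplitude: float = 1.0
    baseline: float = 0.0
    noise_sd: float = 0.0
    duration: float = 12.0             # s
    seed: int = 0

    @property
    def effective_spike_width(self) -> float:
        """Narrow spikes (sigma = 0.5% of the period by default) keep the
        spectral peak at the fundamental rather than at the spike comb."""
        if self.spike_width is not None:
            return self.spike_width
        return 0.005 / self.fundamental_freq if self.fundamental_freq else 0.01

    def __post_init__(self):
        kind = self.label.kind
        if kind in _STEADY:
            if self.fundamental_freq != 0:
                raise ValueError("steady classes must have fundamental_freq = 0")
            return
        if kind not in _BANDS:
            raise ValueError(f"cannot synthesize class {kind}")
        lo, hi = _BANDS[kind]
        if not lo <= self.fundamental_freq <= hi:
            raise ValueError(
                f"{kind.name} requires fundamental_freq in [{lo}, {hi}] Hz, "
                f"got {self.fundamental_freq}")
        if kind in (StateKind.SWD, StateKind.N_SWD):
            if self.n_spikes < 1:
                raise ValueError("SWD family needs n_spikes >= 1")
            if self.label.n_spikes != self.n_spikes:
                raise ValueError("label spike count disagrees with n_spikes")


def _swd_template(t: np.ndarray, spec: WaveformSpec) -> np.ndarray:
    """Per period: a raised-cosine slow wave (pure fundamental plus offset,
    peaking at 25% of the period) with n narrow Gaussian spikes riding the
    second half of the period."""
    T = 1.0 / spec.fundamental_freq
    w = spec.effective_spike_width
    frac = (t % T) / T
    y = spec.wave_amplitude * 0.5 * (1.0 + np.cos(2 * np.pi * (frac - 0.25)))
    n = spec.n_spikes
    for i in range(n):
        center = 0.55 + 0.40 * (i + 0.5) / n
        y = y + spec.spike_amplitude * np.exp(
            -0.5 * ((frac - center) * T / w) ** 2)
    return y


def generate_waveform(spec: WaveformSpec, sample_dt: float = 5e-4
                      ) -> Tuple[Trajectory, StateLabel]:
    """Render a spec to a single-channel trajectory plus its ground truth.

    Deterministic given ``spec.seed``.  The trajectory carries a 2 s
    transient cutoff so the analysis pipeline sees >= 8 s of signal at the
    default duration.
    """
    n = int(round(spec.duration / sample_dt)) + 1
    t = np.arange(n) * sample_dt
    kind = spec.label.kind
    if kind in _STEADY:
        y = np.full(n, spec.baseline)
    elif kind in (StateKind.SWD, StateKind.N_SWD):
        y = spec.baseline + _swd_template(t, spec)
    else:
        y = spec.baseline + spec.wave_amplitude * np.sin(
            2 * np.pi * spec.fundamental_freq * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    traj = Trajectory(times=t, states=y[:, None], dt=sample_dt,
                      record_stride=1, transient_cutoff=min(2.0, 0.1 * spec.duration),
                      channels=("PY1",))
    return traj, spec.label


def _default_class_specs() -> List[WaveformSpec]:
    mk = WaveformSpec
    return [
        mk(StateLabel(StateKind.LOW_SATURATED), baseline=0.17),
        mk(StateLabel(StateKind.HIGH_SATURATED), baseline=0.38),
        mk(StateLabel.swd(1), fundamental_freq=3.0, n_spikes=1),
        mk(StateLabel.swd(2), fundamental_freq=2.5, n_spikes=2),
        mk(StateLabel.swd(3), fundamental_freq=2.0, n_spikes=3),
        mk(StateLabel.swd(4), fundamental_freq=2.0, n_spikes=4),
        mk(StateLabel(StateKind.TONIC), fundamental_freq=15.0, wave_amplitude=0.1,
           baseline=0.17),
        mk(StateLabel(StateKind.CLONIC), fundamental_freq=5.0, wave_amplitude=0.45,
           baseline=0.4),
        mk(StateLabel(StateKind.SLOW_WAVE), fundamental_freq=2.5,
           wave_amplitude=0.3, baseline=0.0),
    ]


#: One representative spec per discharge class (spike-and-wave at 1-4 spikes).
DEFAULT_CLASS_SPECS = _default_class_specs()


@dataclass
class SuiteItem:
    trajectory: Trajectory
    label: StateLabel
    spec: WaveformSpec
    noise_level: float


def _clean_ac_rms(spec: WaveformSpec) -> float:
    clean = replace(spec, noise_sd=0.0)
    traj, _ = generate_waveform(clean)
    y = traj.states[:, 0]
    return float(np.sqrt(np.mean((y - y.mean()) ** 2)))


def generate_test_suite(n_per_class: int = 1,
                        noise_levels: Sequence[float] = (0.0, 0.1),
                        master_seed: int = 0) -> List[SuiteItem]:
    """Labeled suite covering every discharge class at several noise levels.

    ``noise_levels`` are noise standard deviations relative to each clean
    waveform's AC RMS (0.1 corresponds to 20 dB SNR).  Steady classes have
    no AC power; they receive jitter scaled to 1e-4 so that the level
    controls reproducibility rather than pushing a fixed-point trace above
    the classifier's amplitude floor (real measurement noise on EEG-scale
    steady traces is out of scope for these surrogates).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    items: List[SuiteItem] = []
    counter = 0
    for base in DEFAULT_CLASS_SPECS:
        scale = _clean_ac_rms(base)
        if scale == 0.0:
            scale = 1e-4
        for level in noise_levels:
            for _ in range(n_per_class):
                seed = (int(master_seed) * 1000003 + counter * 9176 + 13) % (2 ** 31)
                counter += 1
                spec = replace(base, noise_sd=float(level) * scale, seed=seed)
                traj, label = generate_waveform(spec)
                items.append(SuiteItem(traj, label, spec, float(level)))
    return items
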