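"""One-parameter sweep diagrams and threshold refinement.

A sweep runs the standard settle-and-classify protocol at every grid
value of one coupling strength and records extrema, dominant frequency
and the discharge label — the simulation analogue of a one-parameter
bifurcation diagram.  Initial-condition policies:

* ``fixed`` — every point starts from the default initial condition
  (the protocol behind the headline diagrams);
* ``inherited-forward`` / ``inherited-backward`` — each run is seeded
  with the previous point's final state, scanning up or down the grid;
  disagreement between the two inherited scans marks coexisting
  attractors (a simulation-level surrogate for LPC-bounded windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .integrator import (DEFAULT_DT, DEFAULT_STRIDE, DEFAULT_T_TOTAL,
                         DEFAULT_T_TRANSIENT, DivergenceError, Trajectory,
                         settle_to_attractor)
from .model_core import DEFAULT_IC
from .params import ModelParams
from .waveform_analysis import (DEFAULT_THRESHOLDS, ClassifierThresholds,
                                StateKind, StateLabel, WaveformFeatures,
                                analyze_trajectory, classify_state)

__all__ = [
    "SweepResult",
    "sweep_parameter",
    "refine_threshold",
    "hysteresis_scan",
    "bistable_windows",
    "FIGURE_PRESETS",
]

IC_POLICIES = ("fixed", "inherited-forward", "inherited-backward")

SCANNABLE = tuple(f"k{i}" for i in range(10))


@dataclass
class SweepResult:
    param_name: str
    grid: np.ndarray
    features: List[Optional[WaveformFeatures]]
    labels: List[StateLabel]
    ic_policy: str
    topology: int
    channel: str
    final_states: List[Optional[np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.grid) != len(self.labels) or len(self.grid) != len(self.features):
            raise ValueError("one record required per grid point")

    @property
    def diverged(self) -> np.ndarray:
        return np.array([lab.kind is StateKind.DIVERGENT for lab in self.labels])

    def amplitudes(self) -> np.ndarray:
        return np.array([f.amplitude if f is not None else np.nan
                         for f in self.features])

    def to_frame(self, max_extrema: int = 12) -> pd.DataFrame:
        """Tabular export: one row per grid point, extrema padded."""
        rows = []
        for v, f, lab in zip(self.grid, self.features, self.labels):
            row = {"param": v}
            maxima = np.unique(np.round(f.local_maxima, 6)) if f is not None else []
            minima = np.unique(np.round(f.local_minima, 6)) if f is not None else []
            for j in range(max_extrema):
                row[f"max{j + 1}"] = maxima[j] if j < len(maxima) else np.nan
                row[f"min{j + 1}"] = minima[j] if j < len(minima) else np.nan
            row.update({
                "amplitude": f.amplitude if f else np.nan,
                "mean": f.mean_level if f else np.nan,
                "dominant_freq_hz": f.dominant_freq if f else np.nan,
                "spikes_per_period": f.spikes_per_period if f else 0,
                "label": str(lab),
                "diverged": lab.kind is StateKind.DIVERGENT,
            })
            rows.append(row)
        return pd.DataFrame(rows)


def _run_point(params: ModelParams, topology: int, x0: np.ndarray,
               channel: str, thresholds: ClassifierThresholds,
               t_total: float, t_transient: float, dt: float, stride: int):
    try:
        traj = settle_to_attractor(params, topology, x0, t_total, t_transient,
                                   dt, stride)
    except DivergenceError:
        return None, StateLabel(StateKind.DIVERGENT), None
    feats = analyze_trajectory(traj, channel, thresholds)
    return feats, classify_state(feats, thresholds), traj.final_state


def sweep_parameter(param_name: str, grid: Sequence[float], params: ModelParams,
                    topology: int = 1, ic_policy: str = "fixed",
                    channel: Optional[str] = None,
                    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
                    t_total: float = DEFAULT_T_TOTAL,
                    t_transient: float = DEFAULT_T_TRANSIENT,
                    dt: float = DEFAULT_DT,
                    record_stride: int = DEFAULT_STRIDE) -> SweepResult:
    """Settle-and-classify at every grid value of one coupling strength."""
    if param_name not in SCANNABLE:
        raise ValueError(f"param_name must be one of {SCANNABLE}")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if grid.size > 1:
        d = np.diff(grid)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("grid must be strictly monotone")
    if ic_policy not in IC_POLICIES:
        raise ValueError(f"ic_policy must be one of {IC_POLICIES}")
    channel = channel or ("PY1" if topology == 1 else "PY2")

    order = range(len(grid)) if ic_policy != "inherited-backward" \
        else range(len(grid) - 1, -1, -1)
    feats: List[Optional[WaveformFeatures]] = [None] * len(grid)
    labels: List[StateLabel] = [StateLabel(StateKind.UNCLASSIFIED)] * len(grid)
    finals: List[Optional[np.ndarray]] = [None] * len(grid)
    x0 = DEFAULT_IC(topology)
    for i in order:
        p = params.replace(**{param_name: float(grid[i])})
        f, lab, final = _run_point(p, topology, x0, channel, thresholds,
                                   t_total, t_transient, dt, record_stride)
        feats[i], labels[i], finals[i] = f, lab, final
        if ic_policy != "fixed" and final is not None:
            x0 = final
        elif ic_policy == "fixed":
            x0 = DEFAULT_IC(topology)
        else:  # diverged under an inherited policy: restart from default
            x0 = DEFAULT_IC(topology)
    return SweepResult(param_name=param_name, grid=grid, features=feats,
                       labels=labels, ic_policy=ic_policy, topology=topology,
                       channel=channel, final_states=finals)


def refine_threshold(param_name: str, bracket: Tuple[float, float],
                     predicate: Callable[[StateLabel, Optional[WaveformFeatures]], bool],
                     params: ModelParams, topology: int = 1,
                     tol: float = 1e-3,
                     channel: Optional[str] = None,
                     thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
                     t_total: float = DEFAULT_T_TOTAL,
                     t_transient: float = DEFAULT_T_TRANSIENT,
                     dt: float = DEFAULT_DT,
                     record_stride: int = DEFAULT_STRIDE) -> float:
    """Bisect a label-based predicate to locate a state-transition value.

    The predicate must differ between the two bracket ends; the returned
    midpoint is accurate to ``tol`` in parameter units.
    """
    channel = channel or ("PY1" if topology == 1 else "PY2")
    lo, hi = float(bracket[0]), float(bracket[1])

    def ev(v: float) -> bool:
        p = params.replace(**{param_name: v})
        f, lab, _ = _run_point(p, topology, DEFAULT_IC(topology), channel,
                               thresholds, t_total, t_transient, dt, record_stride)
        return bool(predicate(lab, f))

    plo, phi = ev(lo), ev(hi)
    if plo == phi:
        raise ValueError(
            f"predicate is identical ({plo}) at both bracket ends {bracket}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ev(mid) == plo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bistable_windows(grid: np.ndarray,
                     amp_fwd: np.ndarray, amp_bwd: np.ndarray,
                     labels_fwd: Sequence[StateLabel],
                     labels_bwd: Sequence[StateLabel],
                     delta_amp: float = DEFAULT_THRESHOLDS.delta_amp
                     ) -> List[Tuple[float, float]]:
    """Grid intervals where forward and backward inherited scans disagree
    (different label kind, or amplitudes differing by more than delta_amp)."""
    disagree = np.array([
        (la.kind is not lb.kind) or (abs(aa - ab) > delta_amp)
        for la, lb, aa, ab in zip(labels_fwd, labels_bwd, amp_fwd, amp_bwd)
    ])
    windows: List[Tuple[float, float]] = []
    start = None
    for i, d in enumerate(disagree):
        if d and start is None:
            start = grid[max(i - 1, 0)]
        elif not d and start is not None:
            windows.append((float(start), float(grid[i])))
            start = None
    if start is not None:
        windows.append((float(start), float(grid[-1])))
    return windows


def hysteresis_scan(param_name: str, grid: Sequence[float], params: ModelParams,
                    topology: int = 1,
                    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
                    **kwargs):
    """Forward and backward inherited-IC sweeps; returns the bistable
    windows together with both sweep results."""
    grid = np.asarray(list(grid), dtype=float)
    if grid.size < 3:
        raise ValueError("hysteresis scan needs a grid of length >= 3")
    fwd = sweep_parameter(param_name, grid, params, topology,
                          ic_policy="inherited-forward", thresholds=thresholds,
                          **kwargs)
    bwd = sweep_parameter(param_name, grid, params, topology,
                          ic_policy="inherited-backward", thresholds=thresholds,
                          **kwargs)
    windows = bistable_windows(grid, fwd.amplitudes(), bwd.amplitudes(),
                               fwd.labels, bwd.labels, thresholds.delta_amp)
    return windows, fwd, bwd


def _presets():
    ranges = {"k1": (0.0, 2.0), "k2": (0.0, 2.0), "k3": (0.0, 2.0),
              "k5": (0.0, 8.0), "k6": (0.0, 2.0), "k7": (0.0, 5.0),
              "k8": (0.0, 13.0), "k9": (0.0, 1.5)}
    single = ["k1", "k2", "k3", "k5", "k6", "k7", "k8", "k9"]
    coupled9 = ["k1", "k2", "k3", "k5", "k7", "k8"]
    presets = {}
    for letter, pname in zip("abcdefgh", single):
        presets[f"fig2{letter}"] = dict(topology=1, k0=0.0, param=pname,
                                        lo=ranges[pname][0], hi=ranges[pname][1],
                                        n=201)
        presets[f"fig4{letter}"] = dict(topology=2, k0=0.0, param=pname,
                                        lo=ranges[pname][0], hi=ranges[pname][1],
                                        n=201)
    for letter, pname in zip("abcdef", coupled9):
        presets[f"fig9{letter}"] = dict(topology=2, k0=0.5, param=pname,
                                        lo=ranges[pname][0], hi=ranges[pname][1],
                                        n=201)
    return presets


#: Sweep presets reproducing the published one-parameter diagrams.
FIGURE_PRESETS = _presets()
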