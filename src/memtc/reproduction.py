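"""Headline quantities of the study, each recomputed from scratch.

Every function here runs the full pipeline (simulation protocol,
classifier, continuation) at the published parameter settings and returns
one number; the analysis scripts and the acceptance checks share these
entry points so the reported values always come from the same code path.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .bifurcation import continue_cycles, continue_equilibria, detect_hopf
from .integrator import settle_to_attractor
from .parameter_sweep import hysteresis_scan, refine_threshold, sweep_parameter
from .params import ModelParams
from .waveform_analysis import (DEFAULT_THRESHOLDS, StateKind,
                                analyze_trajectory, classify_trajectory)

__all__ = [
    "tonic_onset_k2",
    "tonic_frequency",
    "swd_onset_k7",
    "low_discharge_onset_k8",
    "coupled_spikes_per_period",
    "coupled_dominant_frequency",
    "hopf_points_k5",
    "hopf_points",
    "coupled_k1_stability_loss",
    "k3_stable_window_lower_edge",
    "k5_coexistence_window",
    "k5_lpc",
]


def _osc_predicate(lab, feats) -> bool:
    return feats is not None and feats.amplitude > DEFAULT_THRESHOLDS.delta_amp


def tonic_onset_k2(tol: float = 1e-3) -> float:
    """Smallest k2 (single model, k0=0) whose settled pyramidal response
    oscillates above 10 Hz — the low-firing to tonic transition."""
    pred = lambda lab, f: f is not None and f.dominant_freq > 10.0
    return refine_threshold("k2", (0.0, 2.0), pred, ModelParams(), tol=tol)


def tonic_frequency(k2: float = 1.8) -> float:
    """Dominant PY1 frequency inside the tonic band (single model, k0=0)."""
    traj = settle_to_attractor(ModelParams(k2=k2))
    return analyze_trajectory(traj).dominant_freq


def swd_onset_k7(coarse_step: float = 0.02, tol: float = 1e-3) -> float:
    """Smallest k7 (single model, k0=0) where the settled response leaves
    the saturated background and shows the SWD oscillation.

    A coarse sweep brackets the first oscillatory grid point; bisection on
    the steady-vs-oscillatory predicate refines the onset.
    """
    grid = np.arange(0.0, 5.0 + 1e-9, coarse_step)
    res = sweep_parameter("k7", grid, ModelParams())
    osc = [i for i, f in enumerate(res.features) if _osc_predicate(None, f)]
    if not osc:
        raise RuntimeError("no oscillatory point found in the k7 sweep")
    i = osc[0]
    if i == 0:
        return float(grid[0])
    return refine_threshold("k7", (grid[i - 1], grid[i]), _osc_predicate,
                            ModelParams(), tol=tol)


def low_discharge_onset_k8(coarse_step: float = 0.25, tol: float = 1e-3) -> float:
    """Smallest k8 (single model, k0=0) at which the settled response has
    collapsed to the steady low-discharge state and stays there for all
    larger k8 in the scanned range."""
    th = DEFAULT_THRESHOLDS

    def low(lab, f):
        return (f is not None and f.amplitude < th.delta_amp
                and f.mean_level < th.theta_sat)

    grid = np.arange(0.0, 13.0 + 1e-9, coarse_step)
    res = sweep_parameter("k8", grid, ModelParams())
    flags = [low(None, f) for f in res.features]
    # last transition into the persistent low-discharge segment
    idx = len(flags) - 1
    while idx > 0 and flags[idx - 1]:
        idx -= 1
    if idx == 0:
        return float(grid[0])
    return refine_threshold("k8", (grid[idx - 1], grid[idx]), low,
                            ModelParams(), tol=tol)


def coupled_spikes_per_period(k6: float = 0.21) -> int:
    """Spike maxima per fundamental period of PY2 (coupled model, k0=0)."""
    traj = settle_to_attractor(ModelParams(k6=k6), topology=2)
    return analyze_trajectory(traj, "PY2").spikes_per_period


def coupled_dominant_frequency(k6: float = 1.8) -> float:
    """Dominant PY2 frequency (coupled model, k0=0); ~5 Hz clonic at
    k6 = 1.8."""
    traj = settle_to_attractor(ModelParams(k6=k6), topology=2)
    return analyze_trajectory(traj, "PY2").dominant_freq


def hopf_points(param: str, prange: Tuple[float, float], k0: float,
                topology: int = 1) -> List[float]:
    """Hopf parameter values along the equilibrium branch, in scan order."""
    params = ModelParams(k0=k0)
    branch = continue_equilibria(param, prange, params, topology)
    return [b.param for b in detect_hopf(branch, params, topology)]


def hopf_points_k5(k0: float) -> List[float]:
    return hopf_points("k5", (0.01, 8.0), k0)


def coupled_k1_stability_loss() -> float:
    """k1 at which the coupled model's steady state loses stability
    (k0=0): the Hopf terminating the widest stable window in [0, 2]."""
    params = ModelParams()
    branch = continue_equilibria("k1", (0.01, 2.0), params, topology=2)
    pts = branch.points
    hbs = detect_hopf(branch, params, topology=2)
    if not hbs:
        raise RuntimeError("no Hopf point found on the k1 branch")
    # windows of consecutive stable points, each ended by the next HB
    best_hb, best_width = None, -1.0
    for hb in hbs:
        stable_below = [p.param for p in pts if p.param < hb.param and p.stable]
        if not stable_below:
            continue
        # width of the contiguous stable run immediately below the HB
        width = 0.0
        prev = hb.param
        for q in reversed([p for p in pts if p.param < hb.param]):
            if not q.stable:
                break
            width = hb.param - q.param
            prev = q.param
        if width > best_width:
            best_hb, best_width = hb, width
    if best_hb is None:
        raise RuntimeError("no stable-to-unstable Hopf crossing found")
    return best_hb.param


def k3_stable_window_lower_edge() -> float:
    """Lower edge of the stable fixed-point window in k3 (single model,
    k0=0.5): first Hopf crossing into all-negative real parts."""
    params = ModelParams(k0=0.5)
    branch = continue_equilibria("k3", (0.01, 2.0), params)
    hbs = detect_hopf(branch, params, 1)
    for hb in hbs:
        after = [p for p in branch.points if p.param > hb.param]
        if after and after[0].stable:
            return hb.param
    raise RuntimeError("no stabilizing Hopf crossing found on the k3 branch")


def k5_coexistence_window(grid=None) -> List[Tuple[float, float]]:
    """Bistable windows in k5 (single model, k0=0.5) from forward vs
    backward inherited-IC scans."""
    if grid is None:
        grid = np.linspace(3.2, 4.0, 17)
    params = ModelParams(k0=0.5)
    windows, _, _ = hysteresis_scan("k5", grid, params)
    return windows


def k5_lpc(start: float = 3.6) -> List[float]:
    """Fold-of-cycles locations found by continuing the k5 SWD cycle
    downward from inside the coexistence region (single model, k0=0.5)."""
    params = ModelParams(k0=0.5, k5=start)
    seed_traj = settle_to_attractor(params)
    _, events = continue_cycles("k5", 3.0, params, 1, seed_traj=seed_traj,
                                start_value=start)
    return [e.param for e in events if e.kind == "LPC"]
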