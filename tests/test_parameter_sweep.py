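"""Sweep mechanics, threshold bisection and bistability detection."""

import numpy as np
import pytest

from memtc import (ModelParams, StateKind, StateLabel, rk4_integrate,
                   refine_threshold, sweep_parameter)
from memtc.parameter_sweep import FIGURE_PRESETS, bistable_windows

FAST = dict(t_total=10.5, t_transient=2.0)


def test_single_point_grid(default_params):
    res = sweep_parameter("k7", [2.0], default_params, **FAST)
    assert len(res.grid) == 1
    assert len(res.labels) == 1
    assert res.labels[0].kind in (StateKind.SWD, StateKind.N_SWD)


def test_sweep_validation(default_params):
    with pytest.raises(ValueError):
        sweep_parameter("k7", [], default_params)
    with pytest.raises(ValueError):
        sweep_parameter("tau1", [1.0], default_params)
    with pytest.raises(ValueError):
        sweep_parameter("k7", [1.0, 0.5, 2.0], default_params)
    with pytest.raises(ValueError):
        sweep_parameter("k7", [1.0, 2.0], default_params, ic_policy="zigzag")


def test_sweep_deterministic(default_params):
    a = sweep_parameter("k7", [1.0, 2.0, 4.5], default_params, **FAST)
    b = sweep_parameter("k7", [1.0, 2.0, 4.5], default_params, **FAST)
    assert a.labels == b.labels
    np.testing.assert_array_equal(a.amplitudes(), b.amplitudes())


def test_sweep_to_frame_schema(default_params):
    res = sweep_parameter("k7", [1.0, 2.0], default_params, **FAST)
    df = res.to_frame()
    for col in ("param", "max1", "min1", "amplitude", "mean",
                "dominant_freq_hz", "spikes_per_period", "label", "diverged"):
        assert col in df.columns
    assert len(df) == 2


def test_four_state_sequence_in_k7(default_params):
    """Scanning the cortex->reticular drive passes through high saturated,
    SWD, low saturated and tonic responses, in that order."""
    grid = [1.0, 2.0, 3.6, 4.5]
    res = sweep_parameter("k7", grid, default_params)
    kinds = [lab.kind for lab in res.labels]
    assert kinds == [StateKind.HIGH_SATURATED, StateKind.SWD,
                     StateKind.LOW_SATURATED, StateKind.TONIC]


def test_refine_threshold_bracket_error(default_params):
    always = lambda lab, f: True
    with pytest.raises(ValueError):
        refine_threshold("k7", (1.0, 2.0), always, default_params, **FAST)


def test_refine_threshold_converges_to_oscillation_onset(default_params):
    """Bisection on the steady-vs-oscillatory predicate localizes the SWD
    onset in k7 independently of the initial bracket."""
    osc = lambda lab, f: f is not None and f.amplitude > 1e-3
    a = refine_threshold("k7", (1.0, 2.0), osc, default_params, tol=5e-3)
    b = refine_threshold("k7", (0.5, 2.2), osc, default_params, tol=5e-3)
    assert abs(a - b) < 1e-2


def test_bistable_windows_on_cubic_normal_form():
    """Forward/backward scans of dx/dt = mu + x - x**3 recover the fold
    window (-2/(3*sqrt(3)), +2/(3*sqrt(3)))."""
    fold = 2.0 / (3.0 * np.sqrt(3.0))
    grid = np.linspace(-0.6, 0.6, 49)

    def settle(mu, x0):
        traj = rk4_integrate(lambda x: mu + x - x ** 3, [x0], t_end=20.0,
                             dt=0.01, record_stride=100)
        return float(traj.states[-1, 0])

    finals_fwd, finals_bwd = [], []
    x = -1.5
    for mu in grid:
        x = settle(mu, x)
        finals_fwd.append(x)
    x = 1.5
    for mu in grid[::-1]:
        x = settle(mu, x)
        finals_bwd.append(x)
    finals_bwd = finals_bwd[::-1]
    lab = lambda v: StateLabel(StateKind.HIGH_SATURATED if v > 0
                               else StateKind.LOW_SATURATED)
    windows = bistable_windows(grid, np.zeros(len(grid)), np.zeros(len(grid)),
                               [lab(v) for v in finals_fwd],
                               [lab(v) for v in finals_bwd])
    assert len(windows) == 1
    lo, hi = windows[0]
    step = grid[1] - grid[0]
    assert lo == pytest.approx(-fold, abs=2 * step)
    assert hi == pytest.approx(fold, abs=2 * step)


def test_figure_presets_cover_published_axes():
    assert FIGURE_PRESETS["fig2f"] == dict(topology=1, k0=0.0, param="k7",
                                           lo=0.0, hi=5.0, n=201)
    assert FIGURE_PRESETS["fig9a"]["k0"] == 0.5
    assert FIGURE_PRESETS["fig4e"]["topology"] == 2
    assert len([k for k in FIGURE_PRESETS if k.startswith("fig2")]) == 8


def test_inherited_policies_seed_from_neighbor(default_params):
    """In a bistable window the inherited-backward scan (coming from the
    oscillatory side) keeps the cycle while inherited-forward (coming from
    the steady side) keeps the fixed point."""
    p = default_params.replace(k0=0.5)
    grid = np.array([3.2, 3.3, 3.4, 3.5, 3.6])
    fwd = sweep_parameter("k5", grid, p, ic_policy="inherited-forward")
    bwd = sweep_parameter("k5", grid, p, ic_policy="inherited-backward")
    # k5 = 3.5 lies in the coexistence window: forward arrives on the
    # fixed point, backward arrives on the cycle
    assert fwd.amplitudes()[3] < 1e-3
    assert bwd.amplitudes()[3] > 0.1
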