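"""Equilibrium continuation, Hopf detection, shooting and Floquet analysis."""

import numpy as np
import pytest

from memtc import (ModelParams, continue_cycles, continue_equilibria,
                   detect_hopf, find_all_equilibria, find_equilibrium,
                   settle_to_attractor, shoot_limit_cycle)
from memtc.bifurcation import (ConvergenceError, NoCycleError,
                               classify_multipliers, nontrivial_multipliers)
from memtc.model_core import rhs
from memtc.waveform_analysis import dominant_frequency


def test_equilibrium_residual_contract(default_params):
    eq = find_equilibrium(default_params, 1)
    assert eq.residual < 1e-10
    assert np.max(np.abs(rhs(eq.state, default_params))) < 1e-10


def test_equilibrium_guess_validation(default_params):
    with pytest.raises(ValueError):
        find_equilibrium(default_params, 1, np.full(5, np.nan))
    with pytest.raises(ValueError):
        find_equilibrium(default_params, 1, np.zeros(7))


def test_stable_equilibrium_attracts_nearby_trajectories(default_params):
    """Simulation oracle: settling from a slightly perturbed state ends
    within 1e-6 of a stable Newton equilibrium."""
    p = default_params.replace(k7=1.0)
    eq = find_equilibrium(p, 1)
    assert eq.stable
    traj = settle_to_attractor(p, x0=eq.state + 0.01)
    assert np.max(np.abs(traj.final_state - eq.state)) < 1e-6


@pytest.mark.parametrize("k5", [0.5, 2.0, 3.0, 5.0, 7.5])
def test_bruteforce_scan_finds_no_extra_equilibria(default_params, k5):
    """Multi-start Newton over the state box agrees with the branch the
    continuation tracks (five test parameter points)."""
    p = default_params.replace(k5=k5)
    found = find_all_equilibria(p, 1)
    assert len(found) == 1
    for e in found:
        assert e.residual < 1e-10


def test_continuation_branch_residuals_and_reversibility(default_params):
    """All branch residuals meet the contract; scanning the branch in the
    reversed direction localizes the same Hopf points."""
    br_f = continue_equilibria("k5", (0.01, 8.0), default_params)
    assert br_f.status == "ok"
    assert all(pt.residual < 1e-10 for pt in br_f.points)
    br_b = continue_equilibria("k5", (0.01, 8.0), default_params, start_at="hi")
    hb_f = detect_hopf(br_f, default_params, 1)
    hb_b = detect_hopf(br_b, default_params, 1)
    assert len(hb_f) == len(hb_b) > 0
    for a, b in zip(sorted(p.param for p in hb_f),
                    sorted(p.param for p in hb_b)):
        assert abs(a - b) < 2e-4


def test_hopf_points_have_complex_crossing_pair(default_params):
    """Every reported Hopf has a genuinely complex crossing pair (no fold
    misclassified as Hopf) and near-zero real part."""
    br = continue_equilibria("k5", (0.01, 8.0), default_params)
    for hb in detect_hopf(br, default_params, 1):
        assert abs(hb.diagnostic.imag) > 1e-6
        assert abs(hb.diagnostic.real) < 1e-2


def test_stable_branch_yields_no_hopf(default_params):
    """k7 in [0.2, 1.2] (no memristor): the equilibrium stays stable."""
    br = continue_equilibria("k7", (0.2, 1.2), default_params)
    assert all(pt.stable for pt in br.points)
    assert detect_hopf(br, default_params, 1) == []


def test_stability_flags_agree_with_simulation(default_params):
    """At 10 branch points away from bifurcations, the eigenvalue stability
    flag predicts whether a perturbed trajectory returns to the
    equilibrium."""
    br = continue_equilibria("k5", (0.01, 8.0), default_params)
    pts = [pt for pt in br.points
           if abs(max(e.real for e in pt.eigenvalues)) > 0.3]
    sel = pts[:: max(1, len(pts) // 10)][:10]
    assert len(sel) >= 10 - 1
    for pt in sel:
        p = default_params.replace(k5=pt.param)
        traj = settle_to_attractor(p, x0=pt.state + 1e-3, t_total=20.0,
                                   t_transient=10.0)
        dist = np.max(np.abs(traj.final_state - pt.state))
        if pt.stable:
            assert dist < 1e-6
        else:
            assert dist > 1e-3


def test_shooting_swd_cycle(default_params, swd_trajectory):
    """The k7 = 2 SWD orbit: closed to 1e-8, trivial multiplier at +1
    within 1e-3, stable (non-trivial multipliers inside the unit circle),
    period consistent with the seed's dominant frequency."""
    p = default_params.replace(k7=2.0)
    cyc = shoot_limit_cycle(p, 1, seed_traj=swd_trajectory)
    assert cyc.residual < 1e-8
    trivial = cyc.multipliers[np.argmin(np.abs(cyc.multipliers - 1.0))]
    assert abs(trivial - 1.0) < 1e-3
    assert np.all(np.abs(nontrivial_multipliers(cyc.multipliers)) < 1.0)
    f = dominant_frequency(swd_trajectory, "PY1")
    assert cyc.period == pytest.approx(1.0 / f, rel=0.05)


def test_shooting_coupled_clonic_cycle(default_params):
    """Coupled-model clonic orbit (k6 = 1.8): the 10-dimensional
    variational problem still yields the trivial multiplier."""
    p = default_params.replace(k6=1.8)
    traj = settle_to_attractor(p, topology=2)
    cyc = shoot_limit_cycle(p, 2, seed_traj=traj)
    assert cyc.residual < 1e-8
    trivial = cyc.multipliers[np.argmin(np.abs(cyc.multipliers - 1.0))]
    assert abs(trivial - 1.0) < 1e-3


def test_shooting_rejects_steady_seed(default_params):
    p = default_params.replace(k7=1.0)
    traj = settle_to_attractor(p)
    with pytest.raises(NoCycleError):
        shoot_limit_cycle(p, 1, seed_traj=traj)


def test_multiplier_crossing_classification():
    mk = lambda *vals: np.array(vals, dtype=complex)
    # non-trivial real multiplier through +1 -> fold of cycles
    assert classify_multipliers(mk(1.0, 0.95, 0.3), mk(1.0, 1.05, 0.3)) == "LPC"
    # real multiplier through -1 -> period doubling, reported as OTHER
    assert classify_multipliers(mk(1.0, -0.95, 0.3), mk(1.0, -1.06, 0.3)) == "OTHER"
    # complex pair through the unit circle -> torus
    a = mk(1.0, 0.9 * np.exp(1j), 0.9 * np.exp(-1j))
    b = mk(1.0, 1.1 * np.exp(1j), 1.1 * np.exp(-1j))
    assert classify_multipliers(a, b) == "TR"
    # everything inside the circle -> nothing flagged
    assert classify_multipliers(mk(1.0, 0.5, 0.3), mk(1.0, 0.6, 0.3)) is None


def test_cycle_continuation_no_events_inside_unit_circle(default_params):
    """Continuing the SWD cycle over a short stable stretch flags nothing."""
    p = default_params.replace(k7=2.0)
    traj = settle_to_attractor(p)
    branch, events = continue_cycles("k7", 2.1, p, 1, seed_traj=traj,
                                     start_value=2.0, step=0.05)
    assert branch.status == "ok"
    assert events == []
    assert all(c.residual < 1e-8 for c in branch.points)
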