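"""Vector-field, activation-function and Jacobian correctness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtc import (DEFAULT_IC, ModelParams, jacobian, linear_G,
                   memristance_rho, rhs, rhs_coupled, rhs_single, sigmoid_F)
from memtc.bifurcation import find_all_equilibria, find_equilibrium


@pytest.mark.parametrize("x, expected", [
    (0.0, 0.5),
    (1.0, 1.0 / (1.0 + 1.0 / 2.5e5)),
    (-1.0, 1.0 - 1.0 / (1.0 + 1.0 / 2.5e5)),
])
def test_sigmoid_values(x, expected):
    assert sigmoid_F(x) == pytest.approx(expected, rel=1e-12)


def test_sigmoid_overflow_safe_and_monotone():
    xs = np.linspace(-500, 500, 2001)
    ys = sigmoid_F(xs)
    assert np.all(np.isfinite(ys))
    assert np.all(ys >= 0.0) and np.all(ys <= 1.0)
    assert np.all(np.diff(ys) >= 0)
    # strict increase where not saturated at double precision
    mid = np.abs(xs) < 2
    assert np.all(np.diff(ys[mid]) > 0)


@pytest.mark.parametrize("x, expected", [(0.0, 0.5), (1.0, 3.3), (-0.5, -0.9)])
def test_linear_activation(x, expected):
    assert linear_G(x) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("phi, expected", [(0.0, 0.4), (1.0, 0.46)])
def test_memristance_values(phi, expected):
    assert memristance_rho(phi) == pytest.approx(expected, rel=1e-12)


@given(st.floats(-50, 50))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_memristance_even_and_bounded_below(phi):
    p = ModelParams()
    assert memristance_rho(phi) == memristance_rho(-phi)
    assert memristance_rho(phi) >= p.alpha1


@pytest.mark.parametrize("fn", [sigmoid_F, linear_G, memristance_rho])
def test_nonfinite_input_rejected(fn):
    with pytest.raises(ValueError):
        fn(np.nan)


def test_rhs_dimension_checks(default_params):
    with pytest.raises(ValueError):
        rhs_single(np.zeros(10), default_params)
    with pytest.raises(ValueError):
        rhs_coupled(np.zeros(5), default_params)
    with pytest.raises(ValueError):
        rhs(np.zeros(7), default_params)


def test_memristor_term_only_enters_py_equation(default_params, rng):
    """At k0 = 0 every derivative is independent of the flux value; at
    k0 > 0 only the PY row changes with phi."""
    p0 = default_params
    p1 = default_params.replace(k0=0.5)
    for _ in range(5):
        x = rng.uniform(-1, 1, 5)
        xa, xb = x.copy(), x.copy()
        xb[4] += 0.7
        da, db = rhs_single(xa, p0), rhs_single(xb, p0)
        assert np.array_equal(da[:4], db[:4])
        da, db = rhs_single(xa, p1), rhs_single(xb, p1)
        assert not np.isclose(da[0], db[0])
        assert np.array_equal(da[1:4], db[1:4])


def test_coupled_restriction_matches_single(default_params, rng):
    for _ in range(5):
        x = rng.uniform(-1, 1, 10)
        assert np.array_equal(rhs_coupled(x, default_params)[:5],
                              rhs_single(x[:5], default_params))


def test_coupling_is_one_way(default_params, rng):
    """Perturbing compartment 2 leaves compartment-1 derivatives
    bit-identical."""
    x = rng.uniform(-1, 1, 10)
    y = x.copy()
    y[5:] += rng.uniform(0.1, 1.0, 5)
    assert np.array_equal(rhs_coupled(x, default_params)[:5],
                          rhs_coupled(y, default_params)[:5])


def test_intercompartment_drive_outside_tau(default_params):
    """With identical compartment states, the compartment-2 derivative
    differs from compartment 1 exactly by the scaled drive terms (which
    are not multiplied by the timescales)."""
    p = default_params
    x5 = np.array([0.3, -0.2, 0.1, -0.5, 0.2])
    x10 = np.concatenate([x5, x5])
    d = rhs_coupled(x10, p)
    c = p.coupling_scale
    drive = np.array([
        c * (p.k1 * sigmoid_F(x5[0], p) - p.k2 * sigmoid_F(x5[1], p)),
        c * p.k4 * sigmoid_F(x5[0], p),
        -c * p.k6 * linear_G(x5[3], p),
        c * (p.k8 * linear_G(x5[2], p) - p.k9 * linear_G(x5[3], p)),
        0.0,
    ])
    np.testing.assert_allclose(d[5:] - d[:5], drive, rtol=1e-12, atol=1e-14)


def _fd_jacobian(x, params, h=1e-6):
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (rhs(x + e, params) - rhs(x - e, params)) / (2 * h)
    return J


@pytest.mark.parametrize("topology", [1, 2])
def test_jacobian_matches_finite_differences(topology, rng):
    """Analytic Jacobian vs central differences at 20 random states and
    random parameter draws, rel. err < 1e-5."""
    for i in range(20):
        params = ModelParams(k0=rng.uniform(0, 0.5),
                             k5=rng.uniform(0.5, 6),
                             k7=rng.uniform(0.5, 4))
        x = rng.uniform(-1.5, 1.5, 5 * topology)
        J = jacobian(x, params)
        Jfd = _fd_jacobian(x, params)
        scale = np.max(np.abs(J))
        assert np.max(np.abs(J - Jfd)) / scale < 1e-5


def test_jacobian_structure(default_params, rng):
    p = default_params
    # (PY row, phi column) vanishes at phi = 0 even with the memristor on
    x = np.array([0.4, 0.1, -0.2, 0.3, 0.0])
    J = jacobian(x, p.replace(k0=0.5))
    assert J[0, 4] == 0.0
    # with k0 = 0 the neural block never sees the flux column
    x = rng.uniform(-1, 1, 5)
    J = jacobian(x, p)
    assert np.all(J[:4, 4] == 0.0)
    # coupled Jacobian is block lower-triangular (one-way coupling)
    x10 = rng.uniform(-1, 1, 10)
    J10 = jacobian(x10, p)
    assert np.all(J10[:5, 5:] == 0.0)


def test_newton_equilibrium_residual_and_bruteforce_scan(default_params):
    """Newton equilibria satisfy the residual contract and the multi-start
    root scan over the state box finds nothing extra."""
    eq = find_equilibrium(default_params, 1)
    assert np.max(np.abs(rhs_single(eq.state, default_params))) < 1e-10
    all_eq = find_all_equilibria(default_params, 1)
    assert len(all_eq) >= 1
    for e in all_eq:
        assert np.max(np.abs(rhs_single(e.state, default_params))) < 1e-10


def test_default_parameter_values():
    p = ModelParams()
    assert (p.k1, p.k2, p.k3, p.k4, p.k5) == (1.8, 1.5, 1.0, 4.0, 3.0)
    assert (p.k6, p.k7, p.k8, p.k9) == (0.6, 3.0, 10.5, 0.2)
    assert (p.tau1, p.tau2, p.tau3, p.tau4) == (26.0, 32.5, 2.6, 2.6)
    assert (p.eps_py, p.eps_in, p.eps_tc, p.eps_re) == (-0.35, -3.4, -2.0, -5.0)


@pytest.mark.parametrize("bad", [dict(tau1=-1.0), dict(sigmoid_base=0.5),
                                 dict(coupling_scale=0.0), dict(k5=np.nan)])
def test_parameter_validation(bad):
    with pytest.raises(ValueError):
        ModelParams(**bad)


def test_params_dict_roundtrip_rejects_unknown():
    p = ModelParams(k0=0.5)
    assert ModelParams.from_dict(p.to_dict()) == p
    with pytest.raises(ValueError):
        ModelParams.from_dict({"k99": 1.0})
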