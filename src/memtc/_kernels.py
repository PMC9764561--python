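"""Numba-compiled numerical kernels.

Everything here operates on the flat parameter vector produced by
:meth:`memtc.params.ModelParams.to_vector` (see ``PARAM_VECTOR_FIELDS``
for the index layout) and on raw state arrays: dimension 5 for the
single-compartment model ``(PY1, IN1, TC1, RE1, phi1)`` and 10 for the
one-way coupled model (compartment 2 appended).

The kernels are the single source of truth for the vector field and its
Jacobian; the public wrappers in :mod:`memtc.model_core` call straight
into them.
"""

import numpy as np
from numba import njit

# parameter-vector indices
_K0 = 0
_TAU = 10
_EPS = 14
_LIN_A = 18
_LIN_B = 19
_LAM1 = 20
_LAM2 = 21
_ALPHA1 = 22
_BETA1 = 23
_CSCALE = 24
_LOGBASE = 25


@njit(cache=True)
def sigmoid(x, log_base):
    """F[x] = 1 / (1 + base**(-x)), overflow-safe for large |x|."""
    z = x * log_base
    if z >= 0.0:
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z)
    return e / (1.0 + e)


@njit(cache=True)
def sigmoid_deriv(x, log_base):
    f = sigmoid(x, log_base)
    return log_base * f * (1.0 - f)


@njit(cache=True)
def _rhs_block(x, p, out, o):
    """Intra-compartment part of the vector field for compartment offset o."""
    lb = p[_LOGBASE]
    py, inn, tc, re, phi = x[o], x[o + 1], x[o + 2], x[o + 3], x[o + 4]
    a, b = p[_LIN_A], p[_LIN_B]
    rho = p[_ALPHA1] + 3.0 * p[_BETA1] * phi * phi
    fpy = sigmoid(py, lb)
    out[o] = (p[_EPS] - py + p[1] * fpy - p[2] * sigmoid(inn, lb)
              + p[3] * sigmoid(tc, lb) - p[_K0] * rho * py) * p[_TAU]
    out[o + 1] = (p[_EPS + 1] - inn + p[4] * fpy) * p[_TAU + 1]
    out[o + 2] = (p[_EPS + 2] - tc + p[5] * fpy - p[6] * (a * re + b)) * p[_TAU + 2]
    out[o + 3] = (p[_EPS + 3] - re + p[7] * fpy + p[8] * (a * tc + b)
                  - p[9] * (a * re + b)) * p[_TAU + 3]
    out[o + 4] = p[_LAM1] * py - p[_LAM2] * phi


@njit(cache=True)
def rhs(x, p, out):
    """Vector field; dispatches on state dimension (5 single, 10 coupled).

    The inter-compartment drive (left -> right only) is added outside the
    timescale multiplication, exactly as the model is written.
    """
    _rhs_block(x, p, out, 0)
    if x.shape[0] == 10:
        _rhs_block(x, p, out, 5)
        lb = p[_LOGBASE]
        a, b = p[_LIN_A], p[_LIN_B]
        c = p[_CSCALE]
        py1, in1, tc1, re1 = x[0], x[1], x[2], x[3]
        out[5] += c * (p[1] * sigmoid(py1, lb) - p[2] * sigmoid(in1, lb))
        out[6] += c * p[4] * sigmoid(py1, lb)
        out[7] += -c * p[6] * (a * re1 + b)
        out[8] += c * (p[8] * (a * tc1 + b) - p[9] * (a * re1 + b))


@njit(cache=True)
def _jac_block(x, p, J, o):
    lb = p[_LOGBASE]
    py, inn, tc, re, phi = x[o], x[o + 1], x[o + 2], x[o + 3], x[o + 4]
    a = p[_LIN_A]
    rho = p[_ALPHA1] + 3.0 * p[_BETA1] * phi * phi
    dfpy = sigmoid_deriv(py, lb)
    J[o, o] = (-1.0 + p[1] * dfpy - p[_K0] * rho) * p[_TAU]
    J[o, o + 1] = -p[2] * sigmoid_deriv(inn, lb) * p[_TAU]
    J[o, o + 2] = p[3] * sigmoid_deriv(tc, lb) * p[_TAU]
    J[o, o + 4] = -p[_K0] * 6.0 * p[_BETA1] * phi * py * p[_TAU]
    J[o + 1, o] = p[4] * dfpy * p[_TAU + 1]
    J[o + 1, o + 1] = -p[_TAU + 1]
    J[o + 2, o] = p[5] * dfpy * p[_TAU + 2]
    J[o + 2, o + 2] = -p[_TAU + 2]
    J[o + 2, o + 3] = -p[6] * a * p[_TAU + 2]
    J[o + 3, o] = p[7] * dfpy * p[_TAU + 3]
    J[o + 3, o + 2] = p[8] * a * p[_TAU + 3]
    J[o + 3, o + 3] = (-1.0 - p[9] * a) * p[_TAU + 3]
    J[o + 4, o] = p[_LAM1]
    J[o + 4, o + 4] = -p[_LAM2]


@njit(cache=True)
def jac(x, p, J):
    """Analytic Jacobian (block lower-triangular for the coupled model)."""
    J[:] = 0.0
    _jac_block(x, p, J, 0)
    if x.shape[0] == 10:
        _jac_block(x, p, J, 5)
        lb = p[_LOGBASE]
        a = p[_LIN_A]
        c = p[_CSCALE]
        J[5, 0] = c * p[1] * sigmoid_deriv(x[0], lb)
        J[5, 1] = -c * p[2] * sigmoid_deriv(x[1], lb)
        J[6, 0] = c * p[4] * sigmoid_deriv(x[0], lb)
        J[7, 3] = -c * p[6] * a
        J[8, 2] = c * p[8] * a
        J[8, 3] = -c * p[9] * a


@njit(cache=True)
def rk4_trajectory(p, x0, dt, n_steps, stride):
    """Classical RK4 with strided recording.

    Returns ``(samples, n_recorded, diverged_at)`` where ``samples`` has
    one row per recorded state (row 0 is the initial condition) and
    ``diverged_at`` is the step index at which a non-finite or exploding
    (|x| > 1e6) state was first recorded, or -1.
    """
    dim = x0.shape[0]
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, dim))
    x = x0.copy()
    out[0] = x
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    tmp = np.empty(dim)
    r = 1
    for i in range(n_steps):
        rhs(x, p, k1)
        for d in range(dim):
            tmp[d] = x[d] + 0.5 * dt * k1[d]
        rhs(tmp, p, k2)
        for d in range(dim):
            tmp[d] = x[d] + 0.5 * dt * k2[d]
        rhs(tmp, p, k3)
        for d in range(dim):
            tmp[d] = x[d] + dt * k3[d]
        rhs(tmp, p, k4)
        for d in range(dim):
            x[d] = x[d] + (dt / 6.0) * (k1[d] + 2.0 * k2[d] + 2.0 * k3[d] + k4[d])
        if (i + 1) % stride == 0:
            ok = True
            for d in range(dim):
                if not np.isfinite(x[d]) or np.abs(x[d]) > 1e6:
                    ok = False
            if not ok:
                return out[:r], r, i + 1
            out[r] = x
            r += 1
    return out[:r], r, -1


@njit(cache=True)
def flow_with_monodromy(p, x0, T, dt):
    """Integrate the state and the variational equations over one period.

    RK4 on the augmented system (x, M) with dM/dt = J(x) M, M(0) = I.
    Returns ``(x(T), M(T), py_min, py_max)``; the PY excursion lets the
    caller reject spurious "cycles" that have collapsed onto a fixed point.
    """
    dim = x0.shape[0]
    n = max(2, int(np.ceil(T / dt)))
    h = T / n
    x = x0.copy()
    M = np.eye(dim)
    J = np.empty((dim, dim))
    f1 = np.empty(dim)
    f2 = np.empty(dim)
    f3 = np.empty(dim)
    f4 = np.empty(dim)
    py_min = x[0]
    py_max = x[0]
    for i in range(n):
        rhs(x, p, f1)
        jac(x, p, J)
        K1 = J @ M
        x2 = x + 0.5 * h * f1
        M2 = M + 0.5 * h * K1
        rhs(x2, p, f2)
        jac(x2, p, J)
        K2 = J @ M2
        x3 = x + 0.5 * h * f2
        M3 = M + 0.5 * h * K2
        rhs(x3, p, f3)
        jac(x3, p, J)
        K3 = J @ M3
        x4 = x + h * f3
        M4 = M + h * K3
        rhs(x4, p, f4)
        jac(x4, p, J)
        K4 = J @ M4
        x = x + (h / 6.0) * (f1 + 2.0 * f2 + 2.0 * f3 + f4)
        M = M + (h / 6.0) * (K1 + 2.0 * K2 + 2.0 * K3 + K4)
        if x[0] < py_min:
            py_min = x[0]
        if x[0] > py_max:
            py_max = x[0]
    return x, M, py_min, py_max
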