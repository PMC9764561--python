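"""Vector fields, activation functions and analytic Jacobians.

Single-compartment state: ``(PY1, IN1, TC1, RE1, phi1)``.
Coupled state: compartment 2 appended, ``(..., PY2, IN2, TC2, RE2, phi2)``;
the inter-compartment drive is strictly one-way (compartment 1 never sees
compartment 2), which makes the coupled Jacobian block lower-triangular.

The memristor term ``-k0 * rho(phi) * PY`` enters only the pyramidal
equation; the flux obeys ``dphi/dt = lambda1*PY - lambda2*phi`` and is
always integrated, even at k0 = 0 where it decouples, so the state layout
is identical with and without electromagnetic induction.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .params import ModelParams

__all__ = [
    "sigmoid_F",
    "linear_G",
    "memristance_rho",
    "rhs_single",
    "rhs_coupled",
    "rhs",
    "jacobian",
    "state_dim",
    "channel_names",
    "DEFAULT_IC",
]


def state_dim(topology: int) -> int:
    if topology not in (1, 2):
        raise ValueError(f"topology must be 1 or 2, got {topology!r}")
    return 5 * topology


def channel_names(topology: int) -> tuple:
    base = ("PY", "IN", "TC", "RE", "phi")
    return tuple(f"{c}{i}" for i in range(1, topology + 1) for c in base)


def DEFAULT_IC(topology: int) -> np.ndarray:
    """Default initial condition: neural variables at 0.1, flux at 0."""
    x0 = np.full(state_dim(topology), 0.1)
    x0[4::5] = 0.0
    return x0


def _check_finite(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    return x


def sigmoid_F(x, params: ModelParams = None):
    """Cortical activation F[x] = 1/(1 + base**(-x)), in (0, 1).

    Computed via exp(-x*ln(base)) with a sign branch so that large |x|
    (the default base gives ln(base) ~ 12.4) cannot overflow.
    """
    params = params or ModelParams()
    x = _check_finite(x)
    lb = np.log(params.sigmoid_base)
    z = x * lb
    out = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                   np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    return out if out.ndim else float(out)


def linear_G(x, params: ModelParams = None):
    """Thalamic activation G[x] = a*x + b."""
    params = params or ModelParams()
    x = _check_finite(x)
    out = params.lin_a * x + params.lin_b
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def memristance_rho(phi, params: ModelParams = None):
    """Flux-controlled memristance rho(phi) = alpha1 + 3*beta1*phi**2."""
    params = params or ModelParams()
    phi = _check_finite(phi)
    out = params.alpha1 + 3.0 * params.beta1 * phi ** 2
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def rhs(state, params: ModelParams) -> np.ndarray:
    """Time derivative of the model state (dimension 5 or 10)."""
    x = np.asarray(state, dtype=np.float64)
    if x.shape != (5,) and x.shape != (10,):
        raise ValueError(f"state must have dimension 5 or 10, got shape {x.shape}")
    out = np.empty_like(x)
    _kernels.rhs(x, params.to_vector(), out)
    return out


def rhs_single(state, params: ModelParams) -> np.ndarray:
    x = np.asarray(state, dtype=np.float64)
    if x.shape != (5,):
        raise ValueError(f"single-compartment state must have dimension 5, got {x.shape}")
    return rhs(x, params)


def rhs_coupled(state, params: ModelParams) -> np.ndarray:
    x = np.asarray(state, dtype=np.float64)
    if x.shape != (10,):
        raise ValueError(f"coupled state must have dimension 10, got {x.shape}")
    return rhs(x, params)


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` at ``state`` (5x5 or 10x10)."""
    x = np.asarray(state, dtype=np.float64)
    if x.shape != (5,) and x.shape != (10,):
        raise ValueError(f"state must have dimension 5 or 10, got shape {x.shape}")
    J = np.empty((x.size, x.size))
    _kernels.jac(x, params.to_vector(), J)
    return J
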