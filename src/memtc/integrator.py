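"""Fixed-step fourth-order Runge-Kutta integration.

Two entry points share the same classical RK4 scheme:

* :func:`rk4_integrate` — generic, takes any Python callable
  ``rhs(x) -> dx/dt`` (used for convergence tests and toy systems);
* :func:`simulate` / :func:`settle_to_attractor` — the fast path for the
  thalamocortical model, running a numba-compiled kernel.

Time is in seconds throughout, so spectral analysis downstream reports
frequencies directly in Hz.  Default protocol: 30 s horizon, 0.05 ms
step, 20 s transient discard, 1 ms recording (record_stride=20; 500 Hz
Nyquist, ample for the model's < 20 Hz rhythms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels
from .model_core import DEFAULT_IC, channel_names, state_dim
from .params import ModelParams

__all__ = [
    "Trajectory",
    "DivergenceError",
    "rk4_integrate",
    "simulate",
    "settle_to_attractor",
    "DEFAULT_DT",
    "DEFAULT_STRIDE",
    "DEFAULT_T_TOTAL",
    "DEFAULT_T_TRANSIENT",
]

DEFAULT_DT = 5e-5
DEFAULT_STRIDE = 20
DEFAULT_T_TOTAL = 30.0
DEFAULT_T_TRANSIENT = 20.0


class DivergenceError(RuntimeError):
    """Raised when the integrated state becomes non-finite (or explodes)."""

    def __init__(self, t_blowup: float):
        super().__init__(f"trajectory diverged at t = {t_blowup:.6g} s")
        self.t_blowup = t_blowup


@dataclass
class Trajectory:
    """Uniformly sampled time course with transient bookkeeping."""

    times: np.ndarray                 # seconds, strictly increasing, uniform
    states: np.ndarray                # (n_samples, dim)
    dt: float                         # integration step (s)
    record_stride: int = 1
    transient_cutoff: float = 0.0     # samples before this time are transient
    channels: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
                raise ValueError("times must be strictly increasing and uniform")
        if not 0 <= self.transient_cutoff < self.times[-1] + 1e-12:
            raise ValueError("transient_cutoff must lie within the time span")
        if not self.channels:
            dim = self.states.shape[1]
            self.channels = channel_names(dim // 5) if dim % 5 == 0 else tuple(
                f"x{i}" for i in range(dim))

    @property
    def sample_dt(self) -> float:
        return self.dt * self.record_stride

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"unknown channel {name!r}; have {list(self.channels)}")
        return self.states[:, list(self.channels).index(name)]

    def post_transient(self, name: str):
        """(times, values) of a channel after the transient cutoff."""
        m = self.times >= self.transient_cutoff
        return self.times[m], self.channel(name)[m]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, **{c: self.states[:, i] for i, c in enumerate(self.channels)}}
        )


def rk4_integrate(
    rhs: Callable[[np.ndarray], np.ndarray],
    x0,
    t_end: float,
    dt: float,
    record_stride: int = 1,
) -> Trajectory:
    """Classical RK4 over [0, t_end] for an arbitrary autonomous field.

    Pure-Python loop: meant for small test systems, not the 30 s model
    protocol (use :func:`simulate` for that).
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    n_steps = int(round(t_end / dt))
    rec = [x.copy()]
    for i in range(n_steps):
        k1 = np.asarray(rhs(x))
        k2 = np.asarray(rhs(x + 0.5 * dt * k1))
        k3 = np.asarray(rhs(x + 0.5 * dt * k2))
        k4 = np.asarray(rhs(x + dt * k3))
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if (i + 1) % record_stride == 0:
            if not np.all(np.isfinite(x)):
                raise DivergenceError((i + 1) * dt)
            rec.append(x.copy())
    states = np.asarray(rec)
    times = np.arange(len(states)) * dt * record_stride
    return Trajectory(times, states, dt, record_stride,
                      channels=tuple(f"x{i}" for i in range(states.shape[1])))


def simulate(
    params: ModelParams,
    topology: int = 1,
    x0: Optional[np.ndarray] = None,
    t_end: float = DEFAULT_T_TOTAL,
    dt: float = DEFAULT_DT,
    record_stride: int = DEFAULT_STRIDE,
    transient_cutoff: float = 0.0,
) -> Trajectory:
    """Integrate the thalamocortical model with the compiled RK4 kernel."""
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    dim = state_dim(topology)
    if x0 is None:
        x0 = DEFAULT_IC(topology)
    x0 = np.asarray(x0, dtype=np.float64)
    if x0.shape != (dim,):
        raise ValueError(f"x0 must have dimension {dim} for topology {topology}")
    n_steps = int(round(t_end / dt))
    samples, n_rec, blew_at = _kernels.rk4_trajectory(
        params.to_vector(), x0, dt, n_steps, record_stride)
    if blew_at >= 0:
        raise DivergenceError(blew_at * dt)
    times = np.arange(n_rec) * dt * record_stride
    return Trajectory(times, samples, dt, record_stride,
                      transient_cutoff=transient_cutoff,
                      channels=channel_names(topology))


def settle_to_attractor(
    params: ModelParams,
    topology: int = 1,
    x0: Optional[np.ndarray] = None,
    t_total: float = DEFAULT_T_TOTAL,
    t_transient: float = DEFAULT_T_TRANSIENT,
    dt: float = DEFAULT_DT,
    record_stride: int = DEFAULT_STRIDE,
) -> Trajectory:
    """Standard protocol: integrate t_total seconds, mark t_transient as
    transient so downstream analysis sees only the settled response."""
    if not t_transient < t_total:
        raise ValueError("t_transient must be smaller than t_total")
    return simulate(params, topology, x0, t_total, dt, record_stride,
                    transient_cutoff=t_transient)
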