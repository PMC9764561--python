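"""Equilibrium and limit-cycle bifurcation analysis.

Native continuation machinery (no external continuation package):

* Newton equilibrium solving with the analytic Jacobian;
* pseudo-arclength equilibrium continuation in one parameter;
* Hopf detection by sign changes of the largest real part among complex
  eigenvalue pairs, refined by bisection in the parameter;
* single-shooting limit cycles with a pyramidal phase anchor, Floquet
  multipliers from the monodromy matrix (RK4 on the variational
  equations);
* cycle continuation flagging fold-of-cycles (LPC: a non-trivial real
  multiplier at +1, equivalently a fold of the branch in the parameter)
  and torus (TR: a complex multiplier pair crossing the unit circle)
  bifurcations; a multiplier crossing -1 (period doubling) is reported
  as OTHER rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .integrator import DEFAULT_STRIDE, Trajectory
from .model_core import DEFAULT_IC, state_dim
from .params import ModelParams
from .waveform_analysis import DEFAULT_THRESHOLDS, dominant_frequency

__all__ = [
    "ConvergenceError",
    "SingularJacobianError",
    "NoCycleError",
    "EquilibriumPoint",
    "EquilibriumBranch",
    "CyclePoint",
    "CycleBranch",
    "BifurcationPoint",
    "find_equilibrium",
    "find_all_equilibria",
    "continue_equilibria",
    "detect_hopf",
    "shoot_limit_cycle",
    "continue_cycles",
    "nontrivial_multipliers",
    "classify_multipliers",
]

RESIDUAL_TOL = 1e-10
HOPF_IM_TOL = 1e-6
HOPF_PARAM_TOL = 1e-4
CYCLE_PARAM_TOL = 1e-3
TRIVIAL_MULT_TOL = 1e-3


class ConvergenceError(RuntimeError):
    pass


class SingularJacobianError(RuntimeError):
    pass


class NoCycleError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# equilibria
# --------------------------------------------------------------------------

@dataclass
class EquilibriumPoint:
    param: float
    state: np.ndarray
    eigenvalues: np.ndarray
    residual: float

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0))


@dataclass
class EquilibriumBranch:
    param_name: str
    points: List[EquilibriumPoint]
    status: str = "ok"   # "ok" | "truncated"

    @property
    def params(self) -> np.ndarray:
        return np.array([p.param for p in self.points])


@dataclass
class BifurcationPoint:
    kind: str            # "HB" | "LPC" | "TR" | "OTHER"
    param: float
    state: np.ndarray
    diagnostic: complex  # crossing eigenvalue or multiplier


def _newton(x0: np.ndarray, pvec: np.ndarray, tol: float = RESIDUAL_TOL,
            max_iter: int = 100) -> Tuple[np.ndarray, float]:
    dim = x0.size
    x = x0.astype(np.float64).copy()
    f = np.empty(dim)
    J = np.empty((dim, dim))
    _kernels.rhs(x, pvec, f)
    res = float(np.max(np.abs(f)))
    for _ in range(max_iter):
        if res < tol:
            return x, res
        _kernels.jac(x, pvec, J)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise SingularJacobianError("singular Jacobian in Newton iteration") from exc
        # backtracking line search on the residual norm
        lam = 1.0
        for _ in range(40):
            xn = x + lam * step
            _kernels.rhs(xn, pvec, f)
            rn = float(np.max(np.abs(f)))
            if rn < res or rn < tol:
                x, res = xn, rn
                break
            lam *= 0.5
        else:
            raise ConvergenceError("Newton line search stalled")
    if res < tol:
        return x, res
    raise ConvergenceError(f"Newton did not reach tolerance (residual {res:.3g})")


def find_equilibrium(params: ModelParams, topology: int = 1,
                     guess: Optional[np.ndarray] = None,
                     param_value: float = np.nan) -> EquilibriumPoint:
    """Newton equilibrium with analytic Jacobian; residual < 1e-10."""
    dim = state_dim(topology)
    if guess is None:
        guess = DEFAULT_IC(topology)
    guess = np.asarray(guess, dtype=np.float64)
    if guess.shape != (dim,):
        raise ValueError(f"guess must have dimension {dim}")
    if not np.all(np.isfinite(guess)):
        raise ValueError("guess must be finite")
    pvec = params.to_vector()
    try:
        x, res = _newton(guess, pvec)
    except ConvergenceError:
        # steep sigmoids can defeat plain damped Newton from a far guess;
        # globalize with Powell's dogleg, then polish back to the contract
        from scipy.optimize import root

        def f_only(y):
            out = np.empty(dim)
            _kernels.rhs(y, pvec, out)
            return out

        def j_only(y):
            Jm = np.empty((dim, dim))
            _kernels.jac(y, pvec, Jm)
            return Jm

        sol = root(f_only, guess, jac=j_only, method="hybr")
        if not sol.success:
            raise ConvergenceError(
                f"no equilibrium from this guess ({sol.message})")
        x, res = _newton(sol.x, pvec)
    J = np.empty((dim, dim))
    _kernels.jac(x, pvec, J)
    return EquilibriumPoint(param=param_value, state=x,
                            eigenvalues=np.linalg.eigvals(J), residual=res)


def find_all_equilibria(params: ModelParams, topology: int = 1,
                        box: Tuple[float, float] = (-2.0, 2.0),
                        n_grid: int = 3, dedup_tol: float = 1e-6
                        ) -> List[EquilibriumPoint]:
    """Multi-start Newton root scan over a state box.

    For the coupled topology the one-way structure is exploited:
    compartment-1 equilibria are found first, then the full system is
    solved from grids of compartment-2 starts conditioned on each.
    """
    grid = np.linspace(box[0], box[1], n_grid)
    lam_ratio = params.lambda1 / params.lambda2

    def scan(dim5_starts, make_guess):
        found: List[EquilibriumPoint] = []
        for s in dim5_starts:
            try:
                eq = find_equilibrium(params, topology, make_guess(s))
            except (ConvergenceError, SingularJacobianError):
                continue
            if not any(np.max(np.abs(eq.state - q.state)) < dedup_tol for q in found):
                found.append(eq)
        return found

    starts5 = [np.array([a, b, c, d, lam_ratio * a])
               for a in grid for b in grid for c in grid for d in grid]
    if topology == 1:
        return scan(starts5, lambda s: s)
    comp1 = find_all_equilibria(params, 1, box, n_grid, dedup_tol)
    out: List[EquilibriumPoint] = []
    for e1 in comp1:
        for eq in scan(starts5, lambda s, e1=e1: np.concatenate([e1.state, s])):
            if not any(np.max(np.abs(eq.state - q.state)) < dedup_tol for q in out):
                out.append(eq)
    return out


def _solve_at(params: ModelParams, param_name: str, value: float,
              topology: int, guess: np.ndarray) -> EquilibriumPoint:
    p = params.replace(**{param_name: value})
    return find_equilibrium(p, topology, guess, param_value=value)


def continue_equilibria(param_name: str, prange: Tuple[float, float],
                        params: ModelParams, topology: int = 1,
                        guess: Optional[np.ndarray] = None,
                        initial_step: Optional[float] = None,
                        max_step: Optional[float] = None,
                        min_step: float = 1e-8,
                        start_at: str = "lo") -> EquilibriumBranch:
    """Pseudo-arclength continuation of an equilibrium branch.

    A secant predictor in (state, parameter) space with a Newton corrector
    on the extended system (vector field + arclength constraint) tracks
    the branch through folds; the step adapts by halving on corrector
    failure.  Returns the branch in traversal order (monotone in the
    parameter away from folds); ``start_at='hi'`` scans in the reversed
    direction.
    """
    lo, hi = float(prange[0]), float(prange[1])
    if not lo < hi:
        raise ValueError("prange must satisfy lo < hi")
    if start_at not in ("lo", "hi"):
        raise ValueError("start_at must be 'lo' or 'hi'")
    sgn = 1.0 if start_at == "lo" else -1.0
    k_start, k_stop = (lo, hi) if start_at == "lo" else (hi, lo)
    span = hi - lo
    h = initial_step if initial_step is not None else span / 200.0
    h_max = max_step if max_step is not None else span / 100.0

    if guess is None:
        guess = DEFAULT_IC(topology)
    try:
        start = _solve_at(params, param_name, k_start, topology, guess)
    except (ConvergenceError, SingularJacobianError):
        cands = find_all_equilibria(params.replace(**{param_name: k_start}), topology)
        if not cands:
            raise ConvergenceError(
                f"no starting equilibrium found at {param_name} = {k_start}")
        start = cands[0]
        start.param = k_start
    points = [start]
    dim = start.state.size
    pvec_template = params.to_vector()
    kindex = list(params_vector_index(param_name))

    def fval(x, k):
        pv = pvec_template.copy()
        for i in kindex:
            pv[i] = k
        f = np.empty(dim)
        _kernels.rhs(x, pv, f)
        return f, pv

    def corrector(xg, kg, tangent, x_prev, k_prev, ds):
        """Newton on [f(x,k); tangent . ((x,k)-(x_prev,k_prev)) - ds]."""
        x, k = xg.copy(), kg
        for _ in range(25):
            f, pv = fval(x, k)
            arc = tangent[:dim] @ (x - x_prev) + tangent[dim] * (k - k_prev) - ds
            res = max(np.max(np.abs(f)), abs(arc))
            if res < RESIDUAL_TOL:
                J = np.empty((dim, dim))
                _kernels.jac(x, pv, J)
                return x, k, J
            J = np.empty((dim, dim))
            _kernels.jac(x, pv, J)
            dk = 1e-7 * max(1.0, abs(k))
            f2, _ = fval(x, k + dk)
            dfdk = (f2 - f) / dk
            A = np.zeros((dim + 1, dim + 1))
            A[:dim, :dim] = J
            A[:dim, dim] = dfdk
            A[dim, :dim] = tangent[:dim]
            A[dim, dim] = tangent[dim]
            rhs_full = -np.concatenate([f, [arc]])
            try:
                d = np.linalg.solve(A, rhs_full)
            except np.linalg.LinAlgError:
                return None
            x = x + d[:dim]
            k = k + d[dim]
        return None

    # initial tangent: pure parameter direction
    tangent = np.zeros(dim + 1)
    tangent[dim] = sgn
    x_prev, k_prev = start.state, k_start
    status = "ok"
    while sgn * (k_stop - k_prev) > 1e-12:
        ds = min(h, abs(k_stop - k_prev) / max(abs(tangent[dim]), 1e-3))
        ds = min(ds, h_max)
        sol = corrector(x_prev + ds * tangent[:dim], k_prev + ds * tangent[dim],
                        tangent, x_prev, k_prev, ds)
        if sol is None:
            if h > min_step:
                h *= 0.5
                continue
            status = "truncated"
            break
        x, k, J = sol
        new = np.concatenate([x - x_prev, [k - k_prev]])
        nrm = np.linalg.norm(new)
        if nrm > 0:
            tangent = new / nrm
        eigs = np.linalg.eigvals(J)
        f, _ = fval(x, k)
        points.append(EquilibriumPoint(param=k, state=x, eigenvalues=eigs,
                                       residual=float(np.max(np.abs(f)))))
        x_prev, k_prev = x, k
        h = min(h * 1.3, h_max)
        if len(points) > 100000:
            status = "truncated"
            break
    return EquilibriumBranch(param_name=param_name, points=points, status=status)


def params_vector_index(param_name: str):
    """Indices of a model parameter inside the flat kernel vector."""
    from .params import PARAM_VECTOR_FIELDS

    if param_name not in PARAM_VECTOR_FIELDS or param_name == "log_sigmoid_base":
        raise ValueError(f"cannot continue in parameter {param_name!r}")
    return (PARAM_VECTOR_FIELDS.index(param_name),)


def _max_re_complex(eigs: np.ndarray) -> float:
    c = eigs[np.abs(eigs.imag) > HOPF_IM_TOL]
    return float(c.real.max()) if len(c) else -np.inf


def detect_hopf(branch: EquilibriumBranch, params: ModelParams,
                topology: int = 1, tol: float = HOPF_PARAM_TOL
                ) -> List[BifurcationPoint]:
    """Hopf points: a complex eigenvalue pair crossing the imaginary axis.

    Sign changes of the largest real part over complex pairs between
    consecutive branch points are refined by bisection in the parameter;
    real-eigenvalue crossings are excluded by construction.
    """
    if len(branch.points) < 2:
        raise ValueError("branch needs at least 2 points")
    out: List[BifurcationPoint] = []
    pts = branch.points
    for a, b in zip(pts[:-1], pts[1:]):
        ga, gb = _max_re_complex(a.eigenvalues), _max_re_complex(b.eigenvalues)
        if not (np.isfinite(ga) and np.isfinite(gb)) or ga * gb >= 0:
            continue
        lo_k, hi_k = a.param, b.param
        lo_g = ga
        x_guess = a.state.copy()
        eq_mid = None
        while abs(hi_k - lo_k) > tol:
            mid = 0.5 * (lo_k + hi_k)
            try:
                eq_mid = _solve_at(params, branch.param_name, mid, topology, x_guess)
            except (ConvergenceError, SingularJacobianError):
                break
            gm = _max_re_complex(eq_mid.eigenvalues)
            x_guess = eq_mid.state
            if lo_g * gm <= 0:
                hi_k = mid
            else:
                lo_k, lo_g = mid, gm
        k_star = 0.5 * (lo_k + hi_k)
        try:
            eq_star = _solve_at(params, branch.param_name, k_star, topology, x_guess)
        except (ConvergenceError, SingularJacobianError):
            eq_star = eq_mid if eq_mid is not None else a
        eigs = eq_star.eigenvalues
        cplx = eigs[np.abs(eigs.imag) > HOPF_IM_TOL]
        crossing = cplx[np.argmax(cplx.real)] if len(cplx) else complex(np.nan)
        out.append(BifurcationPoint(kind="HB", param=k_star, state=eq_star.state,
                                    diagnostic=complex(crossing)))
    return out


# --------------------------------------------------------------------------
# limit cycles
# --------------------------------------------------------------------------

@dataclass
class CyclePoint:
    param: float
    anchor: np.ndarray
    period: float
    multipliers: np.ndarray
    residual: float
    py_amplitude: float

    @property
    def stable(self) -> bool:
        return bool(np.all(np.abs(nontrivial_multipliers(self.multipliers)) < 1.0))


@dataclass
class CycleBranch:
    param_name: str
    points: List[CyclePoint]
    status: str = "ok"


def nontrivial_multipliers(multipliers: np.ndarray) -> np.ndarray:
    """Drop the trivial Floquet multiplier (the one closest to +1)."""
    i = int(np.argmin(np.abs(multipliers - 1.0)))
    return np.delete(multipliers, i)


def _shoot(pvec: np.ndarray, x0: np.ndarray, T0: float, dt: float,
           tol: float = 1e-9, max_iter: int = 30,
           period_bounds: Tuple[float, float] = (0.02, 10.0),
           min_amplitude: float = 1e-4):
    """Newton single shooting on (anchor, period) with a PY-extremum phase
    anchor (dPY/dt = 0 at the section)."""
    dim = x0.size
    x, T = x0.copy(), float(T0)
    for _ in range(max_iter):
        if not period_bounds[0] <= T <= period_bounds[1]:
            raise NoCycleError(f"period {T:.4g} s outside plausible range")
        xT, M, py_lo, py_hi = _kernels.flow_with_monodromy(pvec, x, T, dt)
        f0 = np.empty(dim)
        _kernels.rhs(x, pvec, f0)
        res_vec = np.concatenate([xT - x, [f0[0]]])
        res = float(np.max(np.abs(res_vec)))
        if res < tol:
            if py_hi - py_lo < min_amplitude:
                raise NoCycleError("shooting collapsed onto an equilibrium")
            return x, T, M, res, py_hi - py_lo
        fT = np.empty(dim)
        _kernels.rhs(xT, pvec, fT)
        J0 = np.empty((dim, dim))
        _kernels.jac(x, pvec, J0)
        A = np.zeros((dim + 1, dim + 1))
        A[:dim, :dim] = M - np.eye(dim)
        A[:dim, dim] = fT
        A[dim, :dim] = J0[0]
        try:
            d = np.linalg.solve(A, -res_vec)
        except np.linalg.LinAlgError as exc:
            raise NoCycleError("singular shooting system") from exc
        x = x + d[:dim]
        T = T + d[dim]
    raise NoCycleError("shooting Newton did not converge")


def _seed_from_trajectory(traj: Trajectory, pvec: np.ndarray):
    from scipy.signal import find_peaks

    t, py = traj.post_transient(traj.channels[0])
    m = traj.times >= traj.transient_cutoff
    states = traj.states[m]
    amp = py.max() - py.min()
    if amp < 1e-4:
        raise NoCycleError("seed trajectory shows no post-transient oscillation")
    freq = dominant_frequency(traj, traj.channels[0])
    if freq <= 0:
        raise NoCycleError("seed trajectory has no dominant frequency")
    peaks, _ = find_peaks(py, prominence=0.25 * amp)
    if len(peaks) == 0:
        raise NoCycleError("no anchor extremum found in seed trajectory")
    i = peaks[len(peaks) // 2]
    return states[i].copy(), 1.0 / freq


def shoot_limit_cycle(params: ModelParams, topology: int = 1,
                      seed_traj: Optional[Trajectory] = None,
                      anchor: Optional[np.ndarray] = None,
                      period: Optional[float] = None,
                      dt: float = 1e-4,
                      param_value: float = np.nan) -> CyclePoint:
    """Locate a periodic orbit by single shooting and return its Floquet
    multipliers (eigenvalues of the monodromy matrix)."""
    pvec = params.to_vector()
    if anchor is None or period is None:
        if seed_traj is None:
            raise ValueError("provide either seed_traj or (anchor, period)")
        anchor, period = _seed_from_trajectory(seed_traj, pvec)
    anchor = np.asarray(anchor, dtype=np.float64)
    if anchor.shape != (state_dim(topology),):
        raise ValueError("anchor dimension does not match topology")
    x, T, M, res, amp = _shoot(pvec, anchor, period, dt)
    return CyclePoint(param=param_value, anchor=x, period=T,
                      multipliers=np.linalg.eigvals(M), residual=res,
                      py_amplitude=amp)


def classify_multipliers(prev: np.ndarray, curr: np.ndarray,
                         tol: float = 1e-9) -> Optional[str]:
    """Crossing of the unit circle by non-trivial multipliers between two
    consecutive cycle points: 'LPC' (real through +1), 'OTHER' (real
    through -1, period doubling), 'TR' (complex pair through |mu| = 1)."""
    a = nontrivial_multipliers(prev)
    b = nontrivial_multipliers(curr)

    def real_near(mu, target):
        real = mu[np.abs(mu.imag) < 1e-6].real
        return real[np.argmin(np.abs(real - target))] if len(real) else None

    ra, rb = real_near(a, 1.0), real_near(b, 1.0)
    if ra is not None and rb is not None and (ra - 1.0) * (rb - 1.0) < -tol:
        return "LPC"
    ra, rb = real_near(a, -1.0), real_near(b, -1.0)
    if ra is not None and rb is not None and (ra + 1.0) * (rb + 1.0) < -tol:
        return "OTHER"

    def cplx_mod(mu):
        c = mu[np.abs(mu.imag) >= 1e-6]
        return np.max(np.abs(c)) if len(c) else None

    ca, cb = cplx_mod(a), cplx_mod(b)
    if ca is not None and cb is not None and (ca - 1.0) * (cb - 1.0) < -tol:
        return "TR"
    return None


def continue_cycles(param_name: str, target: float, params: ModelParams,
                    topology: int = 1, seed: Optional[CyclePoint] = None,
                    seed_traj: Optional[Trajectory] = None,
                    start_value: Optional[float] = None,
                    step: float = 0.02, min_step: float = 1e-4,
                    max_step: float = 0.05, dt: float = 1e-4,
                    param_tol: float = CYCLE_PARAM_TOL
                    ) -> Tuple[CycleBranch, List[BifurcationPoint]]:
    """Continue a periodic orbit in one parameter, flagging LPC and TR.

    Natural continuation with adaptive steps.  A fold of cycles manifests
    either as a non-trivial real multiplier crossing +1 between accepted
    points, or as total loss of corrector convergence at the minimum step;
    in the latter case the branch end is refined by bisection on
    shootability and reported as an LPC (the branch folds there).
    """
    if start_value is None:
        start_value = getattr(params, param_name)
    if seed is None:
        if seed_traj is None:
            raise ValueError("provide seed or seed_traj")
        seed = shoot_limit_cycle(params.replace(**{param_name: start_value}),
                                 topology, seed_traj=seed_traj, dt=dt,
                                 param_value=start_value)
    seed.param = start_value
    points = [seed]
    events: List[BifurcationPoint] = []
    direction = 1.0 if target >= start_value else -1.0
    h = abs(step)
    k = start_value
    x, T = seed.anchor.copy(), seed.period
    status = "ok"

    def try_shoot(kv, xg, Tg):
        p = params.replace(**{param_name: kv})
        return shoot_limit_cycle(p, topology, anchor=xg, period=Tg, dt=dt,
                                 param_value=kv)

    while direction * (target - k) > 1e-12:
        kn = k + direction * min(h, abs(target - k))
        try:
            cp = try_shoot(kn, x, T)
        except NoCycleError:
            if h > min_step:
                h *= 0.5
                continue
            # corrector lost at minimum step: bisect on shootability
            lo_k, hi_k = k, kn
            cp_edge = points[-1]
            while abs(hi_k - lo_k) > param_tol:
                mid = 0.5 * (lo_k + hi_k)
                try:
                    cp_mid = try_shoot(mid, cp_edge.anchor, cp_edge.period)
                except NoCycleError:
                    hi_k = mid
                else:
                    lo_k, cp_edge = mid, cp_mid
                    points.append(cp_mid)
            mu = nontrivial_multipliers(cp_edge.multipliers)
            diag = mu[np.argmin(np.abs(mu - 1.0))] if len(mu) else complex(np.nan)
            events.append(BifurcationPoint(kind="LPC", param=0.5 * (lo_k + hi_k),
                                           state=cp_edge.anchor,
                                           diagnostic=complex(diag)))
            status = "truncated"
            break
        kind = classify_multipliers(points[-1].multipliers, cp.multipliers)
        if kind is not None:
            k_ev = _refine_multiplier_crossing(
                try_shoot, points[-1], cp, kind, param_tol)
            events.append(BifurcationPoint(kind=kind, param=k_ev,
                                           state=cp.anchor,
                                           diagnostic=_crossing_diag(cp, kind)))
        points.append(cp)
        k, x, T = kn, cp.anchor.copy(), cp.period
        h = min(h * 1.3, max_step)
    # merge events of the same kind that localize the same bifurcation
    merged: List[BifurcationPoint] = []
    for ev in sorted(events, key=lambda e: e.param):
        if merged and merged[-1].kind == ev.kind and \
                abs(merged[-1].param - ev.param) <= 10 * param_tol:
            merged[-1] = BifurcationPoint(
                kind=ev.kind, param=0.5 * (merged[-1].param + ev.param),
                state=ev.state, diagnostic=ev.diagnostic)
        else:
            merged.append(ev)
    return CycleBranch(param_name=param_name, points=points, status=status), merged


def _crossing_diag(cp: CyclePoint, kind: str) -> complex:
    mu = nontrivial_multipliers(cp.multipliers)
    if len(mu) == 0:
        return complex(np.nan)
    if kind == "LPC":
        return complex(mu[np.argmin(np.abs(mu - 1.0))])
    if kind == "OTHER":
        return complex(mu[np.argmin(np.abs(mu + 1.0))])
    c = mu[np.abs(mu.imag) >= 1e-6]
    return complex(c[np.argmax(np.abs(c))]) if len(c) else complex(np.nan)


def _refine_multiplier_crossing(try_shoot, a: CyclePoint, b: CyclePoint,
                                kind: str, tol: float) -> float:
    lo, hi = a, b
    while abs(hi.param - lo.param) > tol:
        mid_k = 0.5 * (lo.param + hi.param)
        try:
            mid = try_shoot(mid_k, lo.anchor, lo.period)
        except NoCycleError:
            break
        if classify_multipliers(lo.multipliers, mid.multipliers) == kind:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo.param + hi.param)
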