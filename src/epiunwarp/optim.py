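"""Minimizers for the field-map objective.

Three interchangeable solvers share the Armijo line search and stopping
logic:

* :func:`gauss_newton` (default) — outer Gauss-Newton iterations whose
  linearized normal equations are solved approximately by a few Jacobi-
  preconditioned conjugate-gradient steps.
* :func:`admm` — consensus splitting that keeps the data term, barrier and
  PE smoothness in a per-column subproblem (solved by one GN step with a
  column-parallel PCG) and moves the cross-column smoothness into a
  quadratic consensus variable updated by FFT Laplacian solves.
* :func:`lbfgs` — limited-memory BFGS on the explicit gradient, as a
  structure-agnostic baseline.

All three reject infeasible trial points (the barrier makes them J = inf),
so every accepted iterate satisfies max |db/dpe| < 1.  The optimizers are
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable

import numpy as np

from .geometry import FieldMap, OppositePair
from .objective import LossConfig, LossState, evaluate
from .operators import diff_pe, solve_shifted_lap2d

__all__ = [
    "OptimizerOptions",
    "OptimizerResult",
    "armijo",
    "pcg",
    "block_pcg",
    "gauss_newton",
    "admm",
    "lbfgs",
]


@dataclass
class OptimizerOptions:
    """Shared knobs; per-optimizer outer-iteration caps where noted."""

    max_outer_iters: int | None = None  # defaults: GN 50, ADMM 200, LBFGS 500
    tol_grad: float = 1e-2              # relative to the initial gradient norm
    tol_loss_change: float = 1e-4       # relative
    tol_field_change: float = 1e-4      # relative
    pcg_max_iters: int = 10
    pcg_rel_residual: float = 0.1
    armijo_c1: float = 1e-4
    armijo_shrink: float = 0.5
    armijo_max_backtracks: int = 12
    admm_rho_init: float = 1e3
    admm_mu: float = 10.0
    admm_tau: float = 2.0
    lbfgs_memory: int = 10


@dataclass
class OptimizerResult:
    field: FieldMap
    history: list[dict] = dataclass_field(default_factory=list)
    stop_reason: str = "max_iter"


def armijo(
    eval_J: Callable[[np.ndarray], float],
    b: np.ndarray,
    q: np.ndarray,
    g: np.ndarray,
    opts: OptimizerOptions,
    J0: float | None = None,
) -> tuple[float, float] | None:
    """Backtracking line search with the sufficient-decrease condition.

    Returns ``(step, J_at_step)`` or ``None`` if no acceptable step exists
    within the backtracking budget.  Trial points where the objective is
    infinite (barrier violations) are simply backtracked past.
    """
    slope = float(np.vdot(g, q))
    if slope >= 0:
        raise ValueError("armijo requires a descent direction (g^T q < 0)")
    if J0 is None:
        J0 = eval_J(b)
    gamma = 1.0
    for _ in range(opts.armijo_max_backtracks + 1):
        J_trial = eval_J(b + gamma * q)
        if np.isfinite(J_trial) and J_trial <= J0 + opts.armijo_c1 * gamma * slope:
            return gamma, J_trial
        gamma *= opts.armijo_shrink
    return None


def pcg(
    matvec: Callable[[np.ndarray], np.ndarray],
    rhs: np.ndarray,
    precond_diagonal: np.ndarray | None = None,
    max_iters: int = 10,
    rel_res: float = 0.1,
) -> tuple[np.ndarray, int]:
    """Jacobi-preconditioned conjugate gradients with early stopping.

    Stops when ``||r_k|| / ||rhs|| < rel_res`` or after ``max_iters``
    iterations, whichever comes first.  Returns (solution, iterations).
    """
    rhs_norm = float(np.linalg.norm(rhs))
    x = np.zeros_like(rhs)
    if rhs_norm == 0.0:
        return x, 0
    diag = np.ones_like(rhs) if precond_diagonal is None else precond_diagonal
    r = rhs.copy()
    z = r / diag
    p = z.copy()
    rz = float(np.vdot(r, z))
    k = 0
    for k in range(1, max_iters + 1):
        ap = matvec(p)
        pap = float(np.vdot(p, ap))
        if not np.isfinite(pap) or pap <= 0:
            raise FloatingPointError("PCG encountered a non-SPD system")
        alpha = rz / pap
        x += alpha * p
        r -= alpha * ap
        if float(np.linalg.norm(r)) / rhs_norm < rel_res:
            break
        z = r / diag
        rz_new = float(np.vdot(r, z))
        p = z + (rz_new / rz) * p
        rz = rz_new
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("PCG produced non-finite values")
    return x, k


def block_pcg(
    matvec: Callable[[np.ndarray], np.ndarray],
    rhs: np.ndarray,
    precond_diagonal: np.ndarray,
    max_iters: int = 10,
    rel_res: float = 0.1,
) -> tuple[np.ndarray, float]:
    """PCG run independently per PE column (last axis), vectorized.

    ``matvec`` must be column-separable; each column carries its own step
    sizes and stopping test, and converged columns freeze while the rest
    continue.  Returns (solution, mean iterations per column).
    """
    def cdot(a, b):
        return np.sum(a * b, axis=2, keepdims=True)

    rhs_norm = np.sqrt(cdot(rhs, rhs))
    x = np.zeros_like(rhs)
    active = rhs_norm > 0
    if not active.any():
        return x, 0.0
    r = rhs.copy()
    z = r / precond_diagonal
    p = z.copy()
    rz = cdot(r, z)
    iters = np.zeros_like(rhs_norm)
    tiny = np.finfo(rhs.dtype).tiny
    for _ in range(max_iters):
        ap = matvec(p)
        pap = cdot(p, ap)
        alpha = np.where(active & (pap > 0), rz / np.maximum(pap, tiny), 0.0)
        x += alpha * p
        r -= alpha * ap
        iters += active
        resn = np.sqrt(cdot(r, r))
        active = active & (resn >= rel_res * rhs_norm)
        if not active.any():
            break
        z = r / precond_diagonal
        rz_new = cdot(r, z)
        beta = np.where(active, rz_new / np.maximum(rz, tiny), 0.0)
        p = z + beta * p
        rz = rz_new
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("block PCG produced non-finite values")
    return x, float(iters.mean())


def _record(history, it, state: LossState, step, inner):
    history.append(
        {
            "iter": it,
            "J": state.J,
            "D": state.D,
            "S": state.S,
            "P": state.P,
            "grad_norm": float(np.linalg.norm(state.gradient))
            if state.gradient is not None
            else np.nan,
            "step": step,
            "inner_iters": inner,
        }
    )


def gauss_newton(
    pair: OppositePair,
    b0: FieldMap,
    cfg: LossConfig | None = None,
    opts: OptimizerOptions | None = None,
) -> OptimizerResult:
    """Gauss-Newton with Jacobi-preconditioned CG inner solves (default)."""
    cfg = cfg or LossConfig()
    opts = opts or OptimizerOptions()
    max_iters = opts.max_outer_iters if opts.max_outer_iters is not None else 50

    b = b0.values.copy()
    state = evaluate(pair, _fm(b, b0), cfg)
    if not state.feasible:
        raise ValueError("initial field map is infeasible (|db/dpe| >= 1 somewhere)")
    g0 = float(np.linalg.norm(state.gradient))
    history: list[dict] = []
    _record(history, 0, state, 0.0, 0)
    stop = "max_iter"

    def eval_value(bb):
        return evaluate(pair, _fm(bb, b0), cfg, derivatives=False).J

    for it in range(1, max_iters + 1):
        gnorm = float(np.linalg.norm(state.gradient))
        if gnorm <= opts.tol_grad * max(g0, np.finfo(b.dtype).tiny):
            stop = "grad"
            break
        q, inner = pcg(
            state.hessian_matvec,
            -state.gradient,
            state.jacobi_diagonal,
            max_iters=opts.pcg_max_iters,
            rel_res=opts.pcg_rel_residual,
        )
        if float(np.vdot(state.gradient, q)) >= 0:
            stop = "line_search"
            break
        hit = armijo(eval_value, b, q, state.gradient, opts, J0=state.J)
        if hit is None:
            stop = "line_search"
            break
        gamma, J_new = hit
        b_new = b + gamma * q
        dloss = abs(state.J - J_new) / max(abs(state.J), 1.0)
        dfield = float(np.linalg.norm(b_new - b)) / max(float(np.linalg.norm(b)), 1.0)
        b = b_new
        state = evaluate(pair, _fm(b, b0), cfg)
        _record(history, it, state, gamma, inner)
        if dloss < opts.tol_loss_change:
            stop = "loss"
            break
        if dfield < opts.tol_field_change:
            stop = "field"
            break
    return OptimizerResult(field=_fm(b, b0), history=history, stop_reason=stop)


def _fm(values: np.ndarray, like: FieldMap) -> FieldMap:
    return FieldMap(values=values, voxel_sizes=like.voxel_sizes)


def lbfgs(
    pair: OppositePair,
    b0: FieldMap,
    cfg: LossConfig | None = None,
    opts: OptimizerOptions | None = None,
) -> OptimizerResult:
    """Two-loop-recursion LBFGS with Armijo backtracking."""
    cfg = cfg or LossConfig()
    opts = opts or OptimizerOptions()
    max_iters = opts.max_outer_iters if opts.max_outer_iters is not None else 500

    b = b0.values.copy()
    state = evaluate(pair, _fm(b, b0), cfg)
    if not state.feasible:
        raise ValueError("initial field map is infeasible (|db/dpe| >= 1 somewhere)")
    g = state.gradient
    g0 = float(np.linalg.norm(g))
    s_list: list[np.ndarray] = []
    y_list: list[np.ndarray] = []
    history: list[dict] = []
    _record(history, 0, state, 0.0, 0)
    stop = "max_iter"

    def eval_value(bb):
        return evaluate(pair, _fm(bb, b0), cfg, derivatives=False).J

    for it in range(1, max_iters + 1):
        gnorm = float(np.linalg.norm(g))
        if gnorm <= opts.tol_grad * max(g0, np.finfo(b.dtype).tiny):
            stop = "grad"
            break
        # two-loop recursion
        q = -g.copy()
        alphas = []
        for s, y in zip(reversed(s_list), reversed(y_list)):
            rho_i = 1.0 / float(np.vdot(y, s))
            a_i = rho_i * float(np.vdot(s, q))
            q -= a_i * y
            alphas.append((rho_i, a_i))
        if s_list:
            s, y = s_list[-1], y_list[-1]
            q *= float(np.vdot(s, y)) / float(np.vdot(y, y))
        else:
            # first iteration: unit-length steepest descent so the unit
            # trial step is not astronomically long on large objectives
            q /= max(gnorm, np.finfo(float).tiny)
        for (rho_i, a_i), (s, y) in zip(reversed(alphas), zip(s_list, y_list)):
            beta_i = rho_i * float(np.vdot(y, q))
            q += (a_i - beta_i) * s
        if float(np.vdot(g, q)) >= 0:
            q = -g / max(gnorm, np.finfo(float).tiny)
        hit = armijo(eval_value, b, q, g, opts, J0=state.J)
        if hit is None:
            stop = "line_search"
            break
        gamma, J_new = hit
        b_new = b + gamma * q
        new_state = evaluate(pair, _fm(b_new, b0), cfg)
        s_vec = b_new - b
        y_vec = new_state.gradient - g
        if float(np.vdot(s_vec, y_vec)) > 1e-12 * float(
            np.linalg.norm(s_vec) * np.linalg.norm(y_vec) + np.finfo(float).tiny
        ):
            s_list.append(s_vec)
            y_list.append(y_vec)
            if len(s_list) > opts.lbfgs_memory:
                s_list.pop(0)
                y_list.pop(0)
        dloss = abs(state.J - J_new) / max(abs(state.J), 1.0)
        dfield = float(np.linalg.norm(s_vec)) / max(float(np.linalg.norm(b)), 1.0)
        b, state, g = b_new, new_state, new_state.gradient
        _record(history, it, state, gamma, 0)
        if dloss < opts.tol_loss_change:
            stop = "loss"
            break
        if dfield < opts.tol_field_change:
            stop = "field"
            break
    return OptimizerResult(field=_fm(b, b0), history=history, stop_reason=stop)


def admm(
    pair: OppositePair,
    b0: FieldMap,
    cfg: LossConfig | None = None,
    opts: OptimizerOptions | None = None,
) -> OptimizerResult:
    """ADMM consensus splitting with column-parallel b-updates.

    Split: F(b) = D(b) + alpha*S_pe(b) + beta*P(b) (separable per PE
    column) and G(z) = alpha*(S_1 + S_2)(z) (cross-column smoothness), tied
    by b = z with scaled multiplier u.  The b-update takes one Gauss-Newton
    step whose normal equations decouple per column and are solved by
    :func:`block_pcg`; the z-update is a shifted 2D Laplacian solved
    slice-wise by FFT (periodic boundaries); rho adapts to balance the
    primal and dual residuals.
    """
    cfg = cfg or LossConfig()
    opts = opts or OptimizerOptions()
    max_iters = opts.max_outer_iters if opts.max_outer_iters is not None else 200

    h1, h2, h3 = pair.voxel_sizes
    hv = h1 * h2 * h3
    b = b0.values.copy()
    z = b.copy()
    u = np.zeros_like(b)
    rho = opts.admm_rho_init
    history: list[dict] = []
    state_full = evaluate(pair, _fm(b, b0), cfg)
    if not state_full.feasible:
        raise ValueError("initial field map is infeasible (|db/dpe| >= 1 somewhere)")
    _record(history, 0, state_full, 0.0, 0)
    stop = "max_iter"

    for it in range(1, max_iters + 1):
        # --- b update: one GN step on F(b) + (rho h3 / 2) ||b - z + u||^2
        state = evaluate(pair, _fm(b, b0), cfg, smooth_axes=(2,))
        grad_f = state.gradient + rho * h3 * (b - z + u)

        def matvec(x, _s=state):
            return _s.hessian_matvec(x) + rho * h3 * x

        diag = state.jacobi_diagonal + rho * h3
        q, inner = block_pcg(
            matvec, -grad_f, diag,
            max_iters=opts.pcg_max_iters, rel_res=opts.pcg_rel_residual,
        )

        def eval_f(bb):
            st = evaluate(pair, _fm(bb, b0), cfg, derivatives=False, smooth_axes=(2,))
            return st.J + 0.5 * rho * h3 * float(np.vdot(bb - z + u, bb - z + u))

        gamma = 0.0
        if float(np.vdot(grad_f, q)) < 0:
            f0 = state.J + 0.5 * rho * h3 * float(np.vdot(b - z + u, b - z + u))
            hit = armijo(eval_f, b, q, grad_f, opts, J0=f0)
            if hit is not None:
                gamma = hit[0]
        b_new = b + gamma * q

        # --- z update: (alpha hv L12 + rho h3 I) z = rho h3 (b + u)
        z_new = solve_shifted_lap2d(
            rho * h3 * (b_new + u), cfg.alpha * hv, rho * h3, spacings=(h1, h2)
        )

        # --- multiplier update and adaptive rho (Boyd et al. scheme)
        u_new = u + b_new - z_new
        primal = float(np.linalg.norm(b_new - z_new))
        dual = rho * h3 * float(np.linalg.norm(z_new - z))

        db = float(np.linalg.norm(b_new - b)) / max(float(np.linalg.norm(b)), 1.0)
        dz = float(np.linalg.norm(z_new - z)) / max(float(np.linalg.norm(z)), 1.0)
        du = float(np.linalg.norm(u_new - u)) / max(float(np.linalg.norm(u)), 1.0)
        b, z, u = b_new, z_new, u_new

        if primal > opts.admm_mu * dual:
            rho *= opts.admm_tau
            u /= opts.admm_tau
        elif dual > opts.admm_mu * primal:
            rho /= opts.admm_tau
            u *= opts.admm_tau

        state_full = evaluate(pair, _fm(b, b0), cfg, derivatives=False)
        history.append(
            {
                "iter": it,
                "J": state_full.J,
                "D": state_full.D,
                "S": state_full.S,
                "P": state_full.P,
                "grad_norm": np.nan,
                "step": gamma,
                "inner_iters": inner,
                "primal": primal,
                "dual": dual,
                "rho": rho,
            }
        )
        if max(db, dz, du) < opts.tol_field_change:
            stop = "bzu-change"
            break
    return OptimizerResult(field=_fm(b, b0), history=history, stop_reason=stop)
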