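"""Discretized field-map estimation objective J(b) = D(b) + a S(b) + B P(b).

* ``D`` is half the squared distance between the two oppositely corrected
  images (midpoint quadrature of the continuum SSD integral).
* ``S`` is the gradient-smoothness regularizer (h1 h2 h3 / 2) b^T H b with H
  the Neumann negative Laplacian on the staggered grid.
* ``P`` is the barrier (h1 h2 h3 / 2) sum phi(db/dpe) with
  phi(z) = z^4 / (1 - z^2) on (-1, 1) and infinity outside, enforcing that
  the intensity modulation 1 + db/dpe stays positive and the distortion
  stays invertible.

The gradient is assembled explicitly by the chain rule; the Hessian is the
Gauss-Newton approximation J_r^T J_r plus the exact (convex) regularizer
Hessians, exposed as a matrix-free matvec together with its diagonal for
Jacobi preconditioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .geometry import FieldMap, OppositePair, make_grid
from .operators import (
    average_pe,
    average_pe_adjoint,
    diff_pe,
    diff_pe_adjoint,
    interp1d_pe,
    smoothness_H,
    smoothness_H_diagonal,
)

__all__ = ["LossConfig", "LossState", "phi", "phi_prime", "phi_double_prime", "distance", "evaluate"]


@dataclass
class LossConfig:
    """Regularization weights: alpha (smoothness), beta (barrier)."""

    alpha: float = 300.0
    beta: float = 1e-4

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")


@dataclass
class LossState:
    """Objective value, components, and derivative machinery at one point."""

    J: float
    D: float
    S: float
    P: float
    residual: np.ndarray | None = None
    gradient: np.ndarray | None = None
    hessian_matvec: Callable[[np.ndarray], np.ndarray] | None = None
    jacobi_diagonal: np.ndarray | None = None

    @property
    def feasible(self) -> bool:
        return np.isfinite(self.J)


def _as_float(z):
    z = np.asarray(z)
    return z if np.issubdtype(z.dtype, np.floating) else z.astype(float)


def phi(z):
    """Barrier phi(z) = z^4 / (1 - z^2) for |z| < 1, +inf otherwise."""
    z = _as_float(z)
    out = np.full(z.shape, np.inf)
    ok = np.abs(z) < 1.0
    zz = z[ok]
    out[ok] = zz**4 / (1.0 - zz**2)
    return out if out.ndim else float(out)


def phi_prime(z):
    """phi'(z) = (4 z^3 - 2 z^5) / (1 - z^2)^2 on the feasible interval."""
    z = _as_float(z)
    return (4.0 * z**3 - 2.0 * z**5) / (1.0 - z**2) ** 2


def phi_double_prime(z):
    """phi''(z) = 2 z^2 (6 - 3 z^2 + z^4) / (1 - z^2)^3; nonnegative on (-1,1)."""
    z = _as_float(z)
    return 2.0 * z**2 * (6.0 - 3.0 * z**2 + z**4) / (1.0 - z**2) ** 3


def distance(pair: OppositePair, field: FieldMap) -> tuple[float, np.ndarray]:
    """SSD distance D(b) and the residual of the corrected images."""
    state = evaluate(pair, field, LossConfig(), derivatives=False)
    return state.D, state.residual


def evaluate(
    pair: OppositePair,
    field: FieldMap,
    cfg: LossConfig,
    *,
    derivatives: bool = True,
    smooth_axes: tuple[int, ...] = (0, 1, 2),
) -> LossState:
    """Evaluate J(b) and (optionally) its gradient and GN-Hessian handles.

    ``smooth_axes`` selects which axes contribute to the smoothness term;
    the ADMM splitting keeps only the PE part (axis 2) in its data
    subproblem and moves the cross-column part into the consensus variable.
    """
    h1, h2, h3 = pair.voxel_sizes
    hv = h1 * h2 * h3
    b = field.values
    dtype = b.dtype
    smooth_sizes = tuple(
        h if ax in smooth_axes else None for ax, h in enumerate(pair.voxel_sizes)
    )

    z = diff_pe(b, h3)
    if np.max(np.abs(z)) >= 1.0:
        # infeasible: the barrier is infinite and derivatives are undefined
        return LossState(J=np.inf, D=np.nan, S=np.nan, P=np.inf)

    centers_pe = make_grid(pair.plus).centers[2][None, None, :].astype(dtype)
    bc = average_pe(b)

    ip, dip = interp1d_pe(pair.plus, centers_pe + bc, derivative=True)
    im, dim = interp1d_pe(pair.minus, centers_pe - bc, derivative=True)
    mod_p = 1.0 + z
    mod_m = 1.0 - z
    r = ip * mod_p - im * mod_m

    D = 0.5 * hv * float(np.vdot(r, r))
    Hb = smoothness_H(b, smooth_sizes)
    S = 0.5 * hv * float(np.vdot(b, Hb))
    P = 0.5 * hv * float(np.sum(phi(z)))
    alpha, beta = cfg.alpha, cfg.beta
    J = D + alpha * S + beta * P
    if not derivatives:
        return LossState(J=J, D=D, S=S, P=P, residual=r)

    # residual Jacobian J_r = diag(w_avg) A + diag(w_diff) Dpe, where A is
    # node->center averaging and Dpe the node->center difference (1/h3)
    w_avg = dip * mod_p + dim * mod_m
    w_diff = ip + im

    def jr(x: np.ndarray) -> np.ndarray:
        return w_avg * average_pe(x) + w_diff * diff_pe(x, h3)

    def jr_t(y: np.ndarray) -> np.ndarray:
        return average_pe_adjoint(w_avg * y) + diff_pe_adjoint(w_diff * y, h3)

    pp = phi_prime(z)
    gradient = (
        hv * jr_t(r)
        + alpha * hv * Hb
        + beta * 0.5 * hv * diff_pe_adjoint(pp, h3)
    )

    ppp = phi_double_prime(z)

    def hessian_matvec(x: np.ndarray) -> np.ndarray:
        x = x.reshape(b.shape)
        out = hv * jr_t(jr(x))
        out += alpha * hv * smoothness_H(x, smooth_sizes)
        out += beta * 0.5 * hv * diff_pe_adjoint(ppp * diff_pe(x, h3), h3)
        return out

    # diagonal of J_r^T J_r: node j touches centers j-1 and j of its column;
    # the averaging stencil contributes +1/2, the difference +-1/h3
    gn_diag = np.zeros(b.shape, dtype=gradient.dtype)
    coeff_lower = 0.5 * w_avg + w_diff / h3   # center j-1 seen from node j
    coeff_upper = 0.5 * w_avg - w_diff / h3   # center j seen from node j
    gn_diag[:, :, 1:] += coeff_lower**2
    gn_diag[:, :, :-1] += coeff_upper**2

    bar_diag = np.zeros(b.shape, dtype=gradient.dtype)
    bar_diag[:, :, 1:] += ppp / h3**2
    bar_diag[:, :, :-1] += ppp / h3**2

    jacobi_diagonal = (
        hv * gn_diag
        + alpha * hv * smoothness_H_diagonal(b.shape, smooth_sizes, dtype=gradient.dtype)
        + beta * 0.5 * hv * bar_diag
    )

    return LossState(
        J=J,
        D=D,
        S=S,
        P=P,
        residual=r,
        gradient=gradient,
        hessian_matvec=hessian_matvec,
        jacobi_diagonal=jacobi_diagonal,
    )
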