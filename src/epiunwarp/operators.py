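"""Discrete linear operators of the staggered-grid discretization.

Everything here acts column-wise along the last (PE) axis or slice-wise and
is expressed with plain numpy vectorization, so a single call processes all
image columns at once.  Operators come in apply/adjoint pairs so the
objective's chain-rule gradient can be assembled without ever forming a
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.fft

from .geometry import FieldMap, ImageVolume

__all__ = [
    "LinearOperatorHandle",
    "interp1d_pe",
    "average_pe",
    "average_pe_adjoint",
    "diff_pe",
    "diff_pe_adjoint",
    "smoothness_H",
    "smoothness_H_diagonal",
    "smoothness_value",
    "gaussian_blur_333",
    "gaussian_kernel_333",
    "solve_shifted_lap2d",
]


@dataclass
class LinearOperatorHandle:
    """A matrix-free linear operator: apply, shapes, optional diagonal."""

    apply: Callable[[np.ndarray], np.ndarray]
    input_shape: tuple
    output_shape: tuple
    diagonal: Callable[[], np.ndarray] | None = None


def interp1d_pe(
    image: ImageVolume, query: np.ndarray, *, derivative: bool = False
):
    """Piecewise-linear interpolation of the image along each PE column.

    The image is modeled as piecewise linear between its cell-center samples
    at ``(k + 1/2) * h3``; ``query`` holds one PE coordinate (mm) per cell.
    Coordinates outside ``[first center, last center]`` evaluate to 0
    (background air).  With ``derivative=True`` also returns the slope of
    the active segment in intensity per mm; at an exact knot the left
    segment's slope is used, which makes the derivative deterministic.
    """
    query = np.asarray(query)
    if np.any(np.isnan(query)):
        raise ValueError("NaN in interpolation coordinates")
    data = image.data
    n3 = data.shape[2]
    h3 = image.voxel_sizes[2]
    if query.shape != data.shape:
        raise ValueError(f"query shape {query.shape} != image shape {data.shape}")

    t = query / h3 - 0.5  # fractional cell-center index
    inside = (t >= 0.0) & (t <= n3 - 1)
    k = np.floor(t).astype(np.int64)
    # ties at knots: take the left segment (value unchanged, slope from left)
    at_knot = (t == k) & (k > 0)
    k = np.where(at_knot, k - 1, k)
    k = np.clip(k, 0, n3 - 2)
    w = t - k.astype(t.dtype)

    lo = np.take_along_axis(data, k, axis=2)
    hi = np.take_along_axis(data, k + 1, axis=2)
    vals = np.where(inside, lo + w * (hi - lo), 0.0)
    if not derivative:
        return vals
    slope = np.where(inside, (hi - lo) / h3, 0.0)
    return vals, slope


def _check_staggered(values: np.ndarray) -> None:
    if values.ndim != 3 or values.shape[2] < 2:
        raise ValueError(f"expected a staggered (n1,n2,n3+1) array, got {values.shape}")


def average_pe(field: FieldMap | np.ndarray) -> np.ndarray:
    """Node-to-center averaging along PE: out[k] = (b[k] + b[k+1]) / 2."""
    b = field.values if isinstance(field, FieldMap) else np.asarray(field)
    _check_staggered(b)
    return 0.5 * (b[:, :, :-1] + b[:, :, 1:])


def average_pe_adjoint(centered: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`average_pe` (center-to-node half-spreading)."""
    y = np.asarray(centered)
    out = np.zeros(y.shape[:2] + (y.shape[2] + 1,), dtype=y.dtype)
    out[:, :, :-1] += 0.5 * y
    out[:, :, 1:] += 0.5 * y
    return out


def diff_pe(field: FieldMap | np.ndarray, h3: float | None = None) -> np.ndarray:
    """Node-to-center PE finite difference: out[k] = (b[k+1] - b[k]) / h3.

    The result is dimensionless (mm displacement differenced over mm); it is
    the discrete directional derivative entering the intensity modulation.
    """
    if isinstance(field, FieldMap):
        b = field.values
        if h3 is None:
            h3 = field.voxel_sizes[2]
    else:
        b = np.asarray(field)
    if h3 is None or h3 <= 0:
        raise ValueError(f"h3 must be positive, got {h3}")
    _check_staggered(b)
    return (b[:, :, 1:] - b[:, :, :-1]) / h3


def diff_pe_adjoint(centered: np.ndarray, h3: float) -> np.ndarray:
    """Adjoint of :func:`diff_pe`."""
    if h3 <= 0:
        raise ValueError(f"h3 must be positive, got {h3}")
    y = np.asarray(centered)
    out = np.zeros(y.shape[:2] + (y.shape[2] + 1,), dtype=y.dtype)
    out[:, :, :-1] -= y / h3
    out[:, :, 1:] += y / h3
    return out


def _axis_laplacian(b: np.ndarray, axis: int, h: float) -> np.ndarray:
    """D^T D along one axis with homogeneous Neumann boundaries."""
    d = np.diff(b, axis=axis) / h
    out = np.zeros_like(b)
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    out[tuple(sl_lo)] -= d / h
    out[tuple(sl_hi)] += d / h
    return out


def smoothness_H(field: FieldMap | np.ndarray, voxel_sizes=None) -> np.ndarray:
    """Apply the negative Laplacian H = sum_d D_d^T D_d on the staggered grid.

    Neumann boundaries: constants are in the null space, H is symmetric
    positive semi-definite, and b^T H b = sum_d ||D_d b||^2 exactly.
    """
    if isinstance(field, FieldMap):
        b = field.values
        if voxel_sizes is None:
            voxel_sizes = field.voxel_sizes
    else:
        b = np.asarray(field)
    if voxel_sizes is None:
        raise ValueError("voxel_sizes required for a bare array")
    _check_staggered(b)
    out = np.zeros(b.shape, dtype=np.result_type(b.dtype, np.float32))
    for axis, h in enumerate(voxel_sizes):
        if h is None:  # axis excluded (ADMM splitting)
            continue
        if h <= 0:
            raise ValueError(f"voxel sizes must be positive, got {voxel_sizes}")
        out += _axis_laplacian(b.astype(out.dtype, copy=False), axis, h)
    return out


def smoothness_H_diagonal(shape: tuple, voxel_sizes, dtype=float) -> np.ndarray:
    """Diagonal of H without assembling it (2/h^2 interior, 1/h^2 at faces)."""
    diag = np.zeros(shape, dtype=dtype)
    for axis, h in enumerate(voxel_sizes):
        if h is None:
            continue
        d = np.full(shape[axis], 2.0 / h**2)
        d[0] = d[-1] = 1.0 / h**2
        sl = [None] * 3
        sl[axis] = slice(None)
        diag += d[tuple(sl)]
    return diag


def smoothness_value(field: FieldMap) -> float:
    """S(b) = (h1 h2 h3 / 2) * b^T H b, the smoothness regularizer value."""
    hv = float(np.prod(field.voxel_sizes))
    b = field.values
    return 0.5 * hv * float(np.vdot(b, smoothness_H(field)))


def gaussian_kernel_333(sigma: float = 1.0) -> np.ndarray:
    """Normalized 3x3x3 sampled Gaussian kernel (sigma in voxel units)."""
    x = np.arange(-1, 2, dtype=float)
    g1 = np.exp(-0.5 * (x / sigma) ** 2)
    k = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    return k / k.sum()


def gaussian_blur_333(field: FieldMap, sigma: float = 1.0) -> FieldMap:
    """Circular (FFT) convolution with the normalized 3x3x3 Gaussian."""
    b = field.values
    if any(s < 3 for s in b.shape):
        raise ValueError(f"blur needs >= 3 voxels per axis, got {b.shape}")
    kernel = gaussian_kernel_333(sigma)
    padded = np.zeros(b.shape)
    padded[:3, :3, :3] = kernel
    padded = np.roll(padded, (-1, -1, -1), axis=(0, 1, 2))  # center at origin
    blurred = scipy.fft.ifftn(scipy.fft.fftn(b) * scipy.fft.fftn(padded)).real
    return FieldMap(values=blurred.astype(b.dtype, copy=False), voxel_sizes=field.voxel_sizes)


def solve_shifted_lap2d(
    rhs: np.ndarray,
    lap_coeff: float,
    shift_coeff: float,
    spacings: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Solve (lap_coeff * L2D + shift_coeff * I) z = rhs per PE-nodal slice.

    ``L2D`` is the periodic-boundary 2D negative Laplacian over the first
    two axes (spacings ``(h1, h2)``).  With periodic boundaries the system
    matrix is block circulant with circulant blocks, so it diagonalizes in
    the 2D Fourier basis and each slice is solved by one FFT round trip.
    """
    if shift_coeff <= 0:
        raise ValueError(f"shift_coeff must be positive, got {shift_coeff}")
    if lap_coeff < 0:
        raise ValueError(f"lap_coeff must be nonnegative, got {lap_coeff}")
    rhs = np.asarray(rhs)
    n1, n2 = rhs.shape[0], rhs.shape[1]
    h1, h2 = spacings
    lam1 = (2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(n1) / n1)) / h1**2
    lam2 = (2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(n2) / n2)) / h2**2
    denom = lap_coeff * (lam1[:, None] + lam2[None, :]) + shift_coeff
    zhat = scipy.fft.fft2(rhs, axes=(0, 1)) / denom[:, :, None]
    return scipy.fft.ifft2(zhat, axes=(0, 1)).real.astype(rhs.dtype, copy=False)
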