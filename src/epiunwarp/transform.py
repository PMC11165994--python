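"""The physical distortion/correction model.

``mp_transform`` is the mass-preserving pull-back used for correction: a
voxel observed at ``x`` in the +PE acquisition originated at
``x + b(x) v``, and the resampled intensity is modulated by the 1D Jacobian
``1 + db/dpe`` so total signal is conserved.  ``build_push_forward`` is the
matching forward (scatter) operator used to simulate distorted data and to
pose the least-squares reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse

from .geometry import FieldMap, ImageVolume, make_grid
from .operators import average_pe, diff_pe, interp1d_pe

__all__ = ["PushForwardOperator", "mp_transform", "build_push_forward", "apply_push_forward"]


def mp_transform(image: ImageVolume, field: FieldMap, sign: int) -> np.ndarray:
    """Mass-preserving correction T[I, b, sv](x) = I(x + s b(x)) (1 + s db/dpe).

    Returns the cell-centered corrected image.  A non-positive modulation
    factor is *not* clamped here; feasibility is the objective's barrier
    term's job.
    """
    if sign not in (+1, -1):
        raise ValueError(f"sign must be +1 or -1, got {sign}")
    centers_pe = make_grid(image).centers[2][None, None, :]
    bc = average_pe(field)
    vals = interp1d_pe(image, centers_pe + sign * bc)
    mod = 1.0 + sign * diff_pe(field, image.voxel_sizes[2])
    return vals * mod


@dataclass
class PushForwardOperator:
    """Sparse forward-distortion operator (block diagonal over PE columns).

    ``matrix`` maps a flattened volume (PE axis fastest) to its distorted
    counterpart; each ``n3 x n3`` diagonal block handles one PE column.
    Interior source columns of each block sum to 1 (mass conservation);
    mass pushed outside the domain is dropped.
    """

    matrix: scipy.sparse.csr_matrix
    shape: tuple[int, int, int]
    sign: int
    field: FieldMap

    def apply(self, data: np.ndarray) -> np.ndarray:
        if data.shape != self.shape:
            raise ValueError(f"expected shape {self.shape}, got {data.shape}")
        return (self.matrix @ data.reshape(-1)).reshape(self.shape)

    def apply_adjoint(self, data: np.ndarray) -> np.ndarray:
        if data.shape != self.shape:
            raise ValueError(f"expected shape {self.shape}, got {data.shape}")
        return (self.matrix.T @ data.reshape(-1)).reshape(self.shape)


def build_push_forward(field: FieldMap, sign: int) -> PushForwardOperator:
    """Assemble the sparse operator pushing mass from x to x + s*b(x).

    Each cell-centered source voxel ``k`` in a PE column sends its unit mass
    to fractional index ``k + s * b_center(k) / h3``, split linearly between
    the two bracketing cells.  Mass landing outside [0, n3-1] is dropped.
    """
    if sign not in (+1, -1):
        raise ValueError(f"sign must be +1 or -1, got {sign}")
    if not np.all(np.isfinite(field.values)):
        raise ValueError("field map contains non-finite values")
    n1, n2, n3 = field.image_shape()
    h3 = field.voxel_sizes[2]
    shift = sign * average_pe(field) / h3  # index units, shape (n1,n2,n3)

    src = np.arange(n3)[None, None, :] + np.zeros((n1, n2, 1))
    tgt = src + shift
    j = np.floor(tgt).astype(np.int64)
    w = tgt - j  # weight of the upper neighbor

    ncol = n1 * n2
    col_offset = (np.arange(ncol) * n3).reshape(n1, n2, 1)
    src_flat = (src.astype(np.int64) + col_offset).ravel()

    rows, cols, vals = [], [], []
    for jj, ww in ((j, 1.0 - w), (j + 1, w)):
        ok = (jj >= 0) & (jj <= n3 - 1)
        rows.append((jj + col_offset).ravel()[ok.ravel()])
        cols.append(src_flat[ok.ravel()])
        vals.append(np.asarray(ww).ravel()[ok.ravel()])
    n = ncol * n3
    matrix = scipy.sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return PushForwardOperator(matrix=matrix, shape=(n1, n2, n3), sign=sign, field=field)


def apply_push_forward(op: PushForwardOperator, image: ImageVolume | np.ndarray) -> np.ndarray:
    """Distort an image with a prebuilt push-forward operator."""
    data = image.data if isinstance(image, ImageVolume) else np.asarray(image)
    return op.apply(data)
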