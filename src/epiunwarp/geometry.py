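"""Canonical data containers and grid conventions.

All internal computation assumes the phase-encoding (PE) axis is the *last*
stored axis.  Images live on cell centers; the displacement field map lives
on a PE-staggered grid (nodal along PE, cell-centered in the other two
axes).  Coordinates are 0-based: cell center ``k`` along an axis with voxel
size ``h`` sits at ``(k + 1/2) * h``, node ``k`` at ``k * h``.

The field map is stored in **mm of displacement** along the PE axis, so the
intensity-modulation factor ``1 + d(b)/d(pe)`` is dimensionless once the
finite difference is divided by the PE voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "OppositePair",
    "FieldMap",
    "Grid",
    "permute_pe_last",
    "inverse_permute",
    "make_grid",
]


@dataclass
class ImageVolume:
    """A 3D intensity volume with voxel sizes and the axis bookkeeping.

    Parameters
    ----------
    data
        3D array of finite intensities, PE axis last.
    voxel_sizes
        ``(h1, h2, h3)`` in mm, in *stored* axis order (h3 is the PE axis).
    perm
        Permutation that maps stored axis order back to the order of the
        input file, i.e. ``data.transpose(perm)`` restores file order.
    """

    data: np.ndarray
    voxel_sizes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    perm: tuple[int, int, int] = (0, 1, 2)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.data.ndim} axes")
        if any(s < 2 for s in self.data.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        self.voxel_sizes = tuple(float(h) for h in self.voxel_sizes)
        if any(h <= 0 for h in self.voxel_sizes):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_sizes}")
        if sorted(self.perm) != [0, 1, 2]:
            raise ValueError(f"perm must be a permutation of (0,1,2), got {self.perm}")
        self.perm = tuple(int(p) for p in self.perm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class OppositePair:
    """Two volumes of identical geometry, distorted along +PE and -PE."""

    plus: ImageVolume
    minus: ImageVolume

    def __post_init__(self) -> None:
        if self.plus.shape != self.minus.shape:
            raise ValueError(
                f"shape mismatch: plus {self.plus.shape} vs minus {self.minus.shape}"
            )
        if self.plus.voxel_sizes != self.minus.voxel_sizes:
            raise ValueError(
                "voxel size mismatch: "
                f"{self.plus.voxel_sizes} vs {self.minus.voxel_sizes}"
            )
        if self.plus.perm != self.minus.perm:
            raise ValueError("the two volumes record different axis permutations")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.plus.shape

    @property
    def voxel_sizes(self) -> tuple[float, float, float]:
        return self.plus.voxel_sizes


@dataclass
class FieldMap:
    """Scalar PE displacement field on the PE-staggered grid.

    ``values`` has shape ``(n1, n2, n3 + 1)`` for a companion image of shape
    ``(n1, n2, n3)``: nodal along PE, cell-centered elsewhere.  Units: mm.
    """

    values: np.ndarray
    voxel_sizes: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.result_type(self.values, np.float32))
        if self.values.ndim != 3:
            raise ValueError("field map must be 3D (staggered along the PE axis)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field map values must be finite")
        self.voxel_sizes = tuple(float(h) for h in self.voxel_sizes)
        if any(h <= 0 for h in self.voxel_sizes):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_sizes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def image_shape(self) -> tuple[int, int, int]:
        """Shape of the cell-centered companion image."""
        n1, n2, n3p1 = self.values.shape
        return (n1, n2, n3p1 - 1)


@dataclass
class Grid:
    """Coordinate realization of the image domain (mm)."""

    centers: tuple[np.ndarray, np.ndarray, np.ndarray]
    pe_nodes: np.ndarray = field(default=None)  # type: ignore[assignment]


def permute_pe_last(data: np.ndarray, voxel_sizes, pe_dim: int) -> ImageVolume:
    """Reorder axes so the phase-encoding axis is stored last.

    ``pe_dim`` is 1-based (1, 2 or 3), matching the usual scanner/file
    convention.  The remaining axes keep their relative order.  The returned
    volume's ``perm`` undoes the reordering.
    """
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim} axes")
    if pe_dim not in (1, 2, 3):
        raise ValueError(f"pe_dim must be 1, 2 or 3, got {pe_dim}")
    axes = [i for i in range(3) if i != pe_dim - 1] + [pe_dim - 1]
    inv = tuple(int(np.argwhere(np.array(axes) == i)[0, 0]) for i in range(3))
    sizes = tuple(float(voxel_sizes[a]) for a in axes)
    return ImageVolume(data=data.transpose(axes), voxel_sizes=sizes, perm=inv)


def inverse_permute(volume_or_array, perm=None) -> np.ndarray:
    """Restore the axis order of the input file.

    Accepts either an :class:`ImageVolume` (its own ``perm`` is used) or a
    raw array together with an explicit ``perm``.  Works for staggered
    arrays too, since only axes are moved.
    """
    if isinstance(volume_or_array, ImageVolume):
        data, perm = volume_or_array.data, volume_or_array.perm
    else:
        data = np.asarray(volume_or_array)
        if perm is None:
            raise ValueError("perm is required when passing a bare array")
    if sorted(perm) != [0, 1, 2]:
        raise ValueError(f"invalid perm {perm}")
    return data.transpose(perm)


def make_grid(volume: ImageVolume) -> Grid:
    """Cell-center coordinates per axis plus PE nodal coordinates (mm)."""
    centers = tuple(
        (np.arange(n) + 0.5) * h for n, h in zip(volume.shape, volume.voxel_sizes)
    )
    n3, h3 = volume.shape[2], volume.voxel_sizes[2]
    pe_nodes = np.arange(n3 + 1) * h3
    return Grid(centers=centers, pe_nodes=pe_nodes)
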