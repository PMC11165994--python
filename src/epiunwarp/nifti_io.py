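"""NIfTI input/output and run configuration.

Images are loaded with nibabel, permuted so the phase-encoding axis is
stored last, and written back in the original file axis order with the
input affine carried through unchanged.  The field map is saved in mm of
PE displacement, with the unit noted in the NIfTI ``descrip`` field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dataclass_field

import nibabel as nib
import numpy as np

from .correction import CorrectionResult
from .geometry import FieldMap, ImageVolume, OppositePair, inverse_permute, permute_pe_last

__all__ = ["RunConfig", "LoadedPair", "load_pair", "save_results", "write_volume"]


@dataclass
class RunConfig:
    """Everything a correction run needs, with the package defaults."""

    plus_path: str = ""
    minus_path: str = ""
    pe_dim: int = 3
    alpha: float = 300.0
    beta: float = 1e-4
    optimizer: str = "gnpcg"            # gnpcg | admm | lbfgs
    init_blur: bool = True
    correction_mode: str = "jacobian"   # jacobian | lstsq | none
    precision: str = "double"           # single | double
    out_dir: str = "."
    seed: int = 0                       # synthetic mode only
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.pe_dim not in (1, 2, 3):
            raise ValueError(f"pe_dim must be 1, 2 or 3, got {self.pe_dim}")
        if self.alpha < 0 or self.beta <= 0:
            raise ValueError("alpha must be >= 0 and beta > 0")
        if self.optimizer not in ("gnpcg", "admm", "lbfgs"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.correction_mode not in ("jacobian", "lstsq", "none"):
            raise ValueError(f"unknown correction mode {self.correction_mode!r}")
        if self.precision not in ("single", "double"):
            raise ValueError(f"precision must be 'single' or 'double'")


@dataclass
class LoadedPair:
    pair: OppositePair
    affine: np.ndarray
    header: "nib.Nifti1Header" = dataclass_field(repr=False, default=None)


def _load_volume(path: str, pe_dim: int, dtype) -> tuple[ImageVolume, np.ndarray, object]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got shape {data.shape}; "
            "extract a single volume from 4D series first"
        )
    zooms = img.header.get_zooms()[:3]
    vol = permute_pe_last(data.astype(dtype), zooms, pe_dim)
    return vol, img.affine, img.header


def load_pair(
    path_plus: str, path_minus: str, pe_dim: int, precision: str = "double"
) -> LoadedPair:
    """Load the opposite-polarity pair, PE axis permuted last."""
    dtype = np.float32 if precision == "single" else np.float64
    vol_p, affine_p, header = _load_volume(path_plus, pe_dim, dtype)
    vol_m, affine_m, _ = _load_volume(path_minus, pe_dim, dtype)
    if vol_p.shape != vol_m.shape or vol_p.voxel_sizes != vol_m.voxel_sizes:
        raise ValueError(
            "input geometries differ: "
            f"plus shape {vol_p.shape} voxels {vol_p.voxel_sizes} vs "
            f"minus shape {vol_m.shape} voxels {vol_m.voxel_sizes}"
        )
    return LoadedPair(pair=OppositePair(plus=vol_p, minus=vol_m), affine=affine_p, header=header)


def write_volume(path: str, data: np.ndarray, affine: np.ndarray, descrip: str = "") -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, path)


def save_results(
    out_dir: str,
    field: FieldMap,
    result: CorrectionResult | None,
    affine: np.ndarray,
    perm: tuple[int, int, int],
    history: list[dict] | None = None,
    stop_reason: str | None = None,
) -> list[str]:
    """Write field map, corrected image(s) and the iteration log.

    Returns the list of files written.  All volumes are permuted back to
    the input file axis order.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    path = os.path.join(out_dir, "field_map.nii.gz")
    write_volume(path, inverse_permute(field.values, perm), affine,
                 "PE displacement field (mm)")
    written.append(path)

    if result is not None:
        if result.mode == "jacobian":
            names = ["corrected_plus.nii.gz", "corrected_minus.nii.gz"]
        else:
            names = ["corrected_lstsq.nii.gz"]
        for name, vol in zip(names, result.images):
            path = os.path.join(out_dir, name)
            write_volume(path, inverse_permute(vol), affine)
            written.append(path)

    if history is not None:
        path = os.path.join(out_dir, "history.tsv")
        cols = ["iter", "J", "D", "S", "P", "grad_norm", "step", "inner_iters"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in history:
                fh.write("\t".join(_fmt(row.get(c)) for c in cols) + "\n")
            if stop_reason is not None:
                fh.write(f"# stop_reason: {stop_reason}\n")
        written.append(path)
    return written


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6e}"
    return str(v)
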