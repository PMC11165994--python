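"""Synthetic test-data factory and evaluation metrics.

Generates desk-scale, model-consistent ground truth: a smooth ellipsoid
phantom, a smooth feasible random field map, and the distorted opposite-
polarity pair obtained by applying the ±PE push-forward operators to the
phantom.  Because the pair is produced by the same physical model the
estimator assumes (and contains no noise, motion or eddy currents), the
true field map and true image are known exactly and recovery can be
quantified.

All randomness in the package lives here and is fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import FieldMap, ImageVolume, OppositePair
from .operators import diff_pe

__all__ = [
    "SyntheticCase",
    "make_phantom",
    "make_field_map",
    "simulate_pair",
    "make_case",
    "pair_ssd",
    "relative_improvement",
    "field_map_error",
]


@dataclass
class SyntheticCase:
    truth_image: ImageVolume
    truth_field: FieldMap
    pair: OppositePair
    seed: int
    max_slope: float


def make_phantom(
    shape: tuple[int, int, int],
    seed: int,
    voxel_sizes: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_blobs: int = 5,
) -> ImageVolume:
    """Smooth head-like phantom on a zero background.

    One large rounded body (a super-ellipsoid filling most of the field of
    view, as a tightly cropped acquisition would) carries a handful of
    internal ellipsoids of differing intensity for contrast; the whole is
    softened by a 2-voxel Gaussian and a 3-voxel boundary margin is kept at
    exactly zero so no signal sits against the domain edge.  Intensities
    are on a realistic MRI magnitude scale (hundreds to thousands of
    arbitrary units), which matters because the default regularization
    weights balance the data term against smoothness at that scale.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 16 for s in shape):
        raise ValueError(f"each axis needs >= 16 voxels, got {shape}")
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    # rounded body: |x/a|^6 + |y/b|^6 + |z/c|^6 <= 1
    body_center = [0.5 * s + rng.uniform(-0.02 * s, 0.02 * s) for s in shape]
    body_semi = [rng.uniform(0.43, 0.47) * s for s in shape]
    body_r = sum(
        np.abs((g - c) / a) ** 6 for g, c, a in zip(grids, body_center, body_semi)
    )
    data = 700.0 * (body_r <= 1.0)
    for _ in range(n_blobs):
        center = [rng.uniform(0.3 * s, 0.7 * s) for s in shape]
        radii = [rng.uniform(0.08 * s, 0.18 * s) for s in shape]
        intensity = rng.uniform(-400.0, 800.0)
        r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, radii))
        data += intensity * (r2 <= 1.0)
    data = gaussian_filter(data, sigma=2.0)
    margin = 3
    mask = np.zeros(shape, dtype=bool)
    mask[margin:-margin, margin:-margin, margin:-margin] = True
    data *= mask
    return ImageVolume(np.maximum(data, 0.0), voxel_sizes)


def make_field_map(
    shape: tuple[int, int, int],
    voxel_sizes: tuple[float, float, float] = (1.0, 1.0, 1.0),
    max_slope: float = 0.5,
    seed: int = 0,
    support: np.ndarray | None = None,
) -> FieldMap:
    """Smooth zero-mean random field with max |db/dpe| = max_slope exactly.

    ``shape`` is the *image* shape; the returned field is staggered along
    PE.  White noise is heavily blurred (sigma = 1/8 of each axis) to leave
    only low spatial frequencies, then centered and rescaled.

    ``support``, if given, is a cell-centered object mask (or soft weight
    in [0, 1]): the field is windowed by its smooth extension so the
    displacement lives where there is signal.  Displacement in pure air is
    unobservable in the data, so a recovery study must not hide random
    field structure there.
    """
    if not 0.0 < max_slope < 1.0:
        raise ValueError(f"max_slope must be in (0, 1), got {max_slope}")
    n1, n2, n3 = (int(s) for s in shape)
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n1, n2, n3 + 1))
    sigma = [max(2.0, s / 8.0) for s in (n1, n2, n3 + 1)]
    smooth = gaussian_filter(raw, sigma=sigma)
    smooth -= smooth.mean()
    if support is not None:
        window = gaussian_filter(np.asarray(support, dtype=float), sigma=3.0)
        window /= max(window.max(), np.finfo(float).tiny)
        # cube the window so displacement fades inside the object edge, as
        # for susceptibility sources concentrated in the interior
        window = window**3
        staggered = np.empty((n1, n2, n3 + 1))
        staggered[:, :, 1:-1] = 0.5 * (window[:, :, :-1] + window[:, :, 1:])
        staggered[:, :, 0] = window[:, :, 0]
        staggered[:, :, -1] = window[:, :, -1]
        # remove the support-weighted mean before windowing so air stays ~0
        wmean = float(np.sum(smooth * staggered) / max(np.sum(staggered), 1.0))
        smooth = (smooth - wmean) * staggered
    slope = np.max(np.abs(diff_pe(smooth, voxel_sizes[2])))
    if slope == 0:
        raise RuntimeError("degenerate random field (constant along PE)")
    return FieldMap(smooth * (max_slope / slope), voxel_sizes)


def simulate_pair(truth_image: ImageVolume, truth_field: FieldMap) -> OppositePair:
    """Distort the truth with the ±PE push-forward operators."""
    from .transform import apply_push_forward, build_push_forward

    plus = apply_push_forward(build_push_forward(truth_field, +1), truth_image)
    minus = apply_push_forward(build_push_forward(truth_field, -1), truth_image)
    mk = lambda d: ImageVolume(d, truth_image.voxel_sizes, truth_image.perm)
    return OppositePair(plus=mk(plus), minus=mk(minus))


def make_case(
    shape: tuple[int, int, int],
    seed: int,
    max_slope: float = 0.5,
    voxel_sizes: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_sigma: float = 0.0,
) -> SyntheticCase:
    """Phantom + field + distorted pair, all derived from one seed.

    ``noise_sigma`` (relative to the phantom's peak intensity) adds white
    Gaussian noise to both observations for robustness experiments; the
    default study conditions are distortion-only (no noise).
    """
    image = make_phantom(shape, seed, voxel_sizes)
    # offset sub-seed so image and field draws are independent streams;
    # window the field to the phantom's signal support (displacement of
    # air is unobservable, so it is excluded from the ground truth)
    support = image.data > 0.02 * image.data.max()
    fld = make_field_map(shape, voxel_sizes, max_slope, seed + 10_000, support=support)
    pair = simulate_pair(image, fld)
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed + 20_000)
        sigma = noise_sigma * image.data.max()
        mk = lambda d: ImageVolume(
            np.maximum(d + rng.normal(0.0, sigma, d.shape), 0.0),
            image.voxel_sizes, image.perm,
        )
        pair = OppositePair(plus=mk(pair.plus.data), minus=mk(pair.minus.data))
    return SyntheticCase(
        truth_image=image, truth_field=fld, pair=pair, seed=seed, max_slope=max_slope
    )


def pair_ssd(plus, minus, voxel_sizes=None) -> float:
    """Midpoint-quadrature SSD (1/2) integral (plus - minus)^2."""
    if isinstance(plus, ImageVolume):
        voxel_sizes = plus.voxel_sizes
        plus = plus.data
    if isinstance(minus, ImageVolume):
        minus = minus.data
    hv = float(np.prod(voxel_sizes))
    d = np.asarray(plus, dtype=float) - np.asarray(minus, dtype=float)
    return 0.5 * hv * float(np.vdot(d, d))


def relative_improvement(input_pair: OppositePair, corrected_plus, corrected_minus) -> float:
    """Percent SSD reduction: 100 (1 - SSD(corrected) / SSD(input))."""
    ssd_in = pair_ssd(input_pair.plus, input_pair.minus)
    if ssd_in == 0:
        raise ValueError("input pair is identical; relative improvement undefined")
    ssd_out = pair_ssd(corrected_plus, corrected_minus, input_pair.voxel_sizes)
    return 100.0 * (1.0 - ssd_out / ssd_in)


def field_map_error(estimate: FieldMap, truth: FieldMap) -> float:
    """Percent relative L2 error over all staggered entries."""
    if estimate.shape != truth.shape:
        raise ValueError(f"shape mismatch: {estimate.shape} vs {truth.shape}")
    tn = float(np.linalg.norm(truth.values))
    if tn == 0:
        raise ValueError("true field map is identically zero")
    return 100.0 * float(np.linalg.norm(estimate.values - truth.values)) / tn
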