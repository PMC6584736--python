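"""Intensity normalization, resampling, wavelet band-pass filtering, quantization.

These are the texture-extraction parameter axes: a wavelet band-pass weight R,
an isotropic resampling size, a gray-level count and a quantization algorithm.
The full Cartesian grid has 5 * 6 * 4 * 2 = 240 members. The topology track
uses only :func:`normalize_to_255`.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
import pywt
from scipy import ndimage

from ._types import QuantizedGrid, VoxelGrid

__all__ = [
    "ExtractionParams",
    "param_grid",
    "normalize_to_255",
    "resample_isotropic",
    "wavelet_bandpass",
    "quantize_equal_probability",
    "quantize_lloyd_max",
    "quantize",
]

WAVELET_RATIOS = (0.5, 2.0 / 3.0, 1.0, 1.5, 2.0)
#: None means "initial in-plane resolution": make voxels isotropic at the
#: native x/y size by resampling z only.
ISO_VOXEL_SIZES = (None, 1.0, 2.0, 3.0, 4.0, 5.0)
GRAY_LEVELS = (8, 16, 32, 64)
QUANT_ALGORITHMS = ("equal-probability", "lloyd-max")

_WAVELET = "coif1"
_BANDPASS_KEYS = ("aad", "ada", "daa", "add", "dad", "dda")  # the six mixed sub-bands


@dataclass(frozen=True)
class ExtractionParams:
    """One texture-extraction parameter combination."""

    wavelet_ratio: float = 1.0
    iso_voxel: float | None = None
    n_gray_levels: int = 32
    quant_algorithm: Literal["equal-probability", "lloyd-max"] = "equal-probability"

    def __post_init__(self) -> None:
        if self.wavelet_ratio <= 0:
            raise ValueError("wavelet_ratio must be positive")
        if self.iso_voxel is not None and self.iso_voxel <= 0:
            raise ValueError("iso_voxel must be positive or None")
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        if self.quant_algorithm not in QUANT_ALGORITHMS:
            raise ValueError(f"unknown quant_algorithm {self.quant_algorithm!r}")

    def label(self) -> str:
        iso = "native" if self.iso_voxel is None else f"{self.iso_voxel:g}"
        return (
            f"R={self.wavelet_ratio:g}|iso={iso}|Ng={self.n_gray_levels}"
            f"|{self.quant_algorithm}"
        )


def param_grid() -> list[ExtractionParams]:
    """The full 240-member extraction-parameter grid, in fixed nested order
    (wavelet ratio, isotropic size, gray levels, algorithm)."""
    return [
        ExtractionParams(r, iso, ng, alg)
        for r, iso, ng, alg in itertools.product(
            WAVELET_RATIOS, ISO_VOXEL_SIZES, GRAY_LEVELS, QUANT_ALGORITHMS
        )
    ]


def iter_param_grid() -> Iterator[ExtractionParams]:
    return iter(param_grid())


def normalize_to_255(grid: VoxelGrid) -> VoxelGrid:
    """Linearly map intensities onto [0, 255], continuously (no rounding).

    A constant volume maps to all zeros (with a provenance warning): any
    constant is texturally and topologically equivalent.
    """
    v = grid.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn("constant volume: normalize_to_255 returns all zeros", stacklevel=2)
        return grid.with_values(np.zeros_like(v), normalized="constant-input")
    # divide before scaling so the max maps to exactly 255.0
    return grid.with_values((v - lo) / (hi - lo) * 255.0, normalized=(lo, hi))


def resample_isotropic(grid: VoxelGrid, iso_voxel: float | None) -> VoxelGrid:
    """Trilinear resampling onto an isotropic lattice.

    ``iso_voxel=None`` resamples only the z axis down to the native in-plane
    resolution (the "initial in-plane resolution" option), assuming the first
    two axes are in-plane.
    """
    if iso_voxel is None:
        target = (grid.spacing[0], grid.spacing[1], min(grid.spacing[0], grid.spacing[1]))
    else:
        if iso_voxel <= 0:
            raise ValueError("iso_voxel must be positive")
        target = (float(iso_voxel),) * 3
    if target == grid.spacing:
        return grid.with_values(grid.values.copy(), resampled=target)

    new_shape = []
    for ax, (n, sp, tg) in enumerate(zip(grid.shape, grid.spacing, target)):
        m = int(round(n * sp / tg)) if n > 1 else 1
        if m < 1:
            raise ValueError(
                f"axis {ax}: resampling {n} voxels at {sp} mm to {tg} mm leaves no samples"
            )
        new_shape.append(m)

    coords = np.meshgrid(
        *[
            np.arange(m) * (tg / sp) if n > 1 else np.zeros(m)
            for m, n, sp, tg in zip(new_shape, grid.shape, grid.spacing, target)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(grid.values, np.array(coords), order=1, mode="nearest")
    return VoxelGrid(out, target, {**grid.provenance, "resampled": target})


def wavelet_bandpass(grid: VoxelGrid, ratio: float) -> VoxelGrid:
    """One-level 3D wavelet decomposition with the six band-pass sub-bands
    (LLH, LHL, HLL, LHH, HLH, HHL) scaled by ``ratio``; LLL and HHH keep
    weight 1. Perfect reconstruction makes ``ratio=1`` the identity."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    min_len = pywt.Wavelet(_WAVELET).dec_len
    for ax, n in enumerate(grid.shape):
        if n < min_len:
            raise ValueError(
                f"axis {ax} has length {n} < wavelet filter support {min_len}"
            )
    coeffs = pywt.dwtn(grid.values, _WAVELET, mode="symmetric")
    for key in _BANDPASS_KEYS:
        coeffs[key] = coeffs[key] * ratio
    rec = pywt.idwtn(coeffs, _WAVELET, mode="symmetric")
    rec = rec[tuple(slice(0, n) for n in grid.shape)]
    return grid.with_values(rec, wavelet_ratio=ratio)


def _as_voxel_values(grid: VoxelGrid | np.ndarray) -> np.ndarray:
    return grid.values if isinstance(grid, VoxelGrid) else np.asarray(grid, float)


def quantize_equal_probability(grid: VoxelGrid | np.ndarray, n_levels: int) -> QuantizedGrid:
    """Rank-based equal-population quantization.

    Level of a voxel with value v is ``ceil(Ng * ECDF(v))``: bin boundaries sit
    at empirical quantiles, so levels receive as near-equal counts as ties
    permit, and any monotone intensity transform leaves the output unchanged.
    """
    v = _as_voxel_values(grid)
    spacing = grid.spacing if isinstance(grid, VoxelGrid) else (1.0, 1.0, 1.0)
    flat = v.ravel()
    n = flat.size
    if np.all(flat == flat.ravel()[0]):
        return QuantizedGrid(np.ones(v.shape, dtype=np.int64), n_levels, spacing)
    # ECDF via ranks: number of values <= v, shared across ties.
    order = np.argsort(flat, kind="stable")
    sorted_v = flat[order]
    # count of values <= each sorted value = index of last occurrence + 1
    last = np.searchsorted(sorted_v, sorted_v, side="right")
    ecdf = np.empty(n)
    ecdf[order] = last / n
    levels = np.ceil(ecdf * n_levels).astype(np.int64)
    np.clip(levels, 1, n_levels, out=levels)
    return QuantizedGrid(levels.reshape(v.shape), n_levels, spacing)


def quantize_lloyd_max(
    grid: VoxelGrid | np.ndarray,
    n_levels: int,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> QuantizedGrid:
    """Minimum-MSE scalar quantizer fitted by Lloyd iterations.

    Centroids start at the equal-probability bin means; boundaries are
    centroid midpoints; iterate until the largest centroid move is below
    ``tol`` times the intensity range.
    """
    v = _as_voxel_values(grid)
    spacing = grid.spacing if isinstance(grid, VoxelGrid) else (1.0, 1.0, 1.0)
    flat = v.ravel()
    lo, hi = float(flat.min()), float(flat.max())
    if hi == lo:
        return QuantizedGrid(np.ones(v.shape, dtype=np.int64), n_levels, spacing)

    eq = quantize_equal_probability(grid, n_levels).levels.ravel()
    centroids = np.array(
        [flat[eq == k].mean() if np.any(eq == k) else np.nan for k in range(1, n_levels + 1)]
    )
    centroids = centroids[np.isfinite(centroids)]
    centroids = np.unique(centroids)
    scale = hi - lo
    for _ in range(max_iter):
        edges = 0.5 * (centroids[:-1] + centroids[1:])
        assign = np.searchsorted(edges, flat)
        new = centroids.copy()
        for k in range(len(centroids)):
            mask = assign == k
            if np.any(mask):
                new[k] = flat[mask].mean()
        if np.max(np.abs(new - centroids)) < tol * scale:
            centroids = new
            break
        centroids = np.unique(new)
    edges = 0.5 * (centroids[:-1] + centroids[1:])
    levels = np.searchsorted(edges, flat) + 1
    if len(centroids) < n_levels:
        warnings.warn(
            f"lloyd-max: only {len(centroids)} of {n_levels} levels occupied",
            stacklevel=2,
        )
    return QuantizedGrid(levels.reshape(v.shape).astype(np.int64), n_levels, spacing)


def quantize(grid: VoxelGrid | np.ndarray, n_levels: int, algorithm: str) -> QuantizedGrid:
    if algorithm == "equal-probability":
        return quantize_equal_probability(grid, n_levels)
    if algorithm == "lloyd-max":
        return quantize_lloyd_max(grid, n_levels)
    raise ValueError(f"unknown quantization algorithm {algorithm!r}")
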