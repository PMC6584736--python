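"""Synthetic 3D ROI phantoms with controllable texture and topology.

Each phantom is a rectangular-parallelepiped volume emulating an MR ROI
around a hepatic lesion: a bright, smoothly correlated background (a Gaussian
random field) into which dark structures are planted — solid ellipsoids
(components), solid tori (rings: one degree-1 class each) and spherical
shells with a bright core (cavities: one degree-2 class each) — plus i.i.d.
voxel noise. Structures are dark on a bright background, mirroring the low
signal intensity of most hepatic tumors on T1-weighted images, so the
sublevel filtration births them early.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import ndimage

from ._types import VoxelGrid

__all__ = ["PhantomSpec", "CohortDataset", "generate_phantom", "generate_cohort"]

#: default voxel-count bounds, spanning small-to-medium study ROIs
MIN_VOXELS, MAX_VOXELS = 1_000, 250_000


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters for one phantom class."""

    class_name: str = "phantom"
    shape: tuple[int, int, int] = (22, 22, 10)
    spacing: tuple[float, float, float] = (1.2, 1.2, 3.0)
    noise_sd: float = 4.0
    correlation_length_mm: float = 4.0
    background_sd: float = 6.0
    n_rings: int = 0
    n_cavities: int = 0
    n_blobs: int = 0
    intensity_range: tuple[float, float] = (0.0, 255.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.shape):
            raise ValueError("shape components must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        n_vox = int(np.prod(self.shape))
        if not (MIN_VOXELS <= n_vox <= MAX_VOXELS):
            raise ValueError(
                f"voxel count {n_vox} outside [{MIN_VOXELS}, {MAX_VOXELS}]"
            )
        if self.noise_sd < 0 or self.background_sd < 0:
            raise ValueError("noise_sd and background_sd must be non-negative")
        if self.correlation_length_mm <= 0:
            raise ValueError("correlation_length_mm must be positive")
        if min(self.n_rings, self.n_cavities, self.n_blobs) < 0:
            raise ValueError("structure counts must be non-negative")
        if self.intensity_range[0] >= self.intensity_range[1]:
            raise ValueError("intensity_range must be (low, high) with low < high")


def _voxel_centers(shape, spacing):
    axes = [np.arange(n) * sp for n, sp in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _place(rng, extent, radius, placed, margin=2.0, tries=200):
    """Draw a center at least `radius` from the walls and non-overlapping with
    previously placed structures; returns (center, ok)."""
    for _ in range(tries):
        c = np.array([rng.uniform(radius, e - radius) if e > 2 * radius else e / 2 for e in extent])
        if all(np.linalg.norm(c - pc) >= radius + pr + margin for pc, pr in placed):
            placed.append((c, radius))
            return c, True
    c = np.array([e / 2 for e in extent])
    placed.append((c, radius))
    return c, False


def generate_phantom(spec: PhantomSpec) -> VoxelGrid:
    """Deterministically generate one phantom from its spec."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.intensity_range
    span = hi - lo
    bg_level = lo + 0.78 * span
    dark = lo + 0.04 * span

    values = np.full(spec.shape, bg_level, dtype=np.float64)
    if spec.background_sd > 0:
        white = rng.standard_normal(spec.shape)
        sigma_vox = [spec.correlation_length_mm / sp for sp in spec.spacing]
        fieldv = ndimage.gaussian_filter(white, sigma_vox)
        sd = fieldv.std()
        if sd > 0:
            values += spec.background_sd * (fieldv / sd)
    else:
        # keep the stream position independent of background_sd toggling off
        pass

    extent = [n * sp for n, sp in zip(spec.shape, spec.spacing)]
    xs, ys, zs = _voxel_centers(spec.shape, spec.spacing)
    placed: list[tuple[np.ndarray, float]] = []
    overlap = False
    max_sp = max(spec.spacing)

    # cavities: dark spherical shell, bright core
    for _ in range(spec.n_cavities):
        r_in = rng.uniform(2.5, 3.5)
        r_out = r_in + max(4.0, 1.4 * max_sp)
        c, ok = _place(rng, extent, r_out, placed)
        overlap |= not ok
        # snap to the nearest voxel center so the core contains a voxel
        c = np.array([round(ci / sp) * sp for ci, sp in zip(c, spec.spacing)])
        rho = np.sqrt((xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2)
        values[(rho >= r_in) & (rho <= r_out)] = dark

    # rings: dark solid torus in the xy-plane
    for _ in range(spec.n_rings):
        r_minor = rng.uniform(max(1.5, 0.6 * max_sp), max(2.2, 0.75 * max_sp))
        r_major = rng.uniform(4.5, 6.5)
        c, ok = _place(rng, extent, r_major + r_minor, placed)
        overlap |= not ok
        c[2] = round(c[2] / spec.spacing[2]) * spec.spacing[2]
        d_inplane = np.sqrt((xs - c[0]) ** 2 + (ys - c[1]) ** 2)
        d_tube = np.sqrt((d_inplane - r_major) ** 2 + (zs - c[2]) ** 2)
        values[d_tube <= r_minor] = dark

    # blobs: dark solid ellipsoids
    for _ in range(spec.n_blobs):
        semi = rng.uniform(2.0, 4.0, size=3)
        semi[2] = max(semi[2], 1.1 * spec.spacing[2])
        c, ok = _place(rng, extent, float(semi.max()), placed)
        overlap |= not ok
        c = np.array([round(ci / sp) * sp for ci, sp in zip(c, spec.spacing)])
        d = np.sqrt(
            ((xs - c[0]) / semi[0]) ** 2
            + ((ys - c[1]) / semi[1]) ** 2
            + ((zs - c[2]) / semi[2]) ** 2
        )
        values[d <= 1.0] = dark

    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    np.clip(values, lo, hi, out=values)

    return VoxelGrid(
        values,
        spec.spacing,
        provenance={
            "class_name": spec.class_name,
            "seed": spec.seed,
            "overlap_warning": overlap,
            "spec": spec,
        },
    )


@dataclass
class CohortDataset:
    """Labeled phantom collection for one binary task."""

    grids: list[VoxelGrid]
    labels: np.ndarray
    ids: list[str]
    seed: int
    specs: tuple[PhantomSpec, PhantomSpec]
    item_seeds: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self) -> Iterator[tuple[str, int, VoxelGrid]]:
        return iter(zip(self.ids, self.labels, self.grids))


def _jitter_shape(rng, shape) -> tuple[int, int, int]:
    """Per-item lesion-size variation: each axis scaled by a factor in
    [0.85, 1.25], voxel count kept within bounds."""
    for _ in range(50):
        factors = rng.uniform(0.85, 1.25, size=3)
        cand = tuple(max(4, int(round(n * f))) for n, f in zip(shape, factors))
        if MIN_VOXELS <= int(np.prod(cand)) <= MAX_VOXELS:
            return cand  # type: ignore[return-value]
    return tuple(shape)  # type: ignore[return-value]


def generate_cohort(
    spec_a: PhantomSpec, spec_b: PhantomSpec, n_per_class: int, seed: int
) -> CohortDataset:
    """2*n_per_class phantoms, labels 0 (spec_a) and 1 (spec_b); item seeds
    and shape jitter derive reproducibly from the cohort seed."""
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    ss = np.random.SeedSequence(seed)
    item_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2 * n_per_class)]
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    grids: list[VoxelGrid] = []
    labels = np.repeat([0, 1], n_per_class)
    ids: list[str] = []
    for i, label in enumerate(labels):
        base = spec_a if label == 0 else spec_b
        item = replace(
            base,
            shape=_jitter_shape(jitter_rng, base.shape),
            seed=item_seeds[i],
        )
        grids.append(generate_phantom(item))
        ids.append(f"{base.class_name}-{i:03d}")
    return CohortDataset(grids, labels, ids, seed, (spec_a, spec_b), item_seeds)
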