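"""Core containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["VoxelGrid", "QuantizedGrid", "PersistenceDiagram"]


@dataclass
class VoxelGrid:
    """A 3D scalar intensity array with per-axis physical spacing (mm).

    This is the object both analysis tracks consume: a rectangular-
    parallelepiped region of interest around a lesion, voxel intensities in
    arbitrary units, possibly anisotropic spacing (slice thickness commonly
    exceeds the in-plane resolution).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be a 3D array, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise ValueError(f"every axis must have length >= 1, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, **extra: Any) -> "VoxelGrid":
        prov = dict(self.provenance)
        prov.update(extra)
        return VoxelGrid(values, self.spacing, prov)


@dataclass
class QuantizedGrid:
    """Integer gray levels 1..n_levels on the voxel lattice."""

    levels: np.ndarray
    n_levels: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if not np.issubdtype(self.levels.dtype, np.integer):
            raise ValueError("levels must be integer")
        if self.levels.ndim != 3:
            raise ValueError("levels must be a 3D array")
        lo, hi = int(self.levels.min()), int(self.levels.max())
        if lo < 1 or hi > self.n_levels:
            raise ValueError(f"levels must lie in 1..{self.n_levels}, got [{lo}, {hi}]")


@dataclass
class PersistenceDiagram:
    """Multiset of birth-death pairs of one homology degree.

    ``births``/``deaths`` are parallel arrays; ``essential`` flags classes
    that survive the whole filtration (recorded at death 255.5 so diagrams
    stay inside the square [-0.5, 255.5]^2).
    """

    degree: int
    births: np.ndarray
    deaths: np.ndarray
    essential: np.ndarray
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.births = np.asarray(self.births, dtype=np.float64).ravel()
        self.deaths = np.asarray(self.deaths, dtype=np.float64).ravel()
        self.essential = np.asarray(self.essential, dtype=bool).ravel()
        if not (len(self.births) == len(self.deaths) == len(self.essential)):
            raise ValueError("births, deaths, essential must have equal length")
        if np.any(self.deaths <= self.births):
            raise ValueError("every retained pair must have death > birth")

    def __len__(self) -> int:
        return len(self.births)

    @property
    def pairs(self) -> np.ndarray:
        """(l, 2) array of (birth, death)."""
        return np.column_stack([self.births, self.deaths])

    @property
    def lifetimes(self) -> np.ndarray:
        return self.deaths - self.births
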