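"""Persistence images: stable vectorization of persistence diagrams.

A diagram D_q = {(b_k, d_k)} becomes the function

    rho(x, y) = sum_k w(b_k, d_k) * exp(-((b_k - x)^2 + (d_k - y)^2) / (2 sigma^2))
    w(b, d)   = arctan(C * (d - b)^p)

evaluated at the cell centers of a mesh over the square [-0.5, 255.5]^2 and
flattened row-major (birth axis first) to a feature vector. The arctan weight
down-weights short-lived classes, which are the least significant ones.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._types import PersistenceDiagram

__all__ = [
    "PIParams",
    "PersistenceImage",
    "weight",
    "persistence_image",
    "vectorize",
    "PersistenceImager",
    "grid_search_pi_params",
]

_LO, _HI = -0.5, 255.5


@dataclass(frozen=True)
class PIParams:
    """Weight and kernel parameters of the persistence image."""

    C: float = 1.0
    p: float = 1.0
    sigma: float = 4.0
    mesh: int = 256

    def __post_init__(self) -> None:
        if self.C <= 0 or self.p <= 0 or self.sigma <= 0:
            raise ValueError("C, p and sigma must all be positive")
        if self.mesh < 1:
            raise ValueError("mesh must be >= 1")


def grid_centers(mesh: int) -> np.ndarray:
    """Centers of the mesh cells along one axis of [-0.5, 255.5]."""
    width = (_HI - _LO) / mesh
    return _LO + (np.arange(mesh) + 0.5) * width


def weight(b: float | np.ndarray, d: float | np.ndarray, C: float, p: float) -> np.ndarray:
    """arctan(C (d - b)^p); zero at zero lifetime, bounded by pi/2."""
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d < b):
        raise ValueError("death must be >= birth")
    return np.arctan(C * (d - b) ** p)


@dataclass
class PersistenceImage:
    """Discretized rho on the mesh plus its flattened feature vector."""

    values: np.ndarray  # (mesh, mesh), rows = birth axis, cols = death axis
    params: PIParams

    @property
    def vector(self) -> np.ndarray:
        return self.values.ravel(order="C")


def persistence_image(
    diagram: PersistenceDiagram, params: PIParams = PIParams()
) -> PersistenceImage:
    """Evaluate rho at every cell center of the mesh; additive over pairs."""
    mesh = params.mesh
    centers = grid_centers(mesh)
    if len(diagram) == 0:
        return PersistenceImage(np.zeros((mesh, mesh)), params)
    b = diagram.births
    d = diagram.deaths
    w = weight(b, d, params.C, params.p)
    eb = np.exp(-((b[:, None] - centers[None, :]) ** 2) / (2 * params.sigma**2))
    ed = np.exp(-((d[:, None] - centers[None, :]) ** 2) / (2 * params.sigma**2))
    values = np.einsum("k,ki,kj->ij", w, eb, ed)
    return PersistenceImage(values, params)


def vectorize(image: PersistenceImage) -> np.ndarray:
    """Fixed row-major flattening; length mesh**2 (65,536 at the default 256)."""
    return image.vector


class PersistenceImager:
    """sklearn-style transformer: list of PersistenceDiagrams -> (n, mesh^2)."""

    def __init__(self, C: float = 1.0, p: float = 1.0, sigma: float = 4.0, mesh: int = 256):
        self.C = C
        self.p = p
        self.sigma = sigma
        self.mesh = mesh

    def get_params(self, deep: bool = True) -> dict:
        return {"C": self.C, "p": self.p, "sigma": self.sigma, "mesh": self.mesh}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _pi_params(self) -> PIParams:
        return PIParams(self.C, self.p, self.sigma, self.mesh)

    def fit(self, X, y=None):
        self.params_ = self._pi_params()
        return self

    def transform(self, X: Sequence[PersistenceDiagram]) -> np.ndarray:
        params = self._pi_params()
        return np.vstack([persistence_image(dg, params).vector for dg in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def grid_search_pi_params(
    diagrams: Sequence[PersistenceDiagram],
    labels: np.ndarray,
    candidates: Sequence[PIParams],
    model=None,
    seed: int = 0,
    cv_folds: int = 5,
) -> PIParams:
    """Pick the candidate maximizing cross-validated accuracy of the
    downstream classifier; ties broken by declared order."""
    from sklearn.base import clone
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    if len(candidates) == 1:
        return candidates[0]
    if model is None:
        from .classify import make_model

        model = make_model("xgboost", seed=seed)
    labels = np.asarray(labels)
    best: tuple[float, int] | None = None
    for idx, cand in enumerate(candidates):
        X = PersistenceImager(**cand.__dict__).fit_transform(diagrams)
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        acc = float(np.mean(cross_val_score(clone(model), X, labels, cv=skf, scoring="accuracy")))
        if best is None or acc > best[0]:
            best = (acc, idx)
    return candidates[best[1]]
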