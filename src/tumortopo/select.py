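"""Per-feature selection of texture-extraction parameters.

Every texture feature is computed under all 240 extraction-parameter
combinations; for each feature the combination whose values correlate most
strongly (bootstrapped mean |Spearman rho|) with the binary outcome is kept,
suppressing the multicollinearity a 240-fold feature expansion would cause.

By default selection sees all lesions, matching the study procedure of
selecting before leave-one-out evaluation; a nested variant that re-selects
inside each training fold is available through the classify/pipeline layer.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .preprocess import ExtractionParams
from .texture import FEATURE_NAMES

__all__ = ["ParamSelection", "spearman_rho", "select_extraction_params", "ExtractionParamSelector"]


@dataclass(frozen=True)
class ParamSelection:
    """Winning extraction parameters for one feature."""

    feature_index: int  # 1-based, Table order
    feature_name: str
    params: ExtractionParams
    param_index: int  # position in the declared grid
    score: float  # mean |rho| over bootstrap replicates
    n_boot: int
    seed: int


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks
    (ties receive average ranks). Zero rank variance in either argument
    returns 0 with a warning."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        warnings.warn("zero rank variance: Spearman rho set to 0", stacklevel=2)
        return 0.0
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def _stratified_bootstrap(rng: np.random.Generator, labels: np.ndarray) -> np.ndarray:
    """Resample with replacement within each class (class sizes preserved, so
    no resample can lose a class)."""
    idx = np.arange(labels.size)
    take = [rng.choice(idx[labels == c], size=(labels == c).sum(), replace=True)
            for c in np.unique(labels)]
    return np.concatenate(take)


def _abs_rho_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Spearman rho| of every column of x against y (vectorized mid-ranks)."""
    rx = rankdata(x, axis=0)
    ry = rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    sx = rx.std(axis=0)
    sy = ry.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry[:, None]).mean(axis=0) / (sx * sy)
    rho[~np.isfinite(rho)] = 0.0
    return np.abs(rho)


def select_extraction_params(
    features: np.ndarray,
    labels: np.ndarray,
    param_list: Sequence[ExtractionParams],
    n_boot: int = 1000,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> list[ParamSelection]:
    """Bootstrap-scored argmax selection.

    Parameters
    ----------
    features : (n_lesions, n_params, n_features) array
        Feature values under every extraction-parameter combination.
    labels : (n_lesions,) binary vector
    n_boot : bootstrap replicates (``n_boot=0`` scores once on the full
        sample — the plain argmax |rho|).

    Ties in the argmax break by declared grid order.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 3:
        raise ValueError("features must be (n_lesions, n_params, n_features)")
    n, n_params, n_feat = features.shape
    if n_params != len(param_list):
        raise ValueError("param_list length must match features axis 1")
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must be binary")
    if feature_names is None:
        feature_names = FEATURE_NAMES if n_feat == len(FEATURE_NAMES) else [
            f"feature_{i + 1}" for i in range(n_feat)
        ]

    flat = features.reshape(n, n_params * n_feat)
    rng = np.random.default_rng(seed)
    if n_boot <= 0:
        scores = _abs_rho_matrix(flat, labels.astype(float))
    else:
        scores = np.zeros(n_params * n_feat)
        for _ in range(n_boot):
            take = _stratified_bootstrap(rng, labels)
            scores += _abs_rho_matrix(flat[take], labels[take].astype(float))
        scores /= n_boot
    scores = scores.reshape(n_params, n_feat)

    out = []
    for f in range(n_feat):
        j = int(np.argmax(scores[:, f]))  # argmax takes the first of ties
        out.append(
            ParamSelection(
                feature_index=f + 1,
                feature_name=str(feature_names[f]),
                params=param_list[j],
                param_index=j,
                score=float(scores[j, f]),
                n_boot=n_boot,
                seed=seed,
            )
        )
    return out


class ExtractionParamSelector:
    """sklearn-style selector over a (n, n_params, n_features) feature cube.

    ``fit`` chooses one parameter combination per feature; ``transform``
    returns the (n, n_features) matrix of each feature at its chosen
    combination.
    """

    def __init__(self, param_list: Sequence[ExtractionParams] | None = None,
                 n_boot: int = 1000, seed: int = 0):
        self.param_list = param_list
        self.n_boot = n_boot
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"param_list": self.param_list, "n_boot": self.n_boot, "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.asarray(X)
        param_list = self.param_list
        if param_list is None:
            from .preprocess import param_grid

            param_list = param_grid()
        self.selections_ = select_extraction_params(
            X, y, param_list, n_boot=self.n_boot, seed=self.seed
        )
        self.chosen_idx_ = np.array([s.param_index for s in self.selections_])
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        return X[:, self.chosen_idx_, np.arange(X.shape[2])]

    def fit_transform(self, X, y) -> np.ndarray:
        return self.fit(X, y).transform(X)
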