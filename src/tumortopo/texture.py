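"""The 43 texture features: 3 global moments plus GLCM/GLRLM/GLSZM/NGTDM statistics.

Matrix conventions (documented in docs/methods.md): co-occurrence and run-length
matrices are accumulated over the 13 unique 3D direction vectors at displacement 1
and merged into a single matrix; zones use 26-connectivity; the neighborhood
gray-tone difference uses the 26-neighborhood with edge voxels averaging over
their available neighbors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

from ._types import QuantizedGrid, VoxelGrid
from .preprocess import ExtractionParams, quantize, resample_isotropic, wavelet_bandpass

__all__ = [
    "DIRECTIONS_13",
    "FEATURE_NAMES",
    "global_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_table",
    "ngtdm_features",
    "extract_all",
    "TextureFeatureExtractor",
]

#: The 13 unique 3D direction vectors (26 neighbors modulo sign).
DIRECTIONS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_GLOBAL = ["Variance", "Skewness", "Kurtosis"]
_GLCM = [
    "Energy", "Contrast", "Correlation", "Homogeneity", "Variance",
    "Sum Average", "Entropy", "Dissimilarity", "Auto Correlation",
]
_GLRLM = [
    "Short Run Emphasis", "Long Run Emphasis", "Gray-Level (GL) Non-uniformity",
    "Run-Length Non-uniformity", "Run Percentage", "Low GL Run Emphasis",
    "High GL Run Emphasis", "Short Run Low GL Emphasis", "Short Run High GL Emphasis",
    "Long Run Low GL Emphasis", "Long Run High GL Emphasis", "GL Variance",
    "Run-Length Variance",
]
_GLSZM = [
    "Small Zone Emphasis", "Large Zone Emphasis", "GL Level Non-uniformity",
    "Zone-Size Non-uniformity", "Zone Percentage", "Low GL Zone Emphasis",
    "High GL Zone Emphasis", "Small Zone Low GL Emphasis", "Small Zone High GL Emphasis",
    "Large Zone Low GL Emphasis", "Large Zone High GL Emphasis", "GL Variance",
    "Zone-Size Variance",
]
_NGTDM = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

#: Feature columns in fixed index order 1..43, qualified by family.
FEATURE_NAMES: list[str] = (
    [f"Global {n}" for n in _GLOBAL]
    + [f"GLCM {n}" for n in _GLCM]
    + [f"GLRLM {n}" for n in _GLRLM]
    + [f"GLSZM {n}" for n in _GLSZM]
    + [f"NGTDM {n}" for n in _NGTDM]
)


# ---------------------------------------------------------------- global

def global_features(grid: VoxelGrid | np.ndarray) -> dict[str, float]:
    """Population variance and standardized third/fourth moments of all voxels."""
    v = (grid.values if isinstance(grid, VoxelGrid) else np.asarray(grid, float)).ravel()
    if v.size < 2:
        raise ValueError("global features need at least 2 voxels")
    mu = v.mean()
    var = float(((v - mu) ** 2).mean())
    if var == 0.0:
        warnings.warn("zero variance: skewness and kurtosis set to 0", stacklevel=2)
        skew = kurt = 0.0
    else:
        sd = np.sqrt(var)
        skew = float((((v - mu) / sd) ** 3).mean())
        kurt = float((((v - mu) / sd) ** 4).mean())
    return {"Variance": var, "Skewness": skew, "Kurtosis": kurt}


# ---------------------------------------------------------------- GLCM

def glcm_matrix(qgrid: QuantizedGrid) -> np.ndarray:
    """Symmetric co-occurrence probabilities over the 13 directions, displacement 1."""
    q = qgrid.levels
    ng = qgrid.n_levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    for d in DIRECTIONS_13:
        src = tuple(
            slice(max(0, -o), q.shape[ax] - max(0, o)) for ax, o in enumerate(d)
        )
        dst = tuple(
            slice(max(0, o), q.shape[ax] + min(0, o)) for ax, o in enumerate(d)
        )
        a = q[src].ravel() - 1
        b = q[dst].ravel() - 1
        np.add.at(counts, (a, b), 1)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no voxel pairs: grid too small for co-occurrence")
    return counts / total


def glcm_features(qgrid: QuantizedGrid) -> dict[str, float]:
    p = glcm_matrix(qgrid)
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # marginal (symmetric: px == py)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)
    energy = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sigma > 0:
        correlation = float((((ii - mu) * (jj - mu) * p).sum()) / sigma2)
    else:
        correlation = 0.0
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    variance = float(((ii - mu) ** 2 * p).sum())
    # p_{x+y}(k), k = 2..2Ng
    k = ii + jj
    sum_average = float((k * p).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    autocorrelation = float((ii * jj * p).sum())
    return {
        "Energy": energy, "Contrast": contrast, "Correlation": correlation,
        "Homogeneity": homogeneity, "Variance": variance, "Sum Average": sum_average,
        "Entropy": entropy, "Dissimilarity": dissimilarity,
        "Auto Correlation": autocorrelation,
    }


# ---------------------------------------------------------------- GLRLM

@njit(cache=True)
def _rlm_accumulate(q, ng, max_run, dirs):  # pragma: no cover - numba
    nx, ny, nz = q.shape
    rlm = np.zeros((ng, max_run), dtype=np.int64)
    for di in range(dirs.shape[0]):
        dx, dy, dz = dirs[di, 0], dirs[di, 1], dirs[di, 2]
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    # run start: predecessor out of bounds or different level
                    px, py, pz = x - dx, y - dy, z - dz
                    if (
                        0 <= px < nx and 0 <= py < ny and 0 <= pz < nz
                        and q[px, py, pz] == q[x, y, z]
                    ):
                        continue
                    level = q[x, y, z]
                    length = 1
                    cx, cy, cz = x + dx, y + dy, z + dz
                    while 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz and q[cx, cy, cz] == level:
                        length += 1
                        cx += dx
                        cy += dy
                        cz += dz
                    rlm[level - 1, length - 1] += 1
    return rlm


def glrlm_matrix(qgrid: QuantizedGrid, directions=DIRECTIONS_13) -> np.ndarray:
    """Run-length counts, rows = gray level, columns = run length, merged over
    the given directions (the 13 unique 3D directions by default)."""
    q = np.ascontiguousarray(qgrid.levels, dtype=np.int64)
    max_run = int(np.ceil(np.sqrt(sum(n**2 for n in q.shape)))) + 1
    dirs = np.array(directions, dtype=np.int64)
    rlm = _rlm_accumulate(q, qgrid.n_levels, max(max_run, max(q.shape)), dirs)
    # trim trailing all-zero run-length columns (keep at least one)
    last = max(1, int(np.max(np.nonzero(rlm.any(axis=0))[0])) + 1) if rlm.any() else 1
    return rlm[:, :last]


def _sre_family(mat: np.ndarray, n_voxels: int, n_dirs: int) -> dict[str, float]:
    """The 13 run/zone statistics shared by GLRLM and GLSZM.

    ``n_dirs`` normalizes the percentage feature: runs are counted once per
    direction, zones once (n_dirs=1).
    """
    nr = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=float)  # gray level
    ell = np.arange(1, mat.shape[1] + 1, dtype=float)  # run length / zone size
    ii, ll = np.meshgrid(i, ell, indexing="ij")
    ri = mat.sum(axis=1).astype(float)
    rl = mat.sum(axis=0).astype(float)
    p = mat / nr
    mu_i = float((ii * p).sum())
    mu_l = float((ll * p).sum())
    return {
        "short": float((mat / ll**2).sum() / nr),
        "long": float((mat * ll**2).sum() / nr),
        "gln": float((ri**2).sum() / nr),
        "rln": float((rl**2).sum() / nr),
        "pct": float(nr / (n_voxels * n_dirs)),
        "lgl": float((mat / ii**2).sum() / nr),
        "hgl": float((mat * ii**2).sum() / nr),
        "slgl": float((mat / (ii**2 * ll**2)).sum() / nr),
        "shgl": float((mat * ii**2 / ll**2).sum() / nr),
        "llgl": float((mat * ll**2 / ii**2).sum() / nr),
        "lhgl": float((mat * ii**2 * ll**2).sum() / nr),
        "glv": float(((ii - mu_i) ** 2 * p).sum()),
        "rlv": float(((ll - mu_l) ** 2 * p).sum()),
    }


def glrlm_features(qgrid: QuantizedGrid, directions=DIRECTIONS_13) -> dict[str, float]:
    mat = glrlm_matrix(qgrid, directions)
    s = _sre_family(mat, qgrid.levels.size, len(directions))
    keys = ["short", "long", "gln", "rln", "pct", "lgl", "hgl", "slgl", "shgl",
            "llgl", "lhgl", "glv", "rlv"]
    return dict(zip(_GLRLM, (s[k] for k in keys)))


# ---------------------------------------------------------------- GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(qgrid: QuantizedGrid) -> np.ndarray:
    """Size-zone counts: zones are maximal 26-connected sets of equal level."""
    q = qgrid.levels
    max_size = q.size
    szm = np.zeros((qgrid.n_levels, max_size), dtype=np.int64)
    for level in np.unique(q):
        lab, n = ndimage.label(q == level, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            szm[level - 1, sz - 1] += 1
    last = max(1, int(np.max(np.nonzero(szm.any(axis=0))[0])) + 1) if szm.any() else 1
    return szm[:, :last]


def glszm_features(qgrid: QuantizedGrid) -> dict[str, float]:
    mat = glszm_matrix(qgrid)
    s = _sre_family(mat, qgrid.levels.size, 1)
    keys = ["short", "long", "gln", "rln", "pct", "lgl", "hgl", "slgl", "shgl",
            "llgl", "lhgl", "glv", "rlv"]
    return dict(zip(_GLSZM, (s[k] for k in keys)))


# ---------------------------------------------------------------- NGTDM

_EPS = 1e-6


def ngtdm_table(qgrid: QuantizedGrid) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occupancy probabilities p_i and summed gray-tone differences s_i.

    s_i sums |i - A| over voxels of level i, where A is the mean level of the
    voxel's available 26-neighbors (edge voxels use fewer neighbors).
    """
    q = qgrid.levels.astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(q, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(np.ones_like(q), kernel, mode="constant", cval=0.0)
    a = nb_sum / nb_cnt
    ng = qgrid.n_levels
    p = np.zeros(ng)
    s = np.zeros(ng)
    lv = qgrid.levels
    for level in range(1, ng + 1):
        mask = lv == level
        p[level - 1] = mask.sum() / lv.size
        if np.any(mask):
            s[level - 1] = np.abs(level - a[mask]).sum()
    return p, s


def ngtdm_features(qgrid: QuantizedGrid) -> dict[str, float]:
    p, s = ngtdm_table(qgrid)
    n_voxels = qgrid.levels.size
    present = p > 0
    i = np.arange(1, len(p) + 1, dtype=float)
    ngp = int(present.sum())
    psi = float((p * s).sum())

    coarseness = 1.0 / (_EPS + psi)

    if ngp > 1:
        ip, jp = np.meshgrid(i[present], i[present], indexing="ij")
        pp_i, pp_j = np.meshgrid(p[present], p[present], indexing="ij")
        contrast = float(
            (pp_i * pp_j * (ip - jp) ** 2).sum() / (ngp * (ngp - 1)) * s.sum() / n_voxels
        )
        denom_busy = float(np.abs(ip * pp_i - jp * pp_j).sum())
        # i*p_i can coincide across levels; guard the analytic zero
        busyness = psi / denom_busy if denom_busy > 1e-10 else 0.0
        si, sj = np.meshgrid(s[present], s[present], indexing="ij")
        complexity = float(
            (np.abs(ip - jp) * (pp_i * si + pp_j * sj) / (n_voxels * (pp_i + pp_j))).sum()
        )
        strength = float(((pp_i + pp_j) * (ip - jp) ** 2).sum() / (_EPS + s.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness,
        "Complexity": complexity, "Strength": strength,
    }


# ---------------------------------------------------------------- assembly

@dataclass
class TextureFeatureVector:
    """All 43 features of one ROI under one extraction-parameter setting."""

    values: np.ndarray  # length 43, Table order
    params: ExtractionParams

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def extract_all(grid: VoxelGrid, params: ExtractionParams) -> TextureFeatureVector:
    """Full chain: wavelet band-pass -> isotropic resampling -> quantization ->
    the four matrix families, plus global moments on the unquantized
    (filtered, resampled) intensities."""
    filtered = wavelet_bandpass(grid, params.wavelet_ratio)
    resampled = resample_isotropic(filtered, params.iso_voxel)
    qgrid = quantize(resampled, params.n_gray_levels, params.quant_algorithm)
    feats: dict[str, float] = {}
    feats.update({f"Global {k}": v for k, v in global_features(resampled).items()})
    feats.update({f"GLCM {k}": v for k, v in glcm_features(qgrid).items()})
    feats.update({f"GLRLM {k}": v for k, v in glrlm_features(qgrid).items()})
    feats.update({f"GLSZM {k}": v for k, v in glszm_features(qgrid).items()})
    feats.update({f"NGTDM {k}": v for k, v in ngtdm_features(qgrid).items()})
    vec = np.array([feats[name] for name in FEATURE_NAMES])
    if not np.all(np.isfinite(vec)):
        bad = [n for n, v in zip(FEATURE_NAMES, vec) if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite features: {bad}")
    return TextureFeatureVector(vec, params)


class TextureFeatureExtractor:
    """sklearn-style transformer: list of VoxelGrids -> (n, 43) feature matrix.

    Parameters mirror :class:`ExtractionParams`.
    """

    def __init__(
        self,
        wavelet_ratio: float = 1.0,
        iso_voxel: float | None = None,
        n_gray_levels: int = 32,
        quant_algorithm: str = "equal-probability",
    ) -> None:
        self.wavelet_ratio = wavelet_ratio
        self.iso_voxel = iso_voxel
        self.n_gray_levels = n_gray_levels
        self.quant_algorithm = quant_algorithm

    def get_params(self, deep: bool = True) -> dict:
        return {
            "wavelet_ratio": self.wavelet_ratio,
            "iso_voxel": self.iso_voxel,
            "n_gray_levels": self.n_gray_levels,
            "quant_algorithm": self.quant_algorithm,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _extraction_params(self) -> ExtractionParams:
        return ExtractionParams(
            self.wavelet_ratio, self.iso_voxel, self.n_gray_levels, self.quant_algorithm  # type: ignore[arg-type]
        )

    def fit(self, X, y=None):
        self.feature_names_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        params = self._extraction_params()
        return np.vstack([extract_all(g, params).values for g in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
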