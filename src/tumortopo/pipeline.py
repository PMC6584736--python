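"""Configured end-to-end runs: generate -> extract -> select -> classify.

A YAML config (validated by pydantic models) declares the cohort, the
extraction grids, persistence-image parameters and classifier specs; every
random stage receives a seed fanned out deterministically from the global
one. Stages are idempotent: each writes its outputs plus a hash of the
config slice that produced them, and is skipped on rerun when the hash
matches.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import classify as clf
from . import io as tio
from ._types import VoxelGrid
from .phantoms import PhantomSpec, generate_cohort
from .pimage import PersistenceImager, PIParams
from .preprocess import (
    GRAY_LEVELS,
    ISO_VOXEL_SIZES,
    QUANT_ALGORITHMS,
    WAVELET_RATIOS,
    ExtractionParams,
)
from .select import select_extraction_params
from .texture import FEATURE_NAMES, extract_all
from .topology import persistence_diagrams

logger = logging.getLogger("tumortopo")

__all__ = ["PipelineConfig", "run_pipeline", "extract_feature_cube", "loocv_texture"]


# ------------------------------------------------------------------ config

class PhantomConfig(BaseModel):
    class_name: str
    shape: tuple[int, int, int] = (22, 22, 10)
    spacing: tuple[float, float, float] = (1.2, 1.2, 3.0)
    noise_sd: float = 4.0
    correlation_length_mm: float = 4.0
    background_sd: float = 6.0
    n_rings: int = 0
    n_cavities: int = 0
    n_blobs: int = 0
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def to_spec(self, seed: int = 0) -> PhantomSpec:
        return PhantomSpec(seed=seed, **self.model_dump())


class CohortConfig(BaseModel):
    class_a: PhantomConfig
    class_b: PhantomConfig
    n_per_class: int = Field(ge=2, default=20)


class TextureConfig(BaseModel):
    wavelet_ratios: list[float] = list(WAVELET_RATIOS)
    iso_voxels: list[float | None] = list(ISO_VOXEL_SIZES)
    gray_levels: list[int] = list(GRAY_LEVELS)
    algorithms: list[str] = list(QUANT_ALGORITHMS)
    n_boot: int = 1000
    selection_mode: Literal["faithful", "nested"] = "faithful"
    model: str = "lda-enet"
    model_grid: dict[str, list] | None = None

    @field_validator("algorithms")
    @classmethod
    def _check_alg(cls, v):
        for a in v:
            if a not in QUANT_ALGORITHMS:
                raise ValueError(f"unknown quantization algorithm {a!r}")
        return v

    def param_list(self) -> list[ExtractionParams]:
        import itertools

        return [
            ExtractionParams(r, iso, ng, alg)
            for r, iso, ng, alg in itertools.product(
                self.wavelet_ratios, self.iso_voxels, self.gray_levels, self.algorithms
            )
        ]


class PIConfig(BaseModel):
    C: float = 1.0
    p: float = 1.0
    sigma: float = 4.0
    mesh: int = 64

    def to_params(self) -> PIParams:
        return PIParams(self.C, self.p, self.sigma, self.mesh)


class TopologyConfig(BaseModel):
    degrees: list[int] = [0, 1, 2]
    pi: PIConfig = PIConfig()
    model: str = "xgboost"
    model_grid: dict[str, list] | None = None


class PipelineConfig(BaseModel):
    out_dir: str
    seed: int = 0
    track: Literal["texture", "topology", "both"] = "both"
    manifest: str | None = None  # use an existing cohort instead of generating
    cohort: CohortConfig | None = None
    texture: TextureConfig = TextureConfig()
    topology: TopologyConfig = TopologyConfig()
    inner_cv_folds: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data)


# ------------------------------------------------------------------ helpers

def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_fresh(out: Path, stage: str, digest: str) -> bool:
    mark = out / f".{stage}.hash"
    return mark.exists() and mark.read_text() == digest


def _stage_done(out: Path, stage: str, digest: str) -> None:
    (out / f".{stage}.hash").write_text(digest)


def extract_feature_cube(
    grids: Sequence[VoxelGrid], param_list: Sequence[ExtractionParams]
) -> np.ndarray:
    """(n_lesions, n_params, 43) texture feature cube."""
    cube = np.empty((len(grids), len(param_list), len(FEATURE_NAMES)))
    for i, g in enumerate(grids):
        for j, p in enumerate(param_list):
            cube[i, j] = extract_all(g, p).values
    return cube


def loocv_texture(
    cube: np.ndarray,
    labels: np.ndarray,
    param_list: Sequence[ExtractionParams],
    model,
    n_boot: int,
    seed: int,
    mode: str = "faithful",
) -> clf.EvaluationResult:
    """Texture-track LOOCV.

    ``faithful`` selects extraction parameters once on all lesions before the
    LOOCV loop (the study's procedure); ``nested`` re-selects inside each
    training fold so the held-out lesion never informs selection.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if mode == "faithful":
        sel = select_extraction_params(cube, labels, param_list, n_boot=n_boot, seed=seed)
        idx = np.array([s.param_index for s in sel])
        X = cube[:, idx, np.arange(cube.shape[2])]
        return clf.loocv(model, X, labels)
    if mode != "nested":
        raise ValueError(f"unknown selection mode {mode!r}")
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sel = select_extraction_params(
            cube[mask], labels[mask], param_list, n_boot=n_boot, seed=seed
        )
        idx = np.array([s.param_index for s in sel])
        cols = np.arange(cube.shape[2])
        scores[i] = clf.fit_predict(
            model, cube[mask][:, idx, cols], labels[mask], cube[i : i + 1][:, idx, cols]
        )[0]
    y_bin = (labels == np.unique(labels)[1]).astype(int)
    y_pred = (scores >= 0.5).astype(int)
    tp = int(((y_pred == 1) & (y_bin == 1)).sum())
    fp = int(((y_pred == 1) & (y_bin == 0)).sum())
    tn = int(((y_pred == 0) & (y_bin == 0)).sum())
    fn = int(((y_pred == 0) & (y_bin == 1)).sum())
    m = clf.metrics(tp, fp, tn, fn)
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y_bin, scores)
    return clf.EvaluationResult(
        y_true=y_bin, scores=scores, y_pred=y_pred, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=m["accuracy"], sensitivity=m["sensitivity"],
        specificity=m["specificity"], auc=clf.auc(scores, y_bin), roc=(fpr, tpr),
    )


def _result_row(name: str, res: clf.EvaluationResult, n_pos: int, n_neg: int) -> dict:
    return {
        "task": name,
        "accuracy": res.accuracy,
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "auc": res.auc,
        "correct": res.tp + res.tn,
        "n": n_pos + n_neg,
    }


# ------------------------------------------------------------------ runner

def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None) -> Path:
    """Run (or resume) the configured pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logger.handlers:
        logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    try:
        return _run(config, out, stages)
    finally:
        logger.removeHandler(fh)
        fh.close()


def _run(config: PipelineConfig, out: Path, stages: Sequence[str] | None) -> Path:
    want = lambda s: stages is None or s in stages
    cfg_dump = config.model_dump()
    ss = np.random.SeedSequence(config.seed)
    seeds = {k: int(s.generate_state(1)[0] % (2**31))
             for k, s in zip(["cohort", "select", "model", "pi"], ss.spawn(4))}

    # ---- cohort
    manifest = Path(config.manifest) if config.manifest else out / "volumes" / "manifest.csv"
    if config.manifest is None and want("generate"):
        digest = _hash({"cohort": cfg_dump["cohort"], "seed": config.seed})
        if not _stage_fresh(out, "generate", digest):
            if config.cohort is None:
                raise ValueError("config field 'cohort' is required when no manifest is given")
            logger.info("generating cohort (%d per class)", config.cohort.n_per_class)
            cohort = generate_cohort(
                config.cohort.class_a.to_spec(),
                config.cohort.class_b.to_spec(),
                config.cohort.n_per_class,
                seeds["cohort"],
            )
            tio.save_manifest(cohort, out / "volumes")
            _stage_done(out, "generate", digest)
    grids, labels, ids = tio.load_manifest(manifest)
    summary_rows = []

    # ---- texture track
    if config.track in ("texture", "both"):
        tcfg = config.texture
        param_list = tcfg.param_list()
        cube_path = out / "texture_cube.npy"
        digest = _hash({"texture": cfg_dump["texture"], "manifest": str(manifest)})
        if want("extract-texture") and not _stage_fresh(out, "texture", digest):
            logger.info("extracting %d x %d texture vectors", len(grids), len(param_list))
            cube = extract_feature_cube(grids, param_list)
            np.save(cube_path, cube)
            _write_feature_csv(out / "texture_features.csv", cube, ids, labels, param_list)
            _stage_done(out, "texture", digest)
        if want("select-params") or want("classify"):
            cube = np.load(cube_path)
        if want("select-params"):
            sel = select_extraction_params(
                cube, labels, param_list, n_boot=tcfg.n_boot, seed=seeds["select"]
            )
            pd.DataFrame(
                [
                    {
                        "feature_index": s.feature_index, "name": s.feature_name,
                        "R": s.params.wavelet_ratio,
                        "iso": "native" if s.params.iso_voxel is None else s.params.iso_voxel,
                        "Ng": s.params.n_gray_levels, "algorithm": s.params.quant_algorithm,
                        "score": s.score,
                    }
                    for s in sel
                ]
            ).to_csv(out / "param_selection.csv", index=False)
        if want("classify"):
            model = clf.make_model(
                tcfg.model,
                {k: tuple(v) for k, v in tcfg.model_grid.items()} if tcfg.model_grid else None,
                config.inner_cv_folds,
                seeds["model"],
            )
            res = loocv_texture(
                cube, labels, param_list, model, tcfg.n_boot, seeds["select"],
                mode=tcfg.selection_mode,
            )
            _save_result(out / "texture_result.json", res, config)
            summary_rows.append(
                _result_row(f"texture/{tcfg.model}", res, int(labels.sum()),
                            int((1 - labels).sum()))
            )
            logger.info("texture LOOCV accuracy %.3f auc %.3f", res.accuracy, res.auc)

    # ---- topology track
    if config.track in ("topology", "both"):
        ocfg = config.topology
        dgm_path = out / "diagrams.csv"
        digest = _hash({"manifest": str(manifest)})
        if want("extract-topology") and not _stage_fresh(out, "diagrams", digest):
            logger.info("computing persistence diagrams for %d volumes", len(grids))
            from .preprocess import normalize_to_255

            dgms = [persistence_diagrams(normalize_to_255(g), source_id=i)
                    for g, i in zip(grids, ids)]
            tio.save_diagrams(dgms, ids, dgm_path)
            _stage_done(out, "diagrams", digest)
        if want("classify"):
            by_id = tio.load_diagrams(dgm_path)
            model = clf.make_model(
                ocfg.model,
                {k: tuple(v) for k, v in ocfg.model_grid.items()} if ocfg.model_grid else None,
                config.inner_cv_folds,
                seeds["model"],
            )
            imager = PersistenceImager(**ocfg.pi.to_params().__dict__)
            for q in ocfg.degrees:
                X = imager.fit_transform([by_id[i][q] for i in ids])
                tio.save_pi_vectors(X, ocfg.pi.to_params(), out / f"pi_degree{q}")
                res = clf.loocv(model, X, labels)
                _save_result(out / f"topology_degree{q}_result.json", res, config)
                summary_rows.append(
                    _result_row(f"topology/deg{q}/{ocfg.model}", res, int(labels.sum()),
                                int((1 - labels).sum()))
                )
                logger.info("degree-%d LOOCV accuracy %.3f auc %.3f", q, res.accuracy, res.auc)

    if summary_rows:
        pd.DataFrame(summary_rows).to_csv(out / "summary.csv", index=False)
    return out


def _write_feature_csv(path, cube, ids, labels, param_list):
    frames = []
    for j, p in enumerate(param_list):
        df = pd.DataFrame(cube[:, j, :], columns=FEATURE_NAMES)
        df.insert(0, "id", ids)
        df.insert(1, "label", labels)
        df.insert(2, "R", p.wavelet_ratio)
        df.insert(3, "iso", "native" if p.iso_voxel is None else p.iso_voxel)
        df.insert(4, "Ng", p.n_gray_levels)
        df.insert(5, "algorithm", p.quant_algorithm)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _save_result(path: Path, res: clf.EvaluationResult, config: PipelineConfig) -> None:
    from . import __version__

    payload = {
        "scores": res.scores.tolist(),
        "y_true": res.y_true.tolist(),
        "y_pred": res.y_pred.tolist(),
        "confusion": {"tp": res.tp, "fp": res.fp, "tn": res.tn, "fn": res.fn},
        "metrics": res.summary(),
        "roc": {"fpr": res.roc[0].tolist(), "tpr": res.roc[1].tolist()},
        "provenance": {
            "config_hash": _hash(config.model_dump()),
            "seed": config.seed,
            "version": __version__,
        },
    }
    path.write_text(json.dumps(payload, indent=2))
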