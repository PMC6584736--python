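"""Reading and writing volumes, diagrams and feature tables."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from ._types import PersistenceDiagram, VoxelGrid

__all__ = [
    "save_volume",
    "load_volume",
    "save_manifest",
    "load_manifest",
    "save_diagrams",
    "load_diagrams",
    "save_pi_vectors",
]


def save_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a VoxelGrid as NIfTI (.nii/.nii.gz) or a raw .npz array."""
    path = Path(path)
    if path.suffix == ".npz" :
        np.savez(path, values=grid.values, spacing=np.array(grid.spacing))
        return path
    affine = np.diag([*grid.spacing, 1.0])
    nib.save(nib.Nifti1Image(grid.values, affine), str(path))
    return path


def load_volume(path: str | Path) -> VoxelGrid:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return VoxelGrid(z["values"], tuple(z["spacing"]))
    if path.suffix == ".npy":
        return VoxelGrid(np.load(path))
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return VoxelGrid(np.asarray(img.dataobj, dtype=np.float64), spacing)


def save_manifest(cohort, out_dir: str | Path, fmt: str = ".nii.gz") -> Path:
    """Write cohort volumes plus a manifest CSV (id, label, path, seed, shape,
    spacing)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (lesion_id, label, grid), item_seed in zip(cohort, cohort.item_seeds):
        p = out_dir / f"{lesion_id}{fmt}"
        save_volume(grid, p)
        rows.append(
            {
                "id": lesion_id,
                "label": int(label),
                "path": p.name,
                "seed": item_seed,
                "shape": "x".join(map(str, grid.shape)),
                "spacing": "x".join(f"{s:g}" for s in grid.spacing),
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_manifest(manifest: str | Path) -> tuple[list[VoxelGrid], np.ndarray, list[str]]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    grids = [load_volume(manifest.parent / p) for p in df["path"]]
    return grids, df["label"].to_numpy(), df["id"].astype(str).tolist()


def save_diagrams(
    diagrams: Sequence[dict[int, PersistenceDiagram]], ids: Sequence[str], path: str | Path
) -> Path:
    rows = []
    for lesion_id, dgms in zip(ids, diagrams):
        for q, dg in dgms.items():
            for b, d, e in zip(dg.births, dg.deaths, dg.essential):
                rows.append(
                    {"lesion_id": lesion_id, "degree": q, "birth": b, "death": d,
                     "essential": bool(e)}
                )
    path = Path(path)
    pd.DataFrame(rows, columns=["lesion_id", "degree", "birth", "death", "essential"]).to_csv(
        path, index=False
    )
    return path


def load_diagrams(path: str | Path) -> dict[str, dict[int, PersistenceDiagram]]:
    df = pd.read_csv(path)
    out: dict[str, dict[int, PersistenceDiagram]] = {}
    for lesion_id, sub in df.groupby("lesion_id", sort=False):
        dgms = {}
        for q in (0, 1, 2):
            s = sub[sub["degree"] == q]
            dgms[q] = PersistenceDiagram(
                q, s["birth"].to_numpy(), s["death"].to_numpy(),
                s["essential"].to_numpy(bool), source_id=str(lesion_id),
            )
        out[str(lesion_id)] = dgms
    return out


def save_pi_vectors(vectors: np.ndarray, params, path: str | Path) -> Path:
    """Flat PI vectors with a JSON sidecar recording mesh/params/ordering."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), vectors)
    sidecar = {
        "mesh": params.mesh, "C": params.C, "p": params.p, "sigma": params.sigma,
        "ordering": "row-major birth-then-death",
        "domain": [-0.5, 255.5],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npy")
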