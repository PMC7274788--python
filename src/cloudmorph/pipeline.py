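"""Reproducible stage runner with content-hash caching.

A run manifest records, per stage, the configuration and seed; the runner
executes the synthetic end-to-end stage graph

    synth -> segment -> isla -> frames -> embed

caching every stage's outputs in the working directory under a key derived
from its own configuration plus the upstream cache key. Re-running an
unchanged manifest reuses every cached artifact; changing one stage's
configuration or seed invalidates that stage and everything downstream, and
nothing upstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from . import embed, frames, isla, segment, synthgen
from .core import IntensityVolume, LabelVolume, PointCloud

STAGE_ORDER = ["synth", "segment", "isla", "frames", "embed"]


@dataclass
class RunManifest:
    stages: dict
    version: str = "0.1.0"
    hashes: dict = field(default_factory=dict)

    @classmethod
    def default(cls, seed: int = 0) -> "RunManifest":
        return cls(stages={
            "synth": {"n_cells": 6, "shape": [80, 80, 80],
                      "spacing": [0.225, 0.099, 0.099], "seed": seed,
                      "noise_sd": 0.0},
            "segment": {"min_size": 1000, "max_size": 250_000},
            "isla": {"n_points": 400, "seed": seed},
            "frames": {"seed": seed},
            "embed": {"k": 8, "n_neighbors": 10, "n_keep": 10, "seed": seed},
        })

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"version": self.version, "stages": self.stages,
             "hashes": self.hashes}, indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(stages=data["stages"], version=data.get("version", ""),
                   hashes=data.get("hashes", {}))


def _stage_hash(name: str, config: dict, upstream: str) -> str:
    payload = json.dumps({"stage": name, "config": config,
                          "upstream": upstream}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _run_synth(cfg: dict, _inputs: dict) -> dict:
    tissue = synthgen.generate_membrane_volume(
        n_cells=cfg["n_cells"], shape=tuple(cfg["shape"]),
        spacing=tuple(cfg["spacing"]), rng=cfg.get("seed", 0),
        noise_sd=cfg.get("noise_sd", 0.0))
    return {"image": tissue.image.voxels, "truth": tissue.truth.voxels,
            "spacing": np.array(tissue.image.spacing)}


def _run_segment(cfg: dict, inputs: dict) -> dict:
    up = inputs["synth"]
    vol = IntensityVolume(up["image"], tuple(up["spacing"]))
    seg_cfg = segment.SegmentationConfig(
        min_size=cfg.get("min_size", 1000),
        max_size=cfg.get("max_size", 1_000_000))
    labels = segment.segment_cells(vol, seg_cfg)
    return {"labels": labels.voxels, "spacing": np.array(labels.spacing)}


def _run_isla(cfg: dict, inputs: dict) -> dict:
    up = inputs["segment"]
    labels = LabelVolume(up["labels"], tuple(up["spacing"]))
    rng = np.random.default_rng(cfg.get("seed", 0))
    clouds, ids = [], []
    for lab in labels.labels():
        mask = labels.voxels == lab
        hull = isla.boundary_inner_hull(mask)
        vol = IntensityVolume(hull.astype(float), labels.spacing)
        cloud = isla.sample_landmarks(vol, n_points=cfg.get("n_points", 2000),
                                      rng=rng, cell_id=str(lab))
        clouds.append(cloud.points)
        ids.append(lab)
    return {"clouds": np.stack(clouds), "ids": np.array(ids),
            "spacing": up["spacing"]}


def _run_frames(cfg: dict, inputs: dict) -> dict:
    seg_out = inputs["segment"]
    isla_out = inputs["isla"]
    labels = LabelVolume(seg_out["labels"], tuple(seg_out["spacing"]))
    transform = frames.fit_tfor(labels.voxels > 0, labels.spacing,
                                rng=cfg.get("seed", 0))
    tfor_pts, pd_reps = [], []
    for pts in isla_out["clouds"]:
        cloud = PointCloud(pts, frame="raw")
        tfor_pts.append(frames.apply_tfor(cloud, transform).points)
        pd_reps.append(frames.cfor_pipeline(cloud).rep)
    return {"tfor_clouds": np.stack(tfor_pts), "pd_clouds": np.stack(pd_reps),
            "ids": isla_out["ids"], "rotation": transform.rotation,
            "translation": transform.translation}


def _run_embed(cfg: dict, inputs: dict) -> dict:
    up = inputs["frames"]
    seed = cfg.get("seed", 0)
    pd_clouds = [up["pd_clouds"][i] for i in range(up["pd_clouds"].shape[0])]
    refs = embed.fit_reference_clusters(
        {"sample0": pd_clouds}, k=cfg.get("k", 20),
        condense_k=min(cfg.get("condense_k", 500), pd_clouds[0].shape[0]),
        frame="CFOR", rng=seed)
    fm = embed.cbe_feature_matrix(pd_clouds, refs,
                                  n_neighbors=cfg.get("n_neighbors", 25),
                                  row_ids=[str(i) for i in up["ids"]])
    n_keep = min(cfg.get("n_keep", 20), fm.n_samples - 1, fm.n_features)
    pcs, model = embed.pca_reduce(fm, n_keep=n_keep)
    return {"features": fm.values, "pcs": pcs.values,
            "explained_variance": model.explained_variance_ratios,
            "ref_centers": refs.centers, "ids": up["ids"]}


_STAGE_FUNCS: dict[str, Callable] = {
    "synth": _run_synth,
    "segment": _run_segment,
    "isla": _run_isla,
    "frames": _run_frames,
    "embed": _run_embed,
}

_STAGE_PARENTS = {
    "synth": [],
    "segment": ["synth"],
    "isla": ["segment"],
    "frames": ["segment", "isla"],
    "embed": ["frames"],
}


def run_pipeline(manifest: RunManifest, workdir) -> dict:
    """Execute the stage graph with hash-based caching.

    Returns ``{stage: outputs}`` where outputs are dicts of arrays, and
    updates ``manifest.hashes`` with each stage's cache key. A stage whose
    key matches an existing cache file is loaded instead of recomputed.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, dict] = {}
    hashes: dict[str, str] = {}
    for name in STAGE_ORDER:
        if name not in manifest.stages:
            continue
        cfg = manifest.stages[name]
        upstream = "|".join(hashes[p] for p in _STAGE_PARENTS[name]
                            if p in hashes)
        key = _stage_hash(name, cfg, upstream)
        hashes[name] = key
        cache = workdir / f"{name}-{key}.npz"
        if cache.exists():
            with np.load(cache) as data:
                outputs[name] = {k: data[k] for k in data.files}
        else:
            try:
                result = _STAGE_FUNCS[name](cfg, outputs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            np.savez_compressed(cache, **result)
            outputs[name] = result
    manifest.hashes = hashes
    return outputs
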