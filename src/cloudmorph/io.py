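"""Readers and writers: TIFF volumes, point-cloud containers, feature tables.

Volumes travel as multi-page TIFF with the (z, y, x) voxel spacing in µm in
the ImageJ-style metadata or a JSON sidecar (``<path>.spacing.json``); clouds
travel as a compressed NPZ container with an index of cell/sample ids and
frame tags; tables are CSV with a ``#``-prefixed provenance header block.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .core import IntensityVolume, LabelVolume, PointCloud


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def write_volume(path, volume: Union[IntensityVolume, LabelVolume]) -> None:
    """Write a volume as TIFF plus a spacing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume.voxels))
    sidecar = path.with_name(path.name + ".spacing.json")
    sidecar.write_text(json.dumps({"spacing_zyx_um": list(volume.spacing)}))


def read_volume(path, spacing: Optional[Sequence[float]] = None,
                labels: Optional[bool] = None
                ) -> Union[IntensityVolume, LabelVolume]:
    """Read a multi-page TIFF as an intensity or label volume.

    Spacing is taken from the ``<path>.spacing.json`` sidecar or the explicit
    ``spacing`` argument; a missing spacing raises. Whether the file holds
    labels is inferred from integer content unless ``labels`` is forced.
    8-bit data round-trips losslessly; wider integer types are accepted with
    a warning (the pipeline's histogram statistics assume 8-bit).
    """
    path = Path(path)
    vox = tifffile.imread(path)
    if vox.ndim != 3:
        raise ValueError(f"expected a 3D stack, got shape {vox.shape}")
    if spacing is None:
        sidecar = path.with_name(path.name + ".spacing.json")
        if not sidecar.exists():
            raise ValueError(
                f"no spacing metadata for {path}; pass spacing explicitly "
                "(e.g. --spacing Z Y X in µm)")
        spacing = json.loads(sidecar.read_text())["spacing_zyx_um"]
    is_int = np.issubdtype(vox.dtype, np.integer)
    if is_int and vox.dtype.itemsize > 1 and not (labels or False):
        warnings.warn(f"{path.name}: {vox.dtype} input; pipeline statistics "
                      "assume 8-bit intensities")
    if labels is None:
        labels = bool(is_int and vox.dtype.itemsize <= 4
                      and np.unique(vox).size <= max(4096, vox.size // 100)
                      and vox.min() >= 0 and not np.issubdtype(vox.dtype, np.uint8))
    if labels:
        return LabelVolume(vox.astype(np.int32), tuple(spacing))
    return IntensityVolume(vox, tuple(spacing))


# ---------------------------------------------------------------------------
# Point-cloud containers
# ---------------------------------------------------------------------------

def save_clouds(path, clouds: Sequence[PointCloud]) -> None:
    """Write clouds to a compressed NPZ container with an id/frame index."""
    arrays = {}
    index = []
    for i, c in enumerate(clouds):
        key = f"cloud_{i}"
        arrays[key] = c.points
        index.append({"key": key, "cell_id": c.cell_id,
                      "sample_id": c.sample_id, "frame": c.frame,
                      "n_points": int(c.n_points)})
    arrays["_index"] = np.frombuffer(
        json.dumps(index).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_clouds(path) -> list[PointCloud]:
    with np.load(path) as data:
        index = json.loads(bytes(data["_index"]).decode())
        return [PointCloud(data[e["key"]], frame=e["frame"],
                           cell_id=e["cell_id"], sample_id=e["sample_id"])
                for e in index]


# ---------------------------------------------------------------------------
# Tables with provenance headers
# ---------------------------------------------------------------------------

def write_table(path, df: pd.DataFrame, provenance: Optional[dict] = None) -> None:
    """CSV with a ``#``-prefixed provenance header block (stage, seed, ...)."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=True)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    provenance = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                provenance[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=skip, index_col=0)
    return df, provenance
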