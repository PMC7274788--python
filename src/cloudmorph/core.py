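"""Core data containers shared across the toolkit.

Conventions
-----------
* Voxel grids are indexed ``(z, y, x)``; physical voxel spacing is given in the
  same order, in micrometres.
* Point clouds are ``(n, 3)`` arrays of ``(z, y, x)`` coordinates in micrometres.
* A point cloud carries a *frame* tag recording which coordinate system it
  lives in: ``"raw"`` (acquisition frame), ``"TFOR"`` (tissue frame of
  reference) or ``"CFOR"`` (cell frame of reference, size-normalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

VALID_FRAMES = ("raw", "TFOR", "CFOR")


def _as_float_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (n, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite values")
    return pts


@dataclass
class IntensityVolume:
    """A 3D fluorescence intensity grid with physical voxel spacing (µm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (z, y, x)")
        if not np.all(np.isfinite(np.asarray(self.voxels, dtype=float))):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelVolume:
    """A 3D integer label grid; label 0 is background."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label voxels must be integer-typed")
        if self.voxels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def labels(self) -> np.ndarray:
        """Sorted positive labels present in the volume."""
        lab = np.unique(self.voxels)
        return lab[lab > 0]


@dataclass
class PointCloud:
    """An ``(n, 3)`` landmark cloud in µm with a frame tag and identifiers."""

    points: np.ndarray
    frame: str = "raw"
    cell_id: Optional[str] = None
    sample_id: Optional[str] = None

    def __post_init__(self):
        self.points = _as_float_points(self.points)
        if self.points.shape[0] < 1:
            raise ValueError("a point cloud needs at least one point")
        if self.frame not in VALID_FRAMES:
            raise ValueError(f"frame must be one of {VALID_FRAMES}, got {self.frame!r}")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def centered(self) -> "PointCloud":
        return replace(self, points=self.points - self.centroid())

    def with_points(self, points, frame: Optional[str] = None) -> "PointCloud":
        return replace(self, points=_as_float_points(points),
                       frame=self.frame if frame is None else frame)


@dataclass
class PDCloud:
    """Pairwise-distance re-representation of a cloud.

    Each landmark is described by the 10th, 50th and 90th percentiles of its
    distances to every other landmark — an ``(n, 3)`` array invariant to
    translation, rotation and handedness of the source cloud.
    """

    rep: np.ndarray
    cell_id: Optional[str] = None

    def __post_init__(self):
        self.rep = np.asarray(self.rep, dtype=float)
        if self.rep.ndim != 2 or self.rep.shape[1] != 3:
            raise ValueError("PDCloud rep must be (n, 3)")
        if self.rep.min() < 0:
            raise ValueError("pairwise-distance percentiles must be >= 0")
        if not (np.all(self.rep[:, 0] <= self.rep[:, 1] + 1e-12)
                and np.all(self.rep[:, 1] <= self.rep[:, 2] + 1e-12)):
            raise ValueError("percentile columns must be row-wise non-decreasing")


@dataclass
class FeatureMatrix:
    """A samples-by-features matrix with names, frame tag and provenance."""

    values: np.ndarray
    feature_names: Sequence[str]
    row_ids: Optional[Sequence[str]] = None
    frame: str = "raw"
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length mismatch")
        if self.row_ids is None:
            self.row_ids = [str(i) for i in range(self.values.shape[0])]
        else:
            self.row_ids = [str(r) for r in self.row_ids]
            if len(set(self.row_ids)) != len(self.row_ids):
                raise ValueError("row ids must be unique")
            if len(self.row_ids) != self.values.shape[0]:
                raise ValueError("row_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_ids,
                            columns=self.feature_names)
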