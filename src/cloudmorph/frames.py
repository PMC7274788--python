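"""Frames of reference for cellular point clouds.

TFOR (Tissue Frame Of Reference)
    Tissue-level alignment by principal-axis analysis of ~3000 landmarks
    sampled from the whole-tissue segmentation mask. Because the tissue's
    longest axis is its front–rear axis and its shortest is the apicobasal
    axis, ordering principal axes by variance snaps differently mounted
    acquisitions into a common frame; a sign convention prevents 180° flips
    and the frontal-most landmark is translated to the origin. TFOR is rigid:
    cell sizes and orientations keep their biological meaning.

CFOR (Cell Frame Of Reference)
    A per-cell representation invariant to position, size, rotation and
    handedness: the cloud is centered and scaled so the magnitudes of all
    centroid-to-landmark vectors sum to one, then re-represented by the 10th,
    50th and 90th percentiles of each landmark's pairwise distances to all
    other landmarks.

The module also extracts explicitly engineered single-cell shape features
(volume, surface area, sphericity, axis extents, centroid, orientation,
surface smoothness) used to anchor and interpret the learned embeddings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform
from skimage import measure

from .core import IntensityVolume, PDCloud, PointCloud
from . import isla

PD_PERCENTILES = (10.0, 50.0, 90.0)
TFOR_N_LANDMARKS = 3000
_SKEW_TIE_TOL = 1e-6


@dataclass
class TFORTransform:
    """Rigid map into the tissue frame: p' = p @ rotation.T + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    axis_signs: tuple[int, int, int]
    sample_id: Optional[str] = None

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.rotation))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


def fit_tfor(tissue_mask, spacing, rng=None,
             n_landmarks: int = TFOR_N_LANDMARKS,
             sample_id: Optional[str] = None) -> TFORTransform:
    """Fit the tissue frame from a binary whole-tissue mask.

    Landmarks are ISLA-sampled uniformly from the mask, principal axes are
    ordered by decreasing variance (axis 0 = front–rear, axis 2 = apicobasal),
    each axis sign is fixed so the landmark skewness along it is non-negative
    (preventing 180° flips between replicate acquisitions), and the frame is
    translated so the frontal-most landmark sits at the origin.
    """
    mask = np.asarray(tissue_mask).astype(bool)
    if not mask.any():
        raise ValueError("tissue mask is empty")
    vol = IntensityVolume(mask.astype(float), spacing)
    cloud = isla.sample_landmarks(vol, n_points=n_landmarks, rng=rng)
    pts = cloud.points
    mean = pts.mean(axis=0)
    centered = pts - mean
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    if evals[-1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("degenerate tissue mask: rank-deficient covariance")
    axes = evecs[:, order].T  # rows = principal axes, variance-descending

    scores = centered @ axes.T
    signs = []
    for k in range(3):
        skew = np.mean(scores[:, k] ** 3)
        if abs(skew) > _SKEW_TIE_TOL:
            s = 1 if skew > 0 else -1
        else:
            # Tie-break: make the landmark of largest magnitude positive.
            j = np.argmax(np.abs(scores[:, k]))
            s = 1 if scores[j, k] >= 0 else -1
        signs.append(s)
        scores[:, k] *= s
        axes[k] *= s

    # Origin: frontal-most landmark along the front-rear axis; the lateral
    # axes are centered on the landmark centroid (a single extreme landmark
    # would make the lateral origin noisy across replicate samplings).
    offset = np.array([scores[:, 0].min(), 0.0, 0.0])
    translation = -(mean @ axes.T) - offset
    return TFORTransform(rotation=axes, translation=translation,
                         axis_signs=tuple(signs), sample_id=sample_id)


def apply_tfor(clouds, transform: TFORTransform):
    """Rigidly map one cloud or a sequence of clouds into the tissue frame."""
    single = isinstance(clouds, PointCloud)
    items = [clouds] if single else list(clouds)
    out = []
    for c in items:
        if (c.sample_id is not None and transform.sample_id is not None
                and c.sample_id != transform.sample_id):
            raise ValueError(
                f"cloud sample_id {c.sample_id!r} does not match transform "
                f"sample_id {transform.sample_id!r}")
        if c.frame != "raw":
            raise ValueError(f"expected a raw-frame cloud, got {c.frame!r}")
        out.append(c.with_points(transform.apply(c.points), frame="TFOR"))
    return out[0] if single else out


def cfor_normalize(cloud: PointCloud) -> PointCloud:
    """Center a cloud and scale it so centroid-to-landmark magnitudes sum to 1."""
    pts = cloud.points - cloud.points.mean(axis=0)
    total = np.linalg.norm(pts, axis=1).sum()
    if total <= 0:
        raise ValueError("cannot normalize: all points are identical")
    return cloud.with_points(pts / total, frame="CFOR")


def pairwise_distance_representation(cloud: PointCloud,
                                     percentiles: Sequence[float] = PD_PERCENTILES
                                     ) -> PDCloud:
    """Per-landmark percentiles of pairwise distances to all other landmarks.

    Linear interpolation between order statistics; invariant to translation,
    rotation and reflection of the input by construction.
    """
    n = cloud.n_points
    if n < 2:
        raise ValueError("need at least 2 points")
    pts = cloud.points
    # Full distance matrix via the Gram identity (fast for large n).
    sq = np.einsum("ij,ij->i", pts, pts)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (pts @ pts.T)
    d = np.sqrt(np.clip(d2, 0.0, None))
    # Each row holds the n-1 distances to other landmarks plus one self-zero.
    # Distances are >= 0, so the k-th order statistic of the others is the
    # (k+1)-th of the full row (exact even with duplicate points); shifting
    # the percentile positions accordingly reproduces linear interpolation
    # over the reduced row without materializing it.
    q = np.asarray(percentiles, dtype=float) / 100.0 * (n - 2)
    q_full = (q + 1.0) / (n - 1) * 100.0
    rep = np.percentile(d, q_full, axis=1).T
    return PDCloud(rep, cell_id=cloud.cell_id)


def cfor_pipeline(cloud: PointCloud) -> PDCloud:
    """Full CFOR route: volume normalization followed by PD re-representation."""
    return pairwise_distance_representation(cfor_normalize(cloud))


# ---------------------------------------------------------------------------
# Engineered features
# ---------------------------------------------------------------------------

ENGINEERED_FEATURE_NAMES = [
    "volume_um3",
    "surface_area_um2",
    "sphericity",
    "extent_ax0_um", "extent_ax1_um", "extent_ax2_um",
    "centroid_ax0_um", "centroid_ax1_um", "centroid_ax2_um",
    "orientation_polar_rad", "orientation_azimuth_rad",
    "surface_smoothness",
]


def engineered_features(cell_mask, spacing, tfor_cloud: PointCloud) -> dict:
    """Engineered shape measures for one segmented cell.

    Parameters
    ----------
    cell_mask : 3D bool array
        The cell's binary voxel mask (cropped or full volume).
    spacing : (z, y, x) voxel spacing in µm.
    tfor_cloud : PointCloud
        The cell's landmarks in the tissue frame; extents, centroid and
        orientation are measured along the TFOR axes.

    Notes
    -----
    Volume is voxel count times voxel volume; surface area comes from a
    marching-cubes mesh of the mask in physical units; sphericity is
    ``pi**(1/3) * (6 V)**(2/3) / A`` (1 for a perfect ball); the surface
    smoothness proxy is the ratio of the cell's surface area to the surface
    area of its landmark convex hull (1 = smooth, larger = rougher).
    """
    mask = np.asarray(cell_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    spacing = tuple(float(s) for s in spacing)
    voxvol = spacing[0] * spacing[1] * spacing[2]
    volume = mask.sum() * voxvol

    # Mild smoothing before meshing suppresses the staircase bias of
    # marching cubes on a binary mask.
    from scipy import ndimage as ndi

    padded = ndi.gaussian_filter(np.pad(mask, 2).astype(float), sigma=1.0)
    if padded.max() <= 0.5:  # tiny masks: smoothing washes out the surface
        padded = np.pad(mask, 2).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    area = measure.mesh_surface_area(verts, faces)
    sphericity = (math.pi ** (1 / 3)) * (6 * volume) ** (2 / 3) / area

    pts = tfor_cloud.points
    extents = pts.max(axis=0) - pts.min(axis=0)
    centroid = pts.mean(axis=0)

    centered = pts - centroid
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if major[0] < 0:
        major = -major
    polar = math.acos(np.clip(abs(major[0]), 0, 1))
    azimuth = math.atan2(major[1], major[2])

    try:
        hull_area = ConvexHull(pts).area
        smoothness = area / hull_area
    except Exception:
        smoothness = float("nan")

    return {
        "volume_um3": float(volume),
        "surface_area_um2": float(area),
        "sphericity": float(sphericity),
        "extent_ax0_um": float(extents[0]),
        "extent_ax1_um": float(extents[1]),
        "extent_ax2_um": float(extents[2]),
        "centroid_ax0_um": float(centroid[0]),
        "centroid_ax1_um": float(centroid[1]),
        "centroid_ax2_um": float(centroid[2]),
        "orientation_polar_rad": float(polar),
        "orientation_azimuth_rad": float(azimuth),
        "surface_smoothness": float(smoothness),
    }


def engineered_feature_table(rows: Iterable[dict],
                             ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Stack per-cell engineered-feature dicts into a table."""
    df = pd.DataFrame(list(rows))
    if ids is not None:
        df.index = list(ids)
    return df
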