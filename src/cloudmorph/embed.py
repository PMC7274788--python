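"""Cluster-Based Embedding (CBE) and the moments baseline.

CBE re-represents every cell's point cloud by its relationship to a *shared*
set of reference points, making cells directly comparable without landmark
correspondence:

1. Per-cell clouds are centered on their centroids and condensed from 2000 to
   500 landmarks by k-means.
2. Clouds from a representative random subset of samples (at least 10, at
   most 25) are overlaid, density-dependent downsampling caps the overlay at
   200,000 points while flattening local density peaks, and k-means with
   k = 20 on the overlay yields the consensus reference centers.
3. Each cell is then described, per reference center, by the vector from the
   center to the centroid of its 25 nearest cloud landmarks (3k features), or
   by that vector's magnitude (k features).
4. The feature space is standardized and PCA-transformed; PC signs can be
   anchored to positively correlate with their most defining engineered
   feature.

Density-dependent downsampling keeps each point with probability 1 if its
local density LD (neighbors within a sphere of radius = median pairwise
distance x 5) is below the target density TD (3rd percentile of all LD), and
with probability TD/LD otherwise.

The moments baseline embeds a cloud by 55 distribution moments: the 3 first
raw moments, the 6 second centralized moments, and the 10 + 15 + 21 third-to-
fifth standardized moments over all axis-exponent triples (i, j, k) with
i + j + k = m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans, MiniBatchKMeans
from sklearn.decomposition import PCA

from .core import FeatureMatrix, PDCloud, PointCloud

DEFAULT_K_REFS = 20
DEFAULT_CONDENSE_K = 500
DEFAULT_N_NEIGHBORS = 25
MAX_OVERLAY_POINTS = 200_000
DENSITY_RADIUS_FACTOR = 5.0
DENSITY_TARGET_PERCENTILE = 3.0
_MEDIAN_PAIR_SAMPLE = 1_000_000
_MEDIAN_EXACT_LIMIT = 20_000


def _points_of(cloud) -> np.ndarray:
    if isinstance(cloud, PointCloud):
        return cloud.points
    if isinstance(cloud, PDCloud):
        return cloud.rep
    return np.asarray(cloud, dtype=float)


@dataclass
class ReferenceClusters:
    """Consensus k-means centers shared by all cells of a dataset."""

    centers: np.ndarray
    frame: str
    source_samples: tuple[str, ...]
    seed: int

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("centers must be (k, 3)")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")

    @property
    def k(self) -> int:
        return self.centers.shape[0]


@dataclass
class PCAModel:
    """Fitted standardize-then-PCA reduction with per-PC sign conventions."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray
    explained_variance_ratios: np.ndarray
    sign_flips: np.ndarray
    feature_names: list = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.components.shape[0]

    def transform(self, values: np.ndarray) -> np.ndarray:
        x = (np.asarray(values, dtype=float) - self.mean) / self.scale
        return (x @ self.components.T) * self.sign_flips


# ---------------------------------------------------------------------------
# Density-dependent downsampling
# ---------------------------------------------------------------------------

def median_pairwise_distance(points: np.ndarray, rng=None,
                             exact_limit: int = _MEDIAN_EXACT_LIMIT) -> float:
    """Median pairwise distance; estimated from 1e6 random pairs above exact_limit."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if n <= exact_limit:
        from scipy.spatial.distance import pdist

        return float(np.median(pdist(points)))
    rng = np.random.default_rng(rng)
    i = rng.integers(0, n, _MEDIAN_PAIR_SAMPLE)
    j = rng.integers(0, n, _MEDIAN_PAIR_SAMPLE)
    keep = i != j
    return float(np.median(np.linalg.norm(points[i[keep]] - points[j[keep]], axis=1)))


def local_densities(points: np.ndarray, radius: float) -> np.ndarray:
    """Number of other points within ``radius`` of each point."""
    n = points.shape[0]
    diag = float(np.linalg.norm(np.ptp(points, axis=0)))
    if radius >= diag:  # every ball covers the whole cloud (exact shortcut)
        return np.full(n, n - 1, dtype=float)
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, radius, return_length=True)
    return np.asarray(counts, dtype=float) - 1.0  # exclude the point itself


def density_dependent_downsample(cloud, radius_factor: float = DENSITY_RADIUS_FACTOR,
                                 target_percentile: float = DENSITY_TARGET_PERCENTILE,
                                 max_points: int = MAX_OVERLAY_POINTS,
                                 rng=None):
    """Downsample a cloud so local density peaks are flattened.

    Each point is kept with probability 1 if its local density is below the
    target density (the ``target_percentile``-th percentile of all local
    densities) and with probability TD/LD otherwise; if more than
    ``max_points`` survive, a uniform random subsample enforces the cap.
    Returns (points_kept, keep_probabilities).
    """
    points = _points_of(cloud)
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points to downsample")
    rng = np.random.default_rng(rng)
    radius = median_pairwise_distance(points, rng=rng) * radius_factor
    ld = local_densities(points, radius)
    td = np.percentile(ld, target_percentile)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_keep = np.where(ld < td, 1.0, np.where(ld > 0, td / ld, 1.0))
    p_keep = np.clip(p_keep, 0.0, 1.0)
    keep = rng.random(points.shape[0]) < p_keep
    kept = points[keep]
    if kept.shape[0] > max_points:
        idx = rng.choice(kept.shape[0], size=max_points, replace=False)
        kept = kept[idx]
    return kept, p_keep


# ---------------------------------------------------------------------------
# Cloud condensation and reference clusters
# ---------------------------------------------------------------------------

def condense_cloud(cloud, k: int = DEFAULT_CONDENSE_K, rng=None) -> np.ndarray:
    """Replace a cloud by the centers of a k-means clustering of its points."""
    points = _points_of(cloud)
    if points.shape[0] < k:
        raise ValueError(f"cloud has {points.shape[0]} points, fewer than k={k}")
    if k == points.shape[0]:
        return points.copy()
    seed = int(np.random.default_rng(rng).integers(2**31))
    if k == 1:
        return points.mean(axis=0, keepdims=True)
    if points.shape[0] > 50_000:  # mini-batch for very large clouds
        km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3,
                             batch_size=max(1024, 4 * k))
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=1, max_iter=10)
    km.fit(points)
    return km.cluster_centers_


def fit_reference_clusters(clouds_by_sample: Mapping[str, Sequence],
                           k: int = DEFAULT_K_REFS,
                           subset_min: int = 10, subset_max: int = 25,
                           condense_k: int = DEFAULT_CONDENSE_K,
                           frame: str = "CFOR",
                           rng=None) -> ReferenceClusters:
    """Fit the consensus reference centers shared across all samples.

    Per-cell clouds (grouped by sample) are centered, condensed to
    ``condense_k`` landmarks, overlaid across a random representative subset
    of samples, density-downsampled to at most 200,000 points, and k-means
    clustered with ``k`` clusters.
    """
    if len(clouds_by_sample) < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31))
    sample_ids = sorted(clouds_by_sample)
    if len(sample_ids) <= subset_min:
        picked = sample_ids
    else:
        hi = min(len(sample_ids), subset_max)
        n_pick = int(rng.integers(subset_min, hi + 1))
        picked = sorted(rng.choice(sample_ids, size=n_pick, replace=False).tolist())

    overlays = []
    for sid in picked:
        for cloud in clouds_by_sample[sid]:
            pts = _points_of(cloud)
            pts = pts - pts.mean(axis=0)
            if pts.shape[0] > condense_k:
                pts = condense_cloud(pts, k=condense_k, rng=rng)
            overlays.append(pts)
    overlay = np.concatenate(overlays, axis=0)
    if overlay.shape[0] < k:
        raise ValueError(f"only {overlay.shape[0]} overlaid points for k={k}")
    if overlay.shape[0] > 2:
        overlay, _ = density_dependent_downsample(overlay, rng=rng)
    km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3,
                         batch_size=max(1024, 10 * k))
    km.fit(overlay)
    return ReferenceClusters(centers=km.cluster_centers_, frame=frame,
                             source_samples=tuple(picked), seed=seed)


# ---------------------------------------------------------------------------
# Per-cell CBE features
# ---------------------------------------------------------------------------

def cbe_features(cloud, refs: ReferenceClusters, variant: str = "vectors",
                 n_neighbors: int = DEFAULT_N_NEIGHBORS) -> np.ndarray:
    """CBE feature row for one cell.

    For each reference center, the vector from the center to the centroid of
    the ``n_neighbors`` nearest cloud landmarks; ``variant="vectors"`` returns
    the 3k components, ``variant="magnitudes"`` the k Euclidean norms. The
    cloud is centered on its centroid first, mirroring the overlay step of
    reference-cluster fitting.
    """
    points = _points_of(cloud)
    if points.shape[0] < n_neighbors:
        raise ValueError(f"cloud has {points.shape[0]} points, "
                         f"fewer than n_neighbors={n_neighbors}")
    if isinstance(cloud, PointCloud) and refs.frame != cloud.frame:
        raise ValueError(f"cloud frame {cloud.frame!r} does not match "
                         f"reference frame {refs.frame!r}")
    points = points - points.mean(axis=0)
    tree = cKDTree(points)
    _, idx = tree.query(refs.centers, k=n_neighbors)
    if n_neighbors == 1:
        idx = idx[:, None]
    neighbor_centroids = points[idx].mean(axis=1)
    vectors = neighbor_centroids - refs.centers
    if variant == "vectors":
        return vectors.ravel()
    if variant == "magnitudes":
        return np.linalg.norm(vectors, axis=1)
    raise ValueError(f"unknown variant {variant!r}")


def cbe_feature_matrix(clouds: Sequence, refs: ReferenceClusters,
                       variant: str = "vectors",
                       n_neighbors: int = DEFAULT_N_NEIGHBORS,
                       row_ids: Optional[Sequence[str]] = None) -> FeatureMatrix:
    """Stack CBE rows for many cells into a FeatureMatrix."""
    rows = np.stack([cbe_features(c, refs, variant, n_neighbors) for c in clouds])
    if variant == "vectors":
        names = [f"ref{j}_{ax}" for j in range(refs.k) for ax in "zyx"]
    else:
        names = [f"ref{j}_mag" for j in range(refs.k)]
    return FeatureMatrix(rows, feature_names=names, row_ids=row_ids,
                         frame=refs.frame, provenance=f"CBE-{variant}")


# ---------------------------------------------------------------------------
# PCA reduction with sign anchoring
# ---------------------------------------------------------------------------

def pca_reduce(features: FeatureMatrix, n_keep: int = 20,
               sign_anchor=None) -> tuple[FeatureMatrix, PCAModel]:
    """Standardize, project onto principal components and fix PC signs.

    If ``sign_anchor`` (a per-cell engineered feature table aligned row-wise
    with ``features``) is given, each PC's sign is flipped if needed so the PC
    positively correlates with its most defining engineered feature.
    """
    if features.n_samples < 2:
        raise ValueError("need at least 2 samples for PCA")
    x = features.values
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0  # zero-variance guard
    xs = (x - mean) / scale
    n_keep = min(n_keep, min(xs.shape))
    pca = PCA(n_components=n_keep, svd_solver="full")
    scores = pca.fit_transform(xs)

    flips = np.ones(n_keep)
    if sign_anchor is not None:
        anchor = np.asarray(sign_anchor, dtype=float) if not hasattr(sign_anchor, "values") \
            else np.asarray(sign_anchor.values, dtype=float)
        if anchor.ndim == 1:
            anchor = anchor[:, None]
        if anchor.shape[0] != scores.shape[0]:
            raise ValueError("sign_anchor rows must match feature rows")
        a_std = anchor.std(axis=0)
        usable = a_std > 0
        for j in range(n_keep):
            s_std = scores[:, j].std()
            if s_std == 0 or not usable.any():
                continue
            corr = np.zeros(anchor.shape[1])
            sc = scores[:, j] - scores[:, j].mean()
            ac = anchor - anchor.mean(axis=0)
            corr[usable] = (sc @ ac[:, usable]) / (
                (scores.shape[0]) * s_std * a_std[usable])
            best = np.argmax(np.abs(corr))
            if corr[best] < 0:
                flips[j] = -1.0
        scores = scores * flips

    model = PCAModel(mean=mean, scale=scale, components=pca.components_,
                     explained_variance_ratios=pca.explained_variance_ratio_,
                     sign_flips=flips, feature_names=list(features.feature_names))
    pcs = FeatureMatrix(scores, feature_names=[f"PC{i+1}" for i in range(n_keep)],
                        row_ids=features.row_ids, frame=features.frame,
                        provenance=features.provenance + "+PCA")
    return pcs, model


# ---------------------------------------------------------------------------
# Moments baseline
# ---------------------------------------------------------------------------

def _moment_triples(m: int) -> list[tuple[int, int, int]]:
    return [(i, j, k) for i in range(m + 1) for j in range(m + 1)
            for k in range(m + 1) if i + j + k == m]


def moments_feature_names() -> list[str]:
    names = [f"rM1_{i}{j}{k}" for i, j, k in _moment_triples(1)]
    names += [f"cM2_{i}{j}{k}" for i, j, k in _moment_triples(2)]
    for m in (3, 4, 5):
        names += [f"nM{m}_{i}{j}{k}" for i, j, k in _moment_triples(m)]
    return names


def moments_features(cloud) -> np.ndarray:
    """55-dimensional moments embedding of a cloud.

    First raw moments (3), second centralized moments (6) and third-to-fifth
    standardized moments (10 + 15 + 21), over all axis-exponent triples
    (i, j, k) with i + j + k = m; standardized moments divide by
    ``std_z**i * std_y**j * std_x**k``.
    """
    points = _points_of(cloud)
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    cz, cy, cx = points[:, 0], points[:, 1], points[:, 2]
    means = points.mean(axis=0)
    stds = points.std(axis=0)
    if np.any(stds == 0):
        raise ValueError("zero spread along an axis: standardized moments undefined")
    dz, dy, dx = cz - means[0], cy - means[1], cx - means[2]

    # First raw moments, in the same (i, j, k) triple order as the names.
    feats = [np.mean(cz**i * cy**j * cx**k) for i, j, k in _moment_triples(1)]
    # Precompute powers up to 5.
    pz = [np.ones_like(dz), dz, dz**2, dz**3, dz**4, dz**5]
    py = [np.ones_like(dy), dy, dy**2, dy**3, dy**4, dy**5]
    px = [np.ones_like(dx), dx, dx**2, dx**3, dx**4, dx**5]
    for i, j, k in _moment_triples(2):
        feats.append(np.mean(pz[i] * py[j] * px[k]))
    for m in (3, 4, 5):
        for i, j, k in _moment_triples(m):
            cm = np.mean(pz[i] * py[j] * px[k])
            feats.append(cm / (stds[0]**i * stds[1]**j * stds[2]**k))
    return np.array(feats, dtype=float)


def moments_feature_matrix(clouds: Sequence,
                           row_ids: Optional[Sequence[str]] = None,
                           frame: str = "raw") -> FeatureMatrix:
    rows = np.stack([moments_features(c) for c in clouds])
    return FeatureMatrix(rows, feature_names=moments_feature_names(),
                         row_ids=row_ids, frame=frame, provenance="moments")
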