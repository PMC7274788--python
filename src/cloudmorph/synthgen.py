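"""Synthetic cell-like point clouds with known generative parameters.

The generator builds a cell in four stages:

1. **Spine** (5 parameters): a curve along the apicobasal (z) axis defined by
   its height, the lateral offset of its end point relative to its start point
   (distance + angle), and a second-degree polynomial bend with one curvature
   coefficient per lateral axis (end points pinned).
2. **Surface** (9 parameters): the distance from the spine to the surface as a
   function of normalized height is a logit-normal curve — it vanishes at both
   ends, is positive in between, and can be symmetric, skewed or bimodal with
   only two parameters (µ, σ). Three such curves, each with its own
   multiplicative scale, describe the surface at three angles (0°, 120°, 240°)
   around the spine; radii in between are linearly interpolated in angle.
3. **Sampling** (0 parameters): 2000 surface points are drawn with uniform
   random height and angle.
4. **Centering, scaling, rotation** (3 parameters): the cloud is centered on
   its centroid, multiplied by a size scale and rotated by two angles.

That is 17 scalar parameters in total, of which exactly one (``size_scale``)
changes only size and exactly two (``rotation_angles``) change only
orientation; the remaining 14 are shape parameters. Because the random draws
of stage 3 depend only on the seed, two cells generated from the same seed but
different size/rotation parameters are point-for-point similar — the property
the cell-frame-of-reference (CFOR) normalization is designed to exploit.

The module also provides fixture builders for the rest of the toolkit: a
membrane-labeled tissue volume with ground-truth labels, and paired
reference/target feature matrices for regression benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import FeatureMatrix, IntensityVolume, LabelVolume, PointCloud

N_POINTS = 2000
SURFACE_ANGLES = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])

#: Canonical ordering of the 17 scalar parameters.
PARAM_NAMES = [
    "spine_height",
    "spine_offset_distance",
    "spine_offset_angle",
    "spine_curve_y",
    "spine_curve_x",
    "surface_mu_0", "surface_sigma_0",
    "surface_mu_1", "surface_sigma_1",
    "surface_mu_2", "surface_sigma_2",
    "surface_scale_0", "surface_scale_1", "surface_scale_2",
    "size_scale",
    "rotation_angle_1",
    "rotation_angle_2",
]

SIZE_PARAM_NAMES = ["size_scale"]
ROTATION_PARAM_NAMES = ["rotation_angle_1", "rotation_angle_2"]
SHAPE_PARAM_NAMES = [n for n in PARAM_NAMES
                     if n not in SIZE_PARAM_NAMES + ROTATION_PARAM_NAMES]


def logitnormal(t, mu: float, sigma: float):
    """Logit-normal density on (0, 1); 0 at both endpoints, positive inside."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    inside = (t > 0) & (t < 1)
    ti = t[inside]
    logit = np.log(ti / (1 - ti))
    out[inside] = (np.exp(-((logit - mu) ** 2) / (2 * sigma**2))
                   / (sigma * math.sqrt(2 * math.pi) * ti * (1 - ti)))
    return out


@dataclass
class GeneratorParams:
    """The 17 generative parameters of one synthetic cell."""

    spine_height: float
    spine_offset_distance: float
    spine_offset_angle: float
    spine_curve_coeffs: tuple[float, float]          # (y, x) quadratic bend
    surface_logitnormal_params: tuple[tuple[float, float], ...]  # 3 x (mu, sigma)
    surface_scales: tuple[float, float, float]
    size_scale: float
    rotation_angles: tuple[float, float]

    def __post_init__(self):
        self.spine_curve_coeffs = tuple(float(c) for c in self.spine_curve_coeffs)
        self.surface_logitnormal_params = tuple(
            (float(m), float(s)) for m, s in self.surface_logitnormal_params)
        self.surface_scales = tuple(float(s) for s in self.surface_scales)
        self.rotation_angles = tuple(float(a) for a in self.rotation_angles)
        if len(self.spine_curve_coeffs) != 2:
            raise ValueError("spine_curve_coeffs must have 2 entries")
        if len(self.surface_logitnormal_params) != 3:
            raise ValueError("three (mu, sigma) pairs required")
        if len(self.surface_scales) != 3:
            raise ValueError("three surface scales required")
        if len(self.rotation_angles) != 2:
            raise ValueError("two rotation angles required")
        if any(s <= 0 for s in self.surface_scales):
            raise ValueError("surface_scales must be > 0")
        if self.size_scale <= 0:
            raise ValueError("size_scale must be > 0")
        if any(s <= 0 for _, s in self.surface_logitnormal_params):
            raise ValueError("logit-normal sigma must be > 0")

    def to_array(self) -> np.ndarray:
        """Flatten to the canonical 17-vector (order = PARAM_NAMES)."""
        vals = [self.spine_height, self.spine_offset_distance,
                self.spine_offset_angle, *self.spine_curve_coeffs]
        for mu, sigma in self.surface_logitnormal_params:
            vals.extend([mu, sigma])
        vals.extend(self.surface_scales)
        vals.append(self.size_scale)
        vals.extend(self.rotation_angles)
        return np.array(vals, dtype=float)

    @classmethod
    def from_array(cls, arr) -> "GeneratorParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (17,):
            raise ValueError("expected a 17-vector")
        return cls(
            spine_height=arr[0],
            spine_offset_distance=arr[1],
            spine_offset_angle=arr[2],
            spine_curve_coeffs=(arr[3], arr[4]),
            surface_logitnormal_params=((arr[5], arr[6]), (arr[7], arr[8]),
                                        (arr[9], arr[10])),
            surface_scales=(arr[11], arr[12], arr[13]),
            size_scale=arr[14],
            rotation_angles=(arr[15], arr[16]),
        )


@dataclass
class SyntheticCell:
    cloud: PointCloud
    params: GeneratorParams
    seed: int


@dataclass
class SyntheticTissue:
    """Membrane-like image + ground-truth labels (+ optional second channel)."""

    image: IntensityVolume
    truth: LabelVolume
    secondary: Optional[IntensityVolume] = None
    seed_points: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

#: Default hyperparameter distributions. These are this package's own choices
#: (tuned so that a varied population of plausible, non-self-intersecting
#: shapes is produced); each entry is ("normal", mean, sd) or
#: ("uniform", low, high).
DEFAULT_HYPER: dict[str, tuple] = {
    "spine_height": ("uniform", 0.7, 1.3),
    "spine_offset_distance": ("uniform", 0.0, 0.3),
    "spine_offset_angle": ("uniform", 0.0, 2 * np.pi),
    "spine_curve_y": ("normal", 0.0, 0.1),
    "spine_curve_x": ("normal", 0.0, 0.1),
    "surface_mu_0": ("normal", 0.0, 0.4),
    "surface_sigma_0": ("uniform", 0.7, 1.3),
    "surface_mu_1": ("normal", 0.0, 0.4),
    "surface_sigma_1": ("uniform", 0.7, 1.3),
    "surface_mu_2": ("normal", 0.0, 0.4),
    "surface_sigma_2": ("uniform", 0.7, 1.3),
    "surface_scale_0": ("uniform", 0.5, 1.5),
    "surface_scale_1": ("uniform", 0.5, 1.5),
    "surface_scale_2": ("uniform", 0.5, 1.5),
    "size_scale": ("uniform", 0.5, 2.0),
    "rotation_angle_1": ("uniform", 0.0, 2 * np.pi),
    "rotation_angle_2": ("uniform", 0.0, 2 * np.pi),
}


def _validate_hyper(hyper: dict) -> None:
    for name in PARAM_NAMES:
        if name not in hyper:
            raise ValueError(f"hyper missing distribution for {name!r}")
        kind, a, b = hyper[name]
        if kind == "uniform":
            if a > b:
                raise ValueError(f"{name}: uniform min > max ({a} > {b})")
        elif kind == "normal":
            if b <= 0:
                raise ValueError(f"{name}: normal sd must be > 0, got {b}")
        else:
            raise ValueError(f"{name}: unknown distribution kind {kind!r}")
    for name in ("surface_sigma_0", "surface_sigma_1", "surface_sigma_2",
                 "surface_scale_0", "surface_scale_1", "surface_scale_2",
                 "size_scale"):
        kind, a, b = hyper[name]
        lo = a if kind == "uniform" else a - 6 * b
        if lo <= 0 and kind == "uniform":
            if name.startswith(("surface_sigma", "surface_scale")) or name == "size_scale":
                if a <= 0:
                    raise ValueError(f"{name}: lower bound must be > 0")


def sample_generator_params(rng, hyper: Optional[dict] = None) -> GeneratorParams:
    """Draw one 17-parameter set from the configured hyper-distributions."""
    rng = np.random.default_rng(rng)
    hyper = dict(DEFAULT_HYPER if hyper is None else hyper)
    _validate_hyper(hyper)
    vals = []
    for name in PARAM_NAMES:
        kind, a, b = hyper[name]
        if kind == "uniform":
            vals.append(rng.uniform(a, b))
        else:
            vals.append(rng.normal(a, b))
    return GeneratorParams.from_array(np.array(vals))


# ---------------------------------------------------------------------------
# Cloud generation
# ---------------------------------------------------------------------------

def _rotation_matrix(angles: Sequence[float]) -> np.ndarray:
    """Extrinsic rotation acting on (z, y, x) vectors: about z then about y."""
    a, b = angles
    ca, sa, cb, sb = math.cos(a), math.sin(a), math.cos(b), math.sin(b)
    # About the z axis: rotates the (y, x) plane.
    rz = np.array([[1, 0, 0],
                   [0, ca, -sa],
                   [0, sa, ca]])
    # About the y axis: rotates the (z, x) plane.
    ry = np.array([[cb, 0, -sb],
                   [0, 1, 0],
                   [sb, 0, cb]])
    return ry @ rz


def surface_radius(t, theta, params: GeneratorParams) -> np.ndarray:
    """Spine-to-surface distance at normalized height t and angle theta.

    Linear interpolation (periodic in angle) between the three logit-normal
    surface curves defined at 0°, 120° and 240°.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    theta = np.mod(np.atleast_1d(np.asarray(theta, dtype=float)), 2 * np.pi)
    d = np.stack([
        scale * logitnormal(t, mu, sigma)
        for (mu, sigma), scale in zip(params.surface_logitnormal_params,
                                      params.surface_scales)
    ])  # (3, n)
    step = 2 * np.pi / 3
    lo = np.floor(theta / step).astype(int) % 3
    hi = (lo + 1) % 3
    w = (theta - lo * step) / step
    idx = np.arange(t.size)
    return (1 - w) * d[lo, idx] + w * d[hi, idx]


def spine_position(t, params: GeneratorParams) -> np.ndarray:
    """Spine coordinates (z, y, x) at normalized height t in [0, 1]."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    dy = params.spine_offset_distance * math.sin(params.spine_offset_angle)
    dx = params.spine_offset_distance * math.cos(params.spine_offset_angle)
    cy, cx = params.spine_curve_coeffs
    bend = t * (1 - t)  # second-degree polynomial, end points pinned
    z = t * params.spine_height
    y = t * dy + cy * bend
    x = t * dx + cx * bend
    return np.column_stack([z, y, x])


def generate_cell_cloud(params: GeneratorParams, rng) -> SyntheticCell:
    """Sample one 2000-point synthetic cell cloud.

    The underlying random draws (heights and angles) depend only on the seed,
    so re-generating with modified size/rotation parameters but the same seed
    yields a point-matched cloud.
    """
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
    else:
        seed = int(np.random.default_rng(rng).integers(2**31))
    gen = np.random.default_rng(seed)
    t = gen.uniform(0.0, 1.0, N_POINTS)
    theta = gen.uniform(0.0, 2 * np.pi, N_POINTS)

    r = surface_radius(t, theta, params)
    spine = spine_position(t, params)
    pts = spine.copy()
    pts[:, 2] += r * np.cos(theta)
    pts[:, 1] += r * np.sin(theta)

    pts -= pts.mean(axis=0)
    pts *= params.size_scale
    pts = pts @ _rotation_matrix(params.rotation_angles).T

    cloud = PointCloud(pts, frame="raw")
    return SyntheticCell(cloud=cloud, params=params, seed=seed)


def generate_dataset(n: int, rng, hyper: Optional[dict] = None
                     ) -> tuple[list[SyntheticCell], pd.DataFrame]:
    """Generate ``n`` synthetic cells and the table of their 17 parameters."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    cells = []
    rows = np.empty((n, 17))
    for i in range(n):
        params = sample_generator_params(rng, hyper)
        seed = int(rng.integers(2**31))
        cell = generate_cell_cloud(params, seed)
        cell.cloud.cell_id = str(i)
        cells.append(cell)
        rows[i] = params.to_array()
    table = pd.DataFrame(rows, columns=PARAM_NAMES)
    return cells, table


# ---------------------------------------------------------------------------
# Tissue fixture: membrane-labeled volume with ground truth
# ---------------------------------------------------------------------------

def suggest_tissue_shape(n_cells: int, per_cell_voxels: int = 27_000
                         ) -> tuple[int, int, int]:
    """Cubic volume shape giving each cell a realistic size relative to the
    segmentation pipeline's fixed smoothing scale (the central ellipsoid
    occupies ~31% of the cube)."""
    edge = int(round((per_cell_voxels * n_cells / 0.31) ** (1 / 3)))
    return (edge, edge, edge)


def generate_membrane_volume(n_cells: int,
                             shape: tuple[int, int, int] = (64, 64, 64),
                             spacing: tuple[float, float, float] = (0.225, 0.099, 0.099),
                             rng=None,
                             noise_sd: float = 0.0,
                             membrane_intensity: float = 60.0,
                             interior_intensity: float = 0.0,
                             secondary: Optional[Callable[[np.ndarray], np.ndarray]] = None,
                             max_tries: int = 2000) -> SyntheticTissue:
    """Build a membrane-labeled tissue volume with ground-truth labels.

    Cells are Voronoi regions of randomly placed, minimum-separated seed
    points inside a central ellipsoid; membrane shells (~2 voxels thick) are
    drawn on inter-cell and tissue-outer boundaries. ``secondary``, if given,
    maps seed-point coordinates (n_cells, 3; voxel units) to one intensity
    level per cell for a second channel.
    """
    rng = np.random.default_rng(rng)
    shape = tuple(int(s) for s in shape)
    center = np.array(shape, dtype=float) / 2
    semi = np.array(shape, dtype=float) * 0.42

    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).astype(float)
    inside = (((coords - center) / semi) ** 2).sum(axis=-1) <= 1.0

    tissue_vol = inside.sum()
    # Minimum seed separation from the per-cell volume share; relaxed
    # gradually if dart throwing stalls, with a hard floor.
    min_sep = 0.85 * (tissue_vol / max(n_cells, 1)) ** (1 / 3)
    seeds = []
    tries = 0
    while len(seeds) < n_cells:
        tries += 1
        if tries > max_tries:
            if min_sep > 4.0:
                min_sep *= 0.95
                tries = 0
                continue
            raise ValueError(
                f"could not place {n_cells} seeds with separation {min_sep:.1f} "
                f"in shape {shape}; enlarge the volume or reduce n_cells")
        cand = center + (rng.uniform(-1, 1, 3)) * semi * 0.85
        if ((((cand - center) / semi) ** 2).sum() > 0.85**2):
            continue
        if seeds and np.min(np.linalg.norm(np.array(seeds) - cand, axis=1)) < min_sep:
            continue
        seeds.append(cand)
    seeds = np.array(seeds)

    flat = coords[inside]
    nearest = np.argmin(cdist(flat, seeds), axis=1) + 1
    labels = np.zeros(shape, dtype=np.int32)
    labels[inside] = nearest

    # Membrane: voxels with a 6-neighbor of different label (incl. background).
    boundary = np.zeros(shape, dtype=bool)
    for ax in range(3):
        diff = np.diff(labels, axis=ax) != 0
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        boundary[tuple(sl_lo)] |= diff
        boundary[tuple(sl_hi)] |= diff
    # Thicken to a ~2-voxel shell so smoothing cannot open the walls.
    from scipy import ndimage as ndi

    boundary = ndi.binary_dilation(
        boundary, structure=ndi.generate_binary_structure(3, 1))
    boundary &= inside

    img = np.zeros(shape, dtype=float)
    img[inside] = interior_intensity
    img[boundary] = membrane_intensity
    if noise_sd > 0:
        img += rng.normal(0, noise_sd, shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    sec_vol = None
    if secondary is not None:
        levels = np.asarray(secondary(seeds), dtype=float)
        if levels.shape != (n_cells,):
            raise ValueError("secondary must return one level per cell")
        sec = np.zeros(shape, dtype=float)
        sec[inside] = levels[nearest - 1]
        sec[boundary] = 0.0
        if noise_sd > 0:
            sec += rng.normal(0, noise_sd, shape)
        sec_vol = IntensityVolume(np.clip(sec, 0, 255).astype(np.uint8),
                                  spacing, channel_name="secondary")

    return SyntheticTissue(
        image=IntensityVolume(img, spacing, channel_name="membrane"),
        truth=LabelVolume(labels, spacing),
        secondary=sec_vol,
        seed_points=seeds,
    )


# ---------------------------------------------------------------------------
# Paired-channel fixture for regression benchmarks
# ---------------------------------------------------------------------------

def generate_paired_channels(reference: FeatureMatrix,
                             link: Callable[[np.ndarray], np.ndarray],
                             noise_sd: float = 0.0,
                             rng=None) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Build a (reference, target) feature-matrix pair with target = link(ref) + noise."""
    rng = np.random.default_rng(rng)
    target_vals = np.asarray(link(reference.values), dtype=float)
    if target_vals.ndim == 1:
        target_vals = target_vals[:, None]
    if target_vals.shape[0] != reference.n_samples:
        raise ValueError("link must return one row per reference row")
    if noise_sd > 0:
        target_vals = target_vals + rng.normal(0, noise_sd, target_vals.shape)
    target = FeatureMatrix(
        target_vals,
        feature_names=[f"t{i}" for i in range(target_vals.shape[1])],
        row_ids=reference.row_ids,
        frame=reference.frame,
        provenance="synthetic-paired-target",
    )
    return reference, target
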