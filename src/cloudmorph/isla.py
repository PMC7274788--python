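"""Intensity-biased Stochastic Landmark Assignment (ISLA).

Converts a voxel image into a representative point cloud: voxel intensities
are normalized to sum to one and interpreted as the probabilities of a
multinomial distribution from which landmarks are drawn with replacement.
Landmark coordinates are scaled from voxel indices to micrometres, which also
absorbs anisotropic resolution. To capture cell *shape* rather than an
intensity distribution, the 6-connected inner hull of the binary segmentation
mask is used as the input image.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .core import IntensityVolume, PointCloud

DEFAULT_N_POINTS = 2000


def subtract_cell_background(volume: IntensityVolume, mask) -> IntensityVolume:
    """Mask a cell and remove its mean internal intensity.

    Voxels outside the mask are set to zero; inside, the mean intensity over
    the mask is subtracted voxel-wise and negatives are clamped to zero.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape must match volume shape")
    if not mask.any():
        raise ValueError("mask is empty")
    vox = np.asarray(volume.voxels, dtype=float)
    background = vox[mask].mean()
    out = np.where(mask, np.clip(vox - background, 0, None), 0.0)
    return IntensityVolume(out, volume.spacing, volume.channel_name)


def sample_landmarks(volume: IntensityVolume, n_points: int = DEFAULT_N_POINTS,
                     rng=None, cell_id: Optional[str] = None,
                     sample_id: Optional[str] = None) -> PointCloud:
    """Draw landmarks from the multinomial defined by normalized intensities.

    Returns an (n_points, 3) cloud of (z, y, x) positions in µm (voxel
    centers scaled by the per-axis spacing), frame tag ``"raw"``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(rng)
    vox = np.asarray(volume.voxels, dtype=float)
    if vox.min() < 0:
        raise ValueError("intensities must be non-negative for sampling")
    total = vox.sum()
    if total <= 0:
        raise ValueError("nothing to sample: volume has no positive intensity")
    flat = vox.ravel() / total
    counts = rng.multinomial(n_points, flat)
    idx = np.repeat(np.nonzero(counts)[0], counts[counts > 0])
    zyx = np.column_stack(np.unravel_index(idx, vox.shape)).astype(float)
    pts = zyx * np.asarray(volume.spacing)
    return PointCloud(pts, frame="raw", cell_id=cell_id, sample_id=sample_id)


def boundary_inner_hull(mask) -> np.ndarray:
    """6-connected inner hull of a binary mask.

    A mask voxel belongs to the hull if at least one of its six face
    neighbors is outside the mask (voxels on the volume edge count their
    out-of-bounds neighbors as outside).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("mask is empty")
    structure = ndi.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndi.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded
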