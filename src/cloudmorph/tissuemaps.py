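"""Tissue-level summaries: consensus maps, correlation bigraphs, expanded views.

A *consensus map* pools tissue-frame cell centroids from many samples and
shows the local average of any per-cell value (a shape PC, a predicted marker
level, a spot count) across the tissue: a Gaussian kernel density estimate of
the pooled centroids defines the consensus tissue outline (densities below
10% of the density range are outside), and values are smoothed with a
point-cloud Gaussian whose sigma is the 0.5th percentile of all pairwise
centroid distances.

A *correlation bigraph* is a bipartite graph linking engineered features to
embedded PCs with edges weighted by Pearson correlation; edges with |r| below
0.3 are omitted, and engineered-feature nodes are ordered by stochastic
minimization of the sum of rank distances weighted by |r| to reduce edge
crossings.

The *expanded view* ("tissue ripper") shifts segmented cells apart by scaling
their centroids in x and y without rescaling the cells themselves, so each
cell's 3D shape can be inspected in place.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import gaussian_kde

from .core import LabelVolume

DEFAULT_EDGE_THRESHOLD = 0.3
DEFAULT_PATIENCE = 2000
DEFAULT_GRID = (256, 128)


@dataclass
class ConsensusMap:
    values: np.ndarray            # (ny, nx) smoothed values, NaN outside mask
    mask: np.ndarray              # validity mask from the centroid density cut
    grid_axes: tuple[np.ndarray, np.ndarray]
    centroids: np.ndarray
    sigma: float


@dataclass
class Bigraph:
    graph: "nx.Graph"
    engineered_order: list
    embedded_names: list
    sort_loss: float
    threshold: float


# ---------------------------------------------------------------------------
# Consensus maps
# ---------------------------------------------------------------------------

def consensus_map(centroids, values,
                  grid_shape: tuple[int, int] = DEFAULT_GRID,
                  density_cut: float = 0.10,
                  sigma_percentile: float = 0.5,
                  axes: tuple[int, int] = (0, 1)) -> ConsensusMap:
    """Local average of a per-cell value over pooled tissue-frame centroids.

    ``centroids`` is (n, 2) or (n, 3); maps are 2D projections over the two
    ``axes`` (default: front-rear x dorso-ventral). The validity mask keeps
    grid points whose centroid KDE density is at least
    ``min + density_cut * (max - min)``; values are smoothed with a Gaussian
    kernel of sigma = the ``sigma_percentile``-th percentile of all pairwise
    centroid distances.
    """
    cent = np.asarray(centroids, dtype=float)
    vals = np.asarray(values, dtype=float)
    if cent.ndim != 2:
        raise ValueError("centroids must be 2D (n, dims)")
    if cent.shape[0] != vals.shape[0]:
        raise ValueError("centroids and values must match")
    if cent.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    xy = cent[:, list(axes)]
    if np.allclose(xy, xy[0]):
        raise ValueError("all centroids identical: no spatial extent")

    dists = pdist(xy)
    sigma = float(np.percentile(dists, sigma_percentile))
    if sigma <= 0:
        sigma = float(dists[dists > 0].min())

    kde = gaussian_kde(xy.T)
    g0 = np.linspace(xy[:, 0].min(), xy[:, 0].max(), grid_shape[0])
    g1 = np.linspace(xy[:, 1].min(), xy[:, 1].max(), grid_shape[1])
    gg0, gg1 = np.meshgrid(g0, g1, indexing="ij")
    grid_pts = np.stack([gg0.ravel(), gg1.ravel()])
    density = kde(grid_pts).reshape(grid_shape)
    cut = density.min() + density_cut * (density.max() - density.min())
    mask = density >= cut

    # Nadaraya-Watson smoothing of the cell values over the grid.
    d2 = ((grid_pts.T[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2 * sigma**2))
    wsum = w.sum(axis=1)
    smoothed = np.full(grid_pts.shape[1], np.nan)
    ok = wsum > 0
    smoothed[ok] = (w[ok] @ vals) / wsum[ok]
    smoothed = smoothed.reshape(grid_shape)
    smoothed[~mask] = np.nan
    return ConsensusMap(values=smoothed, mask=mask, grid_axes=(g0, g1),
                        centroids=xy, sigma=sigma)


# ---------------------------------------------------------------------------
# Correlation bigraphs
# ---------------------------------------------------------------------------

def _pearson_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlations; NaN for zero-variance columns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    sa = a.std(axis=0)
    sb = b.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (ac.T @ bc) / (a.shape[0] * np.outer(sa, sb))
    corr[sa == 0, :] = np.nan
    corr[:, sb == 0] = np.nan
    return corr


def sort_bigraph_loss(order: Sequence[int], abs_corr: np.ndarray) -> float:
    """Rank-distance loss of an engineered-feature ordering.

    loss = sum_ij |order_i/fE - j/fE| * |r_ij| — the sum of rank distances
    between engineered and latent features, weighted by their absolute
    Pearson correlations (rank positions normalized by the engineered count).
    """
    fe = abs_corr.shape[0]
    order = np.asarray(order)
    ranks_e = order / fe
    ranks_l = np.arange(abs_corr.shape[1]) / fe
    return float(np.sum(np.abs(ranks_e[:, None] - ranks_l[None, :]) * abs_corr))


def _transposition_descent(order: np.ndarray, abs_corr: np.ndarray
                           ) -> tuple[np.ndarray, float]:
    """Polish an ordering: apply improving pair swaps until none remains."""
    fe = order.size
    best = sort_bigraph_loss(order, abs_corr)
    improved = True
    while improved:
        improved = False
        for i in range(fe - 1):
            for j in range(i + 1, fe):
                cand = order.copy()
                cand[[i, j]] = cand[[j, i]]
                loss = sort_bigraph_loss(cand, abs_corr)
                if loss < best - 1e-15:
                    order, best = cand, loss
                    improved = True
    return order, best


def sort_bigraph_nodes(abs_corr: np.ndarray, rng=None,
                       patience: int = DEFAULT_PATIENCE
                       ) -> tuple[np.ndarray, float]:
    """Order engineered-feature nodes by stochastic loss minimization.

    Iterated local search: the identity ordering is polished by improving
    pair swaps, then uniformly random reshuffles are proposed, kept only when
    they reduce the loss (each kept shuffle is polished again), and the
    search stops after ``patience`` consecutive non-improving shuffles.
    Returns (permutation, final loss): permutation[i] is the display rank of
    engineered feature i.
    """
    abs_corr = np.nan_to_num(np.abs(np.asarray(abs_corr, dtype=float)))
    fe = abs_corr.shape[0]
    rng = np.random.default_rng(rng)
    order = np.arange(fe)
    if fe < 2:
        return order, sort_bigraph_loss(order, abs_corr)
    order, best_loss = _transposition_descent(order, abs_corr)
    stale = 0
    while stale < patience:
        cand = rng.permutation(fe)
        loss = sort_bigraph_loss(cand, abs_corr)
        if loss < best_loss:
            order, best_loss = _transposition_descent(cand, abs_corr)
            stale = 0
        else:
            stale += 1
    return order, best_loss


def correlation_bigraph(engineered, embedded,
                        threshold: float = DEFAULT_EDGE_THRESHOLD,
                        rng=None, patience: int = DEFAULT_PATIENCE) -> Bigraph:
    """Bipartite correlation graph between engineered and embedded features.

    ``engineered`` and ``embedded`` are DataFrames or (array, names) pairs
    with matched rows. Edges carry the signed Pearson r; edges with
    |r| < threshold are omitted; zero-variance features are skipped with a
    warning. Engineered nodes carry the optimized display rank.
    """
    e_vals, e_names = _table(engineered, "E")
    l_vals, l_names = _table(embedded, "L")
    if e_vals.shape[0] != l_vals.shape[0]:
        raise ValueError("engineered and embedded tables must have matched rows")
    corr = _pearson_matrix(e_vals, l_vals)
    if np.isnan(corr).any():
        warnings.warn("zero-variance feature(s): their edges are omitted")

    order, loss = sort_bigraph_nodes(np.abs(corr), rng=rng, patience=patience)

    g = nx.Graph()
    for i, name in enumerate(e_names):
        g.add_node(("engineered", name), rank=int(order[i]))
    for j, name in enumerate(l_names):
        g.add_node(("embedded", name), rank=j)
    for i, en in enumerate(e_names):
        for j, ln in enumerate(l_names):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                g.add_edge(("engineered", en), ("embedded", ln),
                           weight=float(r))
    ordered = [e_names[i] for i in np.argsort(order)]
    return Bigraph(graph=g, engineered_order=ordered, embedded_names=list(l_names),
                   sort_loss=loss, threshold=threshold)


def _table(obj, prefix: str) -> tuple[np.ndarray, list]:
    if hasattr(obj, "values") and hasattr(obj, "columns"):
        return np.asarray(obj.values, dtype=float), list(obj.columns)
    if hasattr(obj, "values") and hasattr(obj, "feature_names"):
        return np.asarray(obj.values, dtype=float), list(obj.feature_names)
    arr = np.asarray(obj, dtype=float)
    return arr, [f"{prefix}{i}" for i in range(arr.shape[1])]


# ---------------------------------------------------------------------------
# Expanded view
# ---------------------------------------------------------------------------

def expand_tissue(labels: LabelVolume, factor: float) -> LabelVolume:
    """Shift cells apart by scaling their centroids in x and y.

    Every cell's voxels are pasted unchanged at the new centroid location in
    an enlarged canvas — cells move apart but are not individually rescaled.
    Raises if two cells would overlap after the shift.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    vox = labels.voxels
    ids = labels.labels()
    if ids.size < 1:
        raise ValueError("need at least one cell")
    shape = np.array(vox.shape)
    new_shape = shape.copy()
    new_shape[1] = int(math.ceil(shape[1] * factor)) + 2
    new_shape[2] = int(math.ceil(shape[2] * factor)) + 2
    out = np.zeros(tuple(new_shape), dtype=vox.dtype)
    for lab in ids:
        where = np.nonzero(vox == lab)
        coords = np.stack(where, axis=1).astype(float)
        centroid = coords.mean(axis=0)
        new_centroid = centroid.copy()
        new_centroid[1] *= factor
        new_centroid[2] *= factor
        shift = np.round(new_centroid - centroid).astype(int)
        zz = where[0] + shift[0]
        yy = where[1] + shift[1]
        xx = where[2] + shift[2]
        zz = np.clip(zz, 0, new_shape[0] - 1)
        yy = np.clip(yy, 0, new_shape[1] - 1)
        xx = np.clip(xx, 0, new_shape[2] - 1)
        if np.any(out[zz, yy, xx] != 0):
            raise ValueError(
                f"cells overlap after expansion at factor {factor}; "
                f"raise the factor")
        out[zz, yy, xx] = lab
    return LabelVolume(out, labels.spacing)
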