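# cloudmorph

Point-cloud morphometry of 3D membrane-labeled tissues: from fluorescence
stacks to single-cell segmentations, landmark clouds, frame-normalized shape
embeddings, cross-channel atlas predictions, archetype maps and tissue-level
summaries — with a synthetic cell generator as the built-in validation
engine.

## The problem and the approach

Developing tissues contain dozens to thousands of cells whose 3D shapes and
subcellular organization carry biological meaning, but which have no
homologous landmarks to measure between. `cloudmorph` implements a
landmark-free route:

1. **Unmixing & segmentation** — linear bleed-through removal
   (`M = U + a·C`, with `a` minimizing the correlation between the
   contaminant and the mean-centered absolute cleaned image) and an
   8-step watershed pipeline: median + Gaussian smoothing, automatic
   thresholding (the threshold maximizing the number of membrane-enclosed
   cell bodies), hole filling, labeling of the inverted membrane mask, size
   filtering, seeded watershed, background removal.
2. **ISLA** (Intensity-biased Stochastic Landmark Assignment) — an image is
   converted to a point cloud by drawing 2000 landmarks from the multinomial
   distribution with per-voxel probability proportional to intensity; cell
   shape uses the 6-connected inner hull of the segmentation mask.
3. **Frames of reference** — TFOR aligns whole tissues by principal axes
   (rigid; size and orientation keep their meaning); CFOR makes each cell
   size-, rotation- and handedness-invariant by scaling the cloud so
   centroid-to-landmark magnitudes sum to 1 and re-representing each
   landmark by the 10th/50th/90th percentiles of its pairwise distances.
4. **CBE** (Cluster-Based Embedding) — cells become comparable feature rows
   by describing each cell's landmark distribution around k = 20 consensus
   k-means reference centers (the vector from each center to the centroid
   of its 25 nearest landmarks; 3k features), followed by PCA. A 55-feature
   moments embedding (raw/centralized/standardized moments up to order 5)
   serves as the baseline.
5. **Data integration** — RBF-kernel support-vector regression predicts a
   secondary channel's embedding (or per-cell transcript spot counts) from
   shape features; a probabilistic RBF SVC maps manually annotated
   archetypes onto all cells, and a PCA of the class probabilities gives the
   archetype space.
6. **Tissue summaries** — consensus maps (KDE-masked Gaussian smoothing of
   per-cell values over pooled tissue-frame centroids), correlation
   bigraphs (|r| ≥ 0.3 edges between engineered and embedded features, with
   rank-distance-optimized node ordering), and an expanded "ripped" view of
   segmented cells.

A 17-parameter synthetic cell generator (spine + logit-normal surface
curves + size + rotation) provides ground truth for everything: exactly one
parameter changes only size and two change only rotation, so the CFOR
pipeline's invariances can be verified parameter by parameter, and recovery
of the 14 shape parameters from embeddings is the benchmark of embedding
quality.

## Worked example

```python
import numpy as np
from cloudmorph import segment, synthgen

tissue = synthgen.generate_membrane_volume(12, shape=(128, 128, 128), rng=0)
labels = segment.segment_cells(tissue.image)
report = segment.qc_summary(labels, min_plausible=1000)
print(report.n_cells, len(report.flagged))
```

prints `12 0` — all 12 ground-truth cells recovered, none size-flagged. The
example scripts under `examples/` walk through each capability; running
`python examples/02_segment_tissue.py` ends with

```
segmentation found n = 12 cells (N = 1 sample), 0 flagged
per-cell IoU vs ground truth: min 0.756, mean 0.835
```

meaning every segmented cell overlaps its true cell by at least 75% —
watershed boundaries sit on the membrane midlines. `01_synthetic_cells.py`
prints a CFOR deviation of `5.4e-19` after doubling a cell's size and
rotating it: the cell frame removes size and orientation to machine
precision, so downstream shape statistics cannot be confounded by either.

A thin CLI mirrors the library (`cloudmorph synth tissue`,
`cloudmorph segment run`, `cloudmorph isla`, `cloudmorph frames tfor/cfor`,
`cloudmorph embed fit-refs/features/moments/pca`, `cloudmorph maps
bigraph/rip`, `cloudmorph run` for the cached end-to-end stage graph).

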