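# Methods

`cloudmorph` turns 3D membrane-labeled image stacks into quantitative,
comparable descriptions of single-cell architecture. This note documents the
models and procedures it implements, the choices made where the design was
genuinely open, and what the synthetic validation machinery does and does not
establish.

## Pipeline overview

```
intensity stack ─ unmix ─ segment ─ ISLA ─┬─ TFOR ─┐
                                          │        ├─ CBE ─ PCA ─ atlas /
                                          └─ CFOR ─┘         archetypes / maps
```

## Bleed-through unmixing

A contaminant channel C (e.g. a bright nuclear label) leaking into a mixed
channel M is modeled linearly, `M = U + a·C`. The factor `a` minimizes
`PCC(C, |M − a·C − mean(M − a·C)|)`: once the true contribution is removed,
the cleaned image stops correlating with C, and over-subtraction creates
dark C-shaped holes that — after mean-centering and taking absolute
values — start correlating again. Minimization is a dense scan over
`a ∈ [0, 2]` (41 points) refined by bounded scalar minimization around the
best grid point; the loss is evaluated exactly as defined above, and the method's
accuracy is best when the contaminant is sparse and bright against the mixed
channel's typical intensity (the regime the loss was designed for). A
constant contaminant is degenerate (the loss is undefined); the function
returns `a = 0` with a warning.

## Single-cell segmentation

Eight fixed steps: 3×3×3 median filter; Gaussian filter (σ = 3 px);
automatic threshold; size-limited hole filling; connected-component labeling
of the inverted membrane mask; removal of components < 1,000 voxels and
re-labeling of components > 1,000,000 voxels as background seeds; seeded
watershed over a further Gaussian-smoothed (σ = 3 px) topography with
background seeds expanding too; background zeroed and only the largest
connected foreground object kept. All filtering happens in pixel space;
physical spacing enters when landmark clouds are extracted.

Choices the procedure leaves open:

* **Threshold criterion.** The threshold is the histogram mode plus the
  offset (default scan 0–10 step 1; a 0–40 step 2 scan is available for
  lower-contrast data) that maximizes the number of *enclosed cell bodies* —
  connected components of the inverted mask with at least `min_size` voxels.
  Counting raw components instead breaks on clean images: tie plateaus
  appear whose smallest offset encloses cells only as sub-artifact-size
  cores, which the size filter then deletes.
* **Hole filling** is size-limited (`hole_fill_size`, default 64 voxels):
  it removes small background pockets enclosed in membrane walls. Unbounded
  3D hole filling would also fill every cell interior and leave nothing to
  label.
* **Connectivity.** The inverted mask is labeled with 6-connectivity (thin
  membrane walls are 6-separating but not 26-separating); the final
  foreground-object test uses 26-connectivity. Both are configurable.
* The histogram mode is computed per discrete value for integer images and
  over 256 bins for float input (the pipeline's statistics assume 8-bit
  acquisitions).

## ISLA: landmark sampling

Voxel intensities, normalized to sum to one, are the probabilities of a
multinomial distribution from which 2000 landmarks are drawn with
replacement; coordinates are voxel centers scaled to µm by the per-axis
spacing, which absorbs anisotropy. Cell *shape* is sampled from the
6-connected inner hull of the segmentation mask (mask voxels with at least
one face neighbor outside); arbitrary fluorescence distributions are sampled
after masking and subtraction of the mean in-mask intensity (negatives
clamped). Landmarks sit at voxel centers; sub-voxel jitter is deliberately
not applied.

## Frames of reference

**TFOR** (tissue frame): 3000 landmarks are ISLA-sampled from the
whole-tissue mask and a principal-axis transform is fit. Axes are ordered by
variance — valid because the tissue's longest axis is its front–rear axis
and its shortest the apicobasal axis. To prevent 180° flips between
replicate acquisitions, each axis sign is chosen so the landmark skewness
along it is non-negative (ties broken by the largest-magnitude landmark);
the rule can be overridden with a user-supplied anatomical direction by
negating rows of the returned rotation. The transform translates the
frontal-most landmark to zero along the front–rear axis, with the lateral
axes centered on the landmark centroid — pinning all three coordinates to a
single extreme landmark would make the lateral origin fluctuate by several
µm between replicate samplings. TFOR is rigid: sizes, volumes and pairwise
distances are preserved exactly.

**CFOR** (cell frame): the cloud is centered on its centroid and scaled so
the magnitudes of all centroid-to-landmark vectors sum to 1, then each
landmark is re-represented by the 10th/50th/90th percentiles (linear
interpolation between order statistics) of its distances to all other
landmarks. The result is invariant — to machine precision — under any
composition of translation, rotation, reflection and uniform scaling of the
input, and the three columns are monotone by construction.

## Engineered features

Per cell: volume (voxel count × voxel volume), surface area (marching cubes
on a σ = 1 px smoothed mask, which suppresses the ≈9% staircase bias of
meshing a raw binary mask), sphericity `π^(1/3)·(6V)^(2/3)/A`, extents and
centroid along the TFOR axes, orientation (polar/azimuth angles of the
cell's major principal axis in TFOR), and a surface-smoothness proxy (cell
surface area over landmark convex-hull area; 1 = smooth). There is no single
canonical list of engineered features; this set covers the measures the
interpretation steps downstream rely on, and adding further columns is a
local change.

## Cluster-Based Embedding (CBE)

Reference centers: per-cell clouds are centered, condensed from 2000 to 500
landmarks by k-means, overlaid across a random subset of 10–25 samples,
density-downsampled to at most 200,000 points and clustered with k-means
(k = 20, mini-batch). Density-dependent downsampling computes each point's
local density LD (neighbors within a sphere of radius = median pairwise
distance × 5), the target density TD (3rd percentile of all LD), and keeps
each point with probability 1 if LD < TD, else TD/LD; an exact shortcut
recognizes the case where the radius covers the whole cloud. For clouds
above 20,000 points the median pairwise distance is estimated from 10⁶
random pairs.

Per-cell features: for each reference center, the vector from the center to
the centroid of its 25 nearest cloud landmarks (3k = 60 features at k = 20),
or that vector's magnitude (k features). The neighbor count trades
locality against noise; 25 is the default and the count is exposed
(`n_neighbors`). Features are standardized and PCA-reduced; PC
signs can be anchored to correlate positively with their most defining
engineered feature. For the CFOR route, CBE operates on the pairwise-
distance representation treated as a 3D point set.

**Moments baseline**: 55 features — the 3 first raw moments, 6 second
centralized moments, and all 10 + 15 + 21 third-to-fifth standardized
moments over axis-exponent triples (i, j, k) with i + j + k = m, the
standardization dividing by `std_z^i · std_y^j · std_x^k`.

## Synthetic cell generator

17 parameters: spine height (1), endpoint offset distance and angle (2), one
quadratic bend coefficient per lateral axis with pinned endpoints (2), three
logit-normal surface curves (µ, σ each; 6) with one multiplicative scale
each (3), a size scale (1) and two rotation angles (2). The logit-normal is
evaluated as its density on (0, 1) — zero at both endpoints, positive
inside; its normalization constant is absorbed by the surface scales. The
three surface curves sit at 0°/120°/240° around the spine, with radii
linearly interpolated in angle (periodic). 2000 surface points are sampled
with uniform height and angle; the cloud is centered, scaled and rotated by
extrinsic z-then-y rotations. Because the stochastic draws depend only on
the seed, parameter perturbations yield point-matched clouds — which is how
the tests verify that exactly 1 parameter affects only size and exactly 2
only rotation (CFOR-invariance under those three, non-invariance under the
other 14).

Hyper-distributions for population sampling are this package's own
choices: heights/offsets/σ/scales uniform over moderate ranges, curve
coefficients and logit-normal µ normal around zero, angles uniform on the
circle — chosen to give a varied population without self-intersecting
shapes, and documented in `synthgen.DEFAULT_HYPER` rather than hard-coded.

## Synthetic tissue fixture

The membrane-volume generator (validation plumbing, not part of the analysis pipeline)
builds Voronoi cells of dart-thrown seed points inside an ellipsoid,
~2-voxel membrane shells on all inter-cell and outer boundaries (intensity
60 on the 8-bit scale over dark interiors), optional Gaussian noise and an
optional per-cell secondary channel. Fixture volumes scale with cell count
(`suggest_tissue_shape`, ≈27,000 voxels per cell) so that cell diameter
versus the pipeline's fixed σ = 3 px smoothing matches the imaging regime
of real data while staying desk-sized; full-scale cells at the reference
voxel spacing (0.225 × 0.099 × 0.099 µm) would be ~450k voxels each, which
is not practical for 30-cell test volumes. What passing these fixtures
shows: the pipeline's steps interlock correctly and recover ground truth
under clean conditions. What it does not show: robustness to deconvolution
artifacts, anisotropic PSFs, intensity inhomogeneity or touching-membrane
ambiguities of real microscopy.

## Atlas regression

Secondary-channel embeddings are predicted from shape embeddings (both
standardized, PCA-truncated to 20 components) by RBF-kernel support-vector
regression — realized as one independent single-output SVR per target
dimension — with k-nearest-neighbor, random-forest, elastic-net, lasso and
multi-layer-perceptron alternatives for model comparison. Hyperparameters
come from cross-validated grid search on log grids spanning five orders of
magnitude around the library defaults; evaluation uses shuffled
train/test splits (3 by default) with explained variance averaged uniformly
over target dimensions (the variance-weighted average is a one-line change;
uniform is the default and is what the reports contain). Training-set
curation keeps cells with secondary intensity strictly above its 33rd
percentile, then removes exactly `floor(0.05·n)` cells with the lowest
isolation-forest scores — a deterministic count, where the underlying
library's `contamination` flags only approximately that fraction. Spot-count
regression uses 23 inputs (first 10 tissue-frame shape PCs, first 10
cell-frame shape PCs, 3 tissue-frame centroid coordinates) and 5-fold grid
search; samples with a mean per-cell count below 2 are excluded
(boundary inclusive).

## Archetypes

A probabilistic RBF-kernel support-vector classifier maps annotated cell
classes onto all cells. The grid search covers standardization on/off, PCA
off or keeping 15/30/50 components, and penalty/kernel-coefficient decades;
probabilities come from the classifier's pairwise-coupling calibration and
are renormalized to sum to exactly 1. The archetype space is a PCA of the
raw class probabilities (they share a scale, so no standardization — a
documented choice); C classes span at most C−1 informative dimensions.
Stratified splits (default 436/188 at 624 annotations) preserve class
proportions within one cell. Group comparisons: two-tailed Mann–Whitney U,
Bonferroni correction only when the caller declares a family size, p > 0.01
treated as not significant, Cohen's d (pooled SD) as effect size.

## Tissue-level outputs

Consensus maps pool tissue-frame centroids from all samples (cells weighted
equally, matching the overlay description; per-sample averaging first is the
documented alternative), mask out regions whose Gaussian-KDE centroid
density falls below minimum + 10% of the density range, and smooth per-cell
values with a Nadaraya–Watson Gaussian kernel whose σ is the 0.5th
percentile of pairwise centroid distances, evaluated on a 256×128 grid over
the first two TFOR axes. Correlation bigraphs link engineered features to
embedded PCs when |Pearson r| ≥ 0.3, keeping the signed value; engineered
nodes are ordered by minimizing the sum of rank distances weighted by |r|
(both rank terms normalized by the engineered-feature count). The minimizer is an iterated local search: uniformly
random reshuffles accepted only on improvement, each polished by improving
pair swaps, stopping after 2000 consecutive non-improving shuffles — plain
accept-if-better shuffling alone misses the exhaustive optimum a few
percent of the time even at six features. The expanded view shifts cell
centroids apart by a single x/y factor and pastes each cell's voxels
unchanged, erroring if a factor near 1 would make cells collide.

## Validation benchmark

`evaluation.parameter_recovery_experiment` synthesizes 2000 cells (a
population size that keeps the experiment in minutes on one core),
embeds them along the CFOR route and along a non-normalized route (CBE on
centered raw clouds), PCA-reduces each embedding to 20 components, and
scores k-nearest-neighbor regression of the 17 generative parameters on a
held-out quarter. The kNN neighbor count is chosen by 3-fold grid search on
the training part: a fixed small k biases held-out R² toward −1/k on every
parameter the features carry no information about, which would mask the
informative parameters in a 17-parameter average.

Two structural caveats. First, angular parameters (the spine offset angle,
the assignment of surface curves to 0°/120°/240°) are only defined up to
the cell's free rotation, so no rotation-invariant representation can
recover them individually; the shape-parameter average is carried by the
identifiable parameters (heights, curve widths, scales). Second,
orientation recovery from the non-normalized route is data-hungry: with
rotations free over the full circle and 14 shape parameters varying
simultaneously, feature-space neighbors rarely match in orientation at
2000 cells, so rotation R² from the raw route is positive but small at
this population size (size recovers strongly, ≈0.8), and grows with the
number of cells. The cell-frame contrast the benchmark is designed to show
— rotation information absent after CFOR, present before — is visible in
the sign and ordering of the scores at 2000 cells; substantially higher
rotation R² requires populations an order of magnitude larger.

## Numerical notes

* Pairwise-distance percentiles use the Gram-matrix identity for the
  distance matrix and rank-shifted percentiles to skip self-distances
  without copying; results are bit-identical to the naive oracle.
* k-means condensation uses a lean full-batch KMeans (single init, 10
  iterations) below 50,000 points and mini-batch above.
* Zero-variance feature columns are guarded (scale 1) before
  standardization; degenerate inputs (empty masks, all-identical points,
  single-class annotations) raise informative errors rather than warnings.
* All stochastic steps accept either a seed or a `numpy` Generator; every
  fitted object records the integer seed actually used.
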