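"""Archetype mapping, group statistics, and tissue-level summaries."""

import numpy as np
import pandas as pd

from cloudmorph.context import (archetype_space, compare_groups,
                                predict_archetypes,
                                train_archetype_classifier)
from cloudmorph.core import FeatureMatrix
from cloudmorph.tissuemaps import consensus_map, correlation_bigraph

rng = np.random.default_rng(0)

# three separable shape families standing in for annotated archetypes
centers = {"leader": (0, 0), "central": (6, 0), "peripheral": (0, 6)}
x, y = [], []
for name, c in centers.items():
    mu = np.zeros(6)
    mu[:2] = c
    x.append(rng.normal(mu, 0.7, size=(80, 6)))
    y += [name] * 80
features = FeatureMatrix(np.vstack(x),
                         feature_names=[f"PC{i+1}" for i in range(6)])
labels = np.array(y)

model = train_archetype_classifier(features, labels, rng=0,
                                   pca_options=(None,),
                                   c_grid=[1.0, 100.0],
                                   gamma_grid=["scale"])
pred, probs = predict_archetypes(model, features)
print(f"archetype classifier: cross-validated accuracy "
      f"{model.cv_accuracy:.3f}; probability rows sum to "
      f"{probs.sum(axis=1).mean():.6f}")

space = archetype_space(probs)
print(f"archetype space: {space.coordinates.shape[1]} PCs of the class "
      f"probabilities; variance ratios "
      f"{np.round(space.explained_variance_ratios, 3)}")

# group statistics on a per-cell value
vol_leader = rng.normal(300, 40, 93)
vol_central = rng.normal(260, 40, 182)
cmp = compare_groups(vol_leader, vol_central, n_tests=3)
print(f"leader vs central volumes: p = {cmp.p_value:.2e} "
      f"(Bonferroni x{cmp.n_tests}), Cohen's d = {cmp.cohens_d:.2f}, "
      f"significant: {cmp.significant}")

# consensus map of a value over pooled tissue-frame centroids
centroids = rng.uniform(0, 100, size=(500, 2))
values = centroids[:, 0] * 0.1 + rng.normal(0, 0.5, 500)
cmap = consensus_map(centroids, values)
inside = cmap.values[cmap.mask]
print(f"consensus map: grid {cmap.values.shape}, smoothing sigma "
      f"{cmap.sigma:.2f} µm, value range {inside.min():.2f}..{inside.max():.2f}")

# correlation bigraph between engineered features and embedded PCs
eng = pd.DataFrame({"volume": values, "noise": rng.normal(size=500)})
emb = pd.DataFrame({"PC1": values + rng.normal(0, 0.3, 500),
                    "PC2": rng.normal(size=500)})
bg = correlation_bigraph(eng, emb, rng=0)
print(f"bigraph: {bg.graph.number_of_edges()} edges with |r| >= "
      f"{bg.threshold}; engineered node order {bg.engineered_order}")
print("(the map shows where in the tissue a value is high; the bigraph "
      "shows which engineered features define which embedded PCs)")
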