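"""Archetype mapping and group statistics.

A small set of manually annotated, biologically meaningful cell classes
(e.g. leader, central rosette, peripheral rosette, inter-organ) is used to
train a probabilistic RBF-kernel support-vector classifier on embedded cell
shapes. Predicting class *probabilities* for every cell, then running a PCA
on the probability matrix, yields the "archetype space": each cell is placed
by its similarity to each archetype, with annotated prototypes at the simplex
corners and ambiguous cells in between.

Group comparisons follow the study's statistical conventions: two-tailed
Mann-Whitney U tests, Bonferroni correction when a test family is declared,
p > 0.01 treated as not significant, and Cohen's d reported as effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import FeatureMatrix

DEFAULT_PCA_OPTIONS = (None, 15, 30, 50)


@dataclass
class ArchetypeModel:
    pipeline: Pipeline
    class_names: tuple[str, ...]
    best_params: dict
    cv_accuracy: float
    seed: int

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class ArchetypeSpace:
    coordinates: np.ndarray          # cells x <= 3 PCs of class probabilities
    explained_variance_ratios: np.ndarray
    class_names: tuple[str, ...]


@dataclass
class GroupComparison:
    statistic: float
    p_value: float                   # Bonferroni-adjusted, capped at 1
    p_raw: float
    n_tests: int
    cohens_d: float
    significant: bool                # p_value <= 0.01


def _decades(default: float, n: int = 5) -> list[float]:
    return list(default * np.logspace(-(n / 2), n / 2, n + 1))


def build_archetype_grid(x: np.ndarray, pca_options=DEFAULT_PCA_OPTIONS,
                         c_grid=None, gamma_grid=None, seed: int = 0) -> dict:
    """Search space for the archetype classifier: standardization on/off,
    PCA off or keeping the first 15/30/50 components, and log grids over the
    penalty and kernel coefficient."""
    c_grid = list(c_grid) if c_grid is not None else _decades(1.0)
    gamma_grid = list(gamma_grid) if gamma_grid is not None else \
        ["scale"] + _decades(1.0 / x.shape[1])
    max_pca = min(x.shape[0], x.shape[1])
    pca_steps = [None] + [PCA(n_components=p, random_state=seed)
                          for p in pca_options
                          if p is not None and p <= max_pca]
    return {
        "scale": [None, StandardScaler()],
        "pca": pca_steps,
        "svc__C": c_grid,
        "svc__gamma": gamma_grid,
    }


def train_archetype_classifier(features: FeatureMatrix,
                               labels: Sequence[str],
                               rng=None,
                               pca_options: Sequence = DEFAULT_PCA_OPTIONS,
                               c_grid: Optional[Sequence[float]] = None,
                               gamma_grid: Optional[Sequence] = None,
                               cv: int = 5) -> ArchetypeModel:
    """Grid-search a probabilistic RBF SVC over preprocessing and kernel grids.

    The search covers: standardization on/off, PCA off or keeping the first
    15/30/50 components, and log grids over the penalty C and kernel
    coefficient gamma. The best configuration is refit on all annotated cells
    with probability calibration enabled.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 annotated cells")
    x = features.values
    seed = int(np.random.default_rng(rng).integers(2**31))
    c_grid = list(c_grid) if c_grid is not None else _decades(1.0)
    gamma_grid = list(gamma_grid) if gamma_grid is not None else \
        ["scale"] + _decades(1.0 / x.shape[1])

    grid = build_archetype_grid(x, pca_options, c_grid, gamma_grid, seed)
    pipe = Pipeline([("scale", None), ("pca", None),
                     ("svc", SVC(kernel="rbf", probability=True,
                                 random_state=seed))])
    cv_eff = min(cv, int(counts.min()))
    search = GridSearchCV(pipe, grid, cv=cv_eff, scoring="accuracy")
    search.fit(x, labels)
    return ArchetypeModel(pipeline=search.best_estimator_,
                          class_names=tuple(search.best_estimator_
                                            .named_steps["svc"].classes_),
                          best_params=search.best_params_,
                          cv_accuracy=float(search.best_score_),
                          seed=seed)


def predict_archetypes(model: ArchetypeModel, features
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and calibrated class probabilities for all cells.

    Probability rows are renormalized to sum to exactly 1; the label is the
    argmax class.
    """
    x = features.values if isinstance(features, FeatureMatrix) else \
        np.asarray(features, dtype=float)
    probs = model.pipeline.predict_proba(x)
    probs = probs / probs.sum(axis=1, keepdims=True)
    labels = np.asarray(model.class_names)[np.argmax(probs, axis=1)]
    return labels, probs


def stratified_evaluation(features, labels: Sequence[str],
                          train_n: int = 436, test_n: int = 188,
                          rng=None, model_kwargs: Optional[dict] = None
                          ) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Held-out evaluation on a stratified train/test split.

    Splits the annotated cells with class proportions preserved, trains the
    archetype classifier on the training part and returns (confusion matrix
    with rows = true classes, accuracy, class names).
    """
    labels = np.asarray(labels)
    x = features.values if isinstance(features, FeatureMatrix) else \
        np.asarray(features, dtype=float)
    if train_n + test_n > labels.size:
        raise ValueError("train_n + test_n exceeds the annotated count")
    seed = int(np.random.default_rng(rng).integers(2**31))
    splitter = StratifiedShuffleSplit(n_splits=1, train_size=train_n,
                                      test_size=test_n, random_state=seed)
    (train_idx, test_idx), = splitter.split(x, labels)
    fm = FeatureMatrix(x[train_idx],
                       feature_names=[f"f{i}" for i in range(x.shape[1])])
    model = train_archetype_classifier(fm, labels[train_idx], rng=seed,
                                       **(model_kwargs or {}))
    pred, _ = predict_archetypes(model, x[test_idx])
    cm = confusion_matrix(labels[test_idx], pred, labels=list(model.class_names))
    acc = accuracy_score(labels[test_idx], pred)
    return cm, float(acc), model.class_names


def archetype_space(probabilities: np.ndarray, n_components: int = 3
                    ) -> ArchetypeSpace:
    """PCA of the class-probability matrix.

    Probabilities live on a (C-1)-simplex, so at most C-1 components carry
    variance; coordinates are reported for up to ``n_components`` PCs.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2:
        raise ValueError("probabilities must be 2D")
    if probs.shape[1] < 2:
        raise ValueError("need at least 2 classes for an archetype space")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    n_comp = min(n_components, probs.shape[1], probs.shape[0])
    pca = PCA(n_components=probs.shape[1] if probs.shape[0] >= probs.shape[1]
              else probs.shape[0], svd_solver="full")
    scores = pca.fit_transform(probs)
    return ArchetypeSpace(coordinates=scores[:, :n_comp],
                          explained_variance_ratios=pca.explained_variance_ratio_,
                          class_names=tuple(f"class{i}"
                                            for i in range(probs.shape[1])))


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def compare_groups(values_a, values_b, n_tests: int = 1) -> GroupComparison:
    """Two-tailed Mann-Whitney U with Bonferroni correction and Cohen's d.

    The raw p-value is multiplied by ``n_tests`` (capped at 1); p > 0.01 is
    treated as not statistically significant.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    stat, p_raw = stats.mannwhitneyu(a, b, alternative="two-sided")
    p_adj = min(p_raw * n_tests, 1.0)
    d = cohens_d(a, b)
    return GroupComparison(statistic=float(stat), p_value=float(p_adj),
                           p_raw=float(p_raw), n_tests=int(n_tests),
                           cohens_d=d, significant=bool(p_adj <= 0.01))
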