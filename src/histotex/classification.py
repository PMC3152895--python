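"""Unsupervised classification in the 3-feature space and error scoring.

Samples are standardized per feature and partitioned by 2-cluster
k-means; clusters are mapped to the C/F classes by the assignment that
minimizes total misclassification (equivalently, majority label overlap
with ties resolved toward lower total error).  Labels are used only for
scoring.  A leave-one-out 1-nearest-neighbour mode is available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

GROUPS = ("C", "F")


@dataclass
class ClassificationResult:
    """Per-group percentage error plus the confusion bookkeeping."""

    percent_errors: dict[str, float]  # group -> percent error
    confusion: dict[tuple[str, str], int]  # (true, predicted) -> count
    cluster_to_class: dict[int, str]
    classifier: str = "kmeans"
    seed: int = 0

    @property
    def total_misclassified(self) -> int:
        return sum(n for (true, pred), n in self.confusion.items() if true != pred)


def percent_error(misclassified: int, group_size: int) -> float:
    """100 x misclassified / group size."""
    if group_size <= 0:
        raise ValueError("group size must be positive")
    if not 0 <= misclassified <= group_size:
        raise ValueError("misclassified count outside [0, group size]")
    return 100.0 * misclassified / group_size


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def _score(labels: np.ndarray, predicted: np.ndarray, cluster_map, classifier, seed):
    confusion = {(t, p): 0 for t in GROUPS for p in GROUPS}
    for true, pred in zip(labels, predicted):
        confusion[(true, pred)] += 1
    errors = {}
    for group in GROUPS:
        size = int((labels == group).sum())
        if size == 0:
            continue
        wrong = sum(n for (t, p), n in confusion.items() if t == group and p != group)
        errors[group] = percent_error(wrong, size)
    return ClassificationResult(
        percent_errors=errors,
        confusion=confusion,
        cluster_to_class=cluster_map,
        classifier=classifier,
        seed=seed,
    )


def classify_unsupervised(
    features, labels, seed: int = 0, classifier: str = "kmeans"
) -> ClassificationResult:
    """Cluster samples in feature space and score against the labels.

    ``features`` is samples x 3 (DataFrame or array); ``labels`` holds
    "C"/"F" per sample and is used only to name clusters and compute the
    per-group percentage errors.
    """
    if isinstance(features, pd.DataFrame):
        x = features.to_numpy(dtype=np.float64)
    else:
        x = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"expected samples x 3 features, got shape {x.shape}")
    if len(labels) != x.shape[0]:
        raise ValueError("labels length must match sample count")
    present = set(labels)
    if not present <= set(GROUPS) or len(present) < 2:
        raise ValueError("need samples from both groups C and F")

    z = _standardize(x)
    if classifier == "kmeans":
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        assignments = km.fit_predict(z)
        best = None
        for mapping in ({0: "C", 1: "F"}, {0: "F", 1: "C"}):
            predicted = np.array([mapping[a] for a in assignments])
            total = int((predicted != labels).sum())
            if best is None or total < best[0]:
                best = (total, mapping, predicted)
        _, cluster_map, predicted = best
        return _score(labels, predicted, cluster_map, classifier, seed)
    if classifier == "1nn-loo":
        dist = cdist(z, z)
        np.fill_diagonal(dist, np.inf)
        predicted = labels[dist.argmin(axis=1)]
        return _score(labels, predicted, {}, classifier, seed)
    raise ValueError(f"unknown classifier {classifier!r}")
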