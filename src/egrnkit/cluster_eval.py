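"""Clustering stability selection and internal quality indices.

Community detection itself (Louvain/Leiden over a kNN graph) is an input: the
caller supplies label vectors obtained at a sweep of resolutions, and
``stability_select`` returns a representative of the most frequent partition
equivalence class (identical up to label renaming). ``dunn_index`` and
``silhouette_mean`` score a chosen partition geometrically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

__all__ = ["PartitionEnsemble", "stability_select", "dunn_index", "silhouette_mean"]


@dataclass
class PartitionEnsemble:
    """(resolution, label vector) pairs over one fixed set of nuclei."""

    resolutions: list
    labels: list  # list of pd.Series sharing one index

    def __post_init__(self):
        if len(self.resolutions) != len(self.labels):
            raise ValueError("one label vector per resolution required")
        self.labels = [pd.Series(l) for l in self.labels]
        base = self.labels[0].index
        for l in self.labels[1:]:
            if not base.equals(l.index) and set(base) != set(l.index):
                raise ValueError("all partitions must cover the same nuclei")
        self.labels = [l.loc[base] for l in self.labels]


def stability_select(ensemble: PartitionEnsemble, ari_tol: float = 0.0):
    """Pick the modal partition class across a resolution sweep.

    Partitions are grouped into equivalence classes by adjusted Rand index
    (ARI = 1 means identical up to label renaming; ``ari_tol`` relaxes this
    to ARI >= 1 - tol). The representative of the most frequent class is
    returned together with a frequency report; ties go to the class
    containing the lowest resolution.
    """
    if len(ensemble.labels) < 2:
        raise ValueError("need >= 2 partitions")
    classes: list[list[int]] = []
    for i, lab in enumerate(ensemble.labels):
        for cls in classes:
            rep = ensemble.labels[cls[0]]
            if adjusted_rand_score(rep.to_numpy(), lab.to_numpy()) >= 1.0 - ari_tol:
                cls.append(i)
                break
        else:
            classes.append([i])
    n = len(ensemble.labels)

    def class_key(cls):
        return (-len(cls), min(ensemble.resolutions[i] for i in cls))

    classes.sort(key=class_key)
    best = classes[0]
    report = pd.DataFrame(
        {
            "class_id": range(len(classes)),
            "size": [len(c) for c in classes],
            "frequency": [len(c) / n for c in classes],
            "resolutions": [sorted(ensemble.resolutions[i] for i in c) for c in classes],
        }
    )
    return ensemble.labels[best[0]].copy(), report


def _check_partition(points: np.ndarray, labels: np.ndarray):
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    return uniq


def dunn_index(points, labels) -> float:
    """min inter-cluster distance / max intra-cluster diameter.

    If every cluster is a singleton (max diameter 0) the index is +inf.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    labels = np.asarray(labels)
    uniq = _check_partition(points, labels)
    dm = squareform(pdist(points))
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    intra = dm[same & off]
    inter = dm[~same]
    max_diam = intra.max() if intra.size else 0.0
    if max_diam == 0.0:
        return float("inf")
    return float(inter.min() / max_diam)


def silhouette_mean(points, labels) -> float:
    """Mean silhouette coefficient; singleton clusters score 0 by convention."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    labels = np.asarray(labels)
    uniq = _check_partition(points, labels)
    dm = squareform(pdist(points))
    sizes = {c: int((labels == c).sum()) for c in uniq}
    s = np.zeros(len(labels))
    for i in range(len(labels)):
        own = labels[i]
        if sizes[own] == 1:
            continue  # s = 0
        a = dm[i, (labels == own)].sum() / (sizes[own] - 1)
        b = min(dm[i, labels == c].mean() for c in uniq if c != own)
        s[i] = (b - a) / max(a, b)
    return float(s.mean())
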