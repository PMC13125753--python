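"""Clustering of embeddings and trees, Rand-Index evaluation, baselines."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .distance import DistanceMatrix
from .model import Embedding
from .trees import PatientTreeSet, TreeDataset

__all__ = [
    "Clustering",
    "kmeans_cluster",
    "rand_index",
    "hierarchical_tree_clustering",
    "random_clustering_matched",
    "filter_outlier_trees",
]


@dataclass
class Clustering:
    assignment: Dict[str, int]
    K: int

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if labels and (min(labels) < 0 or max(labels) >= self.K):
            raise ValueError("labels must lie in [0, K)")

    def labels_for(self, items: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[i] for i in items], dtype=int)

    def sizes(self) -> List[int]:
        counts = [0] * self.K
        for lab in self.assignment.values():
            counts[lab] += 1
        return counts


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map labels to 0..K-1 in order of first appearance."""
    mapping: Dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def kmeans_cluster(
    embeddings: Sequence[Embedding], K: int, seed: int = 0
) -> Clustering:
    """Lloyd's algorithm (k-means++ init) on embedding vectors."""
    if K > len(embeddings):
        raise ValueError("K exceeds the number of embeddings")
    ids = [e.tree_id for e in embeddings]
    X = np.stack([e.vector for e in embeddings])
    km = KMeans(n_clusters=K, random_state=seed, n_init=10)
    labels = _relabel_contiguous(km.fit_predict(X))
    return Clustering(assignment=dict(zip(ids, labels.tolist())), K=K)


def rand_index(c1: Clustering, c2: Clustering) -> float:
    """Fraction of item pairs on which the two clusterings agree."""
    if set(c1.assignment) != set(c2.assignment):
        raise ValueError("clusterings cover different item sets")
    items = sorted(c1.assignment)
    n = len(items)
    if n < 2:
        raise ValueError("need at least two items")
    a = c1.labels_for(items)
    b = c2.labels_for(items)
    # contingency-based count of agreeing pairs
    cont = np.zeros((a.max() + 1, b.max() + 1), dtype=np.int64)
    np.add.at(cont, (a, b), 1)
    same_both = (cont * (cont - 1) // 2).sum()
    rows = cont.sum(axis=1)
    cols = cont.sum(axis=0)
    same_a = (rows * (rows - 1) // 2).sum()
    same_b = (cols * (cols - 1) // 2).sum()
    total = n * (n - 1) // 2
    diff_both = total - same_a - same_b + same_both
    return float((same_both + diff_both) / total)


def hierarchical_tree_clustering(
    dmatrix: DistanceMatrix, K: int, method: str = "average"
) -> Clustering:
    """Agglomerative clustering of the tree-distance matrix, cut at K."""
    n = len(dmatrix.labels)
    if K > n:
        raise ValueError("K exceeds the number of trees")
    if n == 1:
        return Clustering(assignment={dmatrix.labels[0]: 0}, K=1)
    condensed = squareform(dmatrix.values, checks=False)
    Z = linkage(condensed, method=method)
    flat = fcluster(Z, t=K, criterion="maxclust")
    labels = _relabel_contiguous(np.asarray(flat))
    return Clustering(
        assignment=dict(zip(dmatrix.labels, labels.tolist())), K=int(labels.max()) + 1
    )


def random_clustering_matched(
    sizes: Sequence[int], item_ids: Sequence[str], seed: int = 0
) -> Clustering:
    """Uniformly random assignment with a fixed cluster-size profile."""
    if sum(sizes) != len(item_ids):
        raise ValueError("sizes must sum to the number of items")
    rng = np.random.default_rng(seed)
    perm = list(item_ids)
    rng.shuffle(perm)
    assignment: Dict[str, int] = {}
    pos = 0
    for k, s in enumerate(sizes):
        for item in perm[pos : pos + s]:
            assignment[item] = k
        pos += s
    return Clustering(assignment=assignment, K=len(sizes))


def filter_outlier_trees(
    dataset: TreeDataset, dmatrix: DistanceMatrix, quantile: float
) -> TreeDataset:
    """Drop trees whose mean distance to all others exceeds the given
    quantile of that statistic; quantile=1 is the identity.

    Stand-in rule for an outlier-removal preprocessing step; the matrix
    labels must match ``dataset.tree_labels()``.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    labels = dataset.tree_labels()
    if labels != list(dmatrix.labels):
        raise ValueError("distance matrix labels do not match dataset trees")
    n = len(labels)
    if n < 2 or quantile == 1.0:
        return dataset
    mean_dist = dmatrix.values.sum(axis=1) / (n - 1)
    threshold = np.quantile(mean_dist, quantile)
    keep = {lab for lab, md in zip(labels, mean_dist) if md <= threshold}
    patients = []
    for p in dataset.patients:
        kept = [
            t for i, t in enumerate(p.trees) if f"{p.patient_id}:{i}" in keep
        ]
        if kept:
            patients.append(
                PatientTreeSet(patient_id=p.patient_id, trees=kept, survival=p.survival)
            )
    return TreeDataset(patients=patients, provenance=dataset.provenance)
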