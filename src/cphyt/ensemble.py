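"""Ensemble progression scoring.

Patients are partitioned by k-means on their embeddings, one progression
scorer is fitted per cluster, and an unseen tree receives the maximum of
the per-cluster scores.  Any object implementing the :class:`TreeScorer`
contract can be plugged in; :class:`EdgeFrequencyScorer` is the built-in
reference implementation.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence

import numpy as np

from .clustering import Clustering
from .model import Embedding
from .trees import PhyloTree, TreeDataset, clone

__all__ = [
    "TreeScorer",
    "EdgeFrequencyScorer",
    "edge_frequency_scorer",
    "EnsembleModel",
    "fit_ensemble",
    "ensemble_score",
    "patient_score",
    "ComparisonReport",
    "compare_methods",
]

_ROOT_TOKEN = "<root>"


class TreeScorer(ABC):
    """Contract: fit on trees, then deterministically score any tree.

    Scores are probability-like non-negative reals; higher means the tree
    is more plausible under the fitted model.
    """

    @abstractmethod
    def fit(self, trees: Sequence[PhyloTree]) -> "TreeScorer":
        ...

    @abstractmethod
    def score(self, tree: PhyloTree) -> float:
        ...


class EdgeFrequencyScorer(TreeScorer):
    """Smoothed frequencies of (parent-clone alteration -> child alteration).

    For every edge (u, v) and every alteration b newly listed on v, each
    alteration a in the parent clone (or a root token when the parent clone
    is empty) witnesses a transition a -> b.  Scoring is the geometric mean
    of the smoothed transition probabilities over a tree's acquisition
    events, with pseudocount 1, so unseen transitions get a positive floor
    and scores lie in (0, 1].
    """

    def __init__(self) -> None:
        self._counts: Optional[Counter] = None
        self._source_totals: Optional[Counter] = None
        self._n_targets: int = 0

    def fit(self, trees: Sequence[PhyloTree]) -> "EdgeFrequencyScorer":
        counts: Counter = Counter()
        targets = set()
        for tree in trees:
            for a, b in self._transitions(tree):
                counts[(a, b)] += 1
                targets.add(b)
        self._counts = counts
        self._source_totals = Counter()
        for (a, _b), c in counts.items():
            self._source_totals[a] += c
        self._n_targets = max(len(targets), 1)
        return self

    @staticmethod
    def _transitions(tree: PhyloTree):
        for u, v in sorted(tree.edges):
            parent_clone = clone(tree, u)
            sources = sorted(parent_clone) if parent_clone else [_ROOT_TOKEN]
            for b in sorted(tree.nodes[v].label):
                for a in sources:
                    if a != b:
                        yield a, b

    def score(self, tree: PhyloTree) -> float:
        if self._counts is None:
            raise RuntimeError("scorer not fitted")
        log_sum = 0.0
        n = 0
        for a, b in self._transitions(tree):
            num = self._counts.get((a, b), 0) + 1
            den = self._source_totals.get(a, 0) + self._n_targets + 1
            log_sum += np.log(num / den)
            n += 1
        if n == 0:
            return 1.0  # empty product over zero acquisition events
        return float(np.exp(log_sum / n))


def edge_frequency_scorer() -> EdgeFrequencyScorer:
    return EdgeFrequencyScorer()


@dataclass
class EnsembleModel:
    K: int
    clustering: Clustering
    scorers: List[TreeScorer]

    def __post_init__(self) -> None:
        if len(self.scorers) != self.K:
            raise ValueError("ensemble must hold exactly K scorers")


def fit_ensemble(
    train: TreeDataset,
    embeddings: Sequence[Embedding],
    K: int,
    scorer_factory: Callable[[], TreeScorer] = edge_frequency_scorer,
    seed: int = 0,
) -> EnsembleModel:
    """Partition patients by k-means on patient-level embeddings and fit one
    scorer per cluster.

    ``embeddings`` must carry one vector per patient, with ``tree_id`` equal
    to the patient id.  Clusters with fewer than two patients are merged
    into the nearest other cluster (by centroid distance).
    """
    from .clustering import kmeans_cluster  # local import to avoid cycles

    patient_ids = [p.patient_id for p in train.patients]
    if sorted(e.tree_id for e in embeddings) != sorted(patient_ids):
        raise ValueError("embeddings are not aligned with training patients")
    if K > len(patient_ids):
        raise ValueError("K exceeds the number of patients")

    clustering = kmeans_cluster(list(embeddings), K, seed=seed)
    labels = {e.tree_id: clustering.assignment[e.tree_id] for e in embeddings}
    vectors = {e.tree_id: e.vector for e in embeddings}

    # merge sub-minimal clusters into the nearest cluster by centroid
    sizes = Counter(labels.values())
    small = sorted(k for k, s in sizes.items() if s < 2 and len(sizes) > 1)
    for k in small:
        members = [pid for pid, lab in labels.items() if lab == k]
        others = sorted(set(labels.values()) - {k})
        if not others or not members:
            continue
        centroids = {
            o: np.mean([vectors[p] for p, lab in labels.items() if lab == o], axis=0)
            for o in others
        }
        for pid in members:
            nearest = min(
                others, key=lambda o: float(np.linalg.norm(vectors[pid] - centroids[o]))
            )
            labels[pid] = nearest

    # relabel contiguously
    remap: Dict[int, int] = {}
    for pid in patient_ids:
        lab = labels[pid]
        if lab not in remap:
            remap[lab] = len(remap)
        labels[pid] = remap[lab]
    K_eff = len(remap)
    clustering = Clustering(assignment=dict(labels), K=K_eff)

    scorers: List[TreeScorer] = []
    for k in range(K_eff):
        cluster_trees = [
            t
            for p in train.patients
            if labels[p.patient_id] == k
            for t in p.trees
        ]
        scorers.append(scorer_factory().fit(cluster_trees))
    return EnsembleModel(K=K_eff, clustering=clustering, scorers=scorers)


def ensemble_score(ensemble: EnsembleModel, tree: PhyloTree) -> float:
    """Maximum score across the ensemble's fitted scorers."""
    if not ensemble.scorers:
        raise ValueError("ensemble has no fitted scorers")
    return max(s.score(tree) for s in ensemble.scorers)


def patient_score(tree_scores: Sequence[float]) -> float:
    """Patient-level aggregation over multiple plausible trees: the maximum."""
    if len(tree_scores) == 0:
        raise ValueError("patient has no tree scores")
    return float(max(tree_scores))


@dataclass
class ComparisonReport:
    """Win percentages between progression-scoring methods on test patients."""

    methods: List[str]
    pairwise_wins: Dict[str, Dict[str, float]]  # A -> B -> % patients A > B
    beats_all: Dict[str, float]  # method -> % patients strictly above all others


def compare_methods(
    scores_by_method: Mapping[str, Mapping[str, float]]
) -> ComparisonReport:
    """Percentage of test patients where one method out-scores another.

    Ties are not wins.  ``scores_by_method`` maps method name to a mapping
    from patient id to that method's patient-level score; all methods must
    cover the same patients.
    """
    methods = sorted(scores_by_method)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    patient_sets = [set(scores_by_method[m]) for m in methods]
    patients = sorted(patient_sets[0])
    if any(s != patient_sets[0] for s in patient_sets):
        raise ValueError("methods scored different patient sets")
    if not patients:
        raise ValueError("no patients to compare")

    n = len(patients)
    pairwise: Dict[str, Dict[str, float]] = {m: {} for m in methods}
    for a in methods:
        for b in methods:
            if a == b:
                continue
            wins = sum(
                1
                for pid in patients
                if scores_by_method[a][pid] > scores_by_method[b][pid]
            )
            pairwise[a][b] = 100.0 * wins / n
    beats_all = {}
    for a in methods:
        wins = sum(
            1
            for pid in patients
            if all(
                scores_by_method[a][pid] > scores_by_method[b][pid]
                for b in methods
                if b != a
            )
        )
        beats_all[a] = 100.0 * wins / n
    return ComparisonReport(methods=methods, pairwise_wins=pairwise, beats_all=beats_all)
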