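"""Extended Ancestor-Descendant (AD) distance between phylogenetic trees.

Each tree is reduced to two relations over alteration identifiers:

* ``ancestor_pairs`` — ordered pairs ``(a, b)`` such that some node labeled
  by ``a`` is a strict ancestor of some node labeled by ``b`` (``a != b``);
* ``cocluster_pairs`` — unordered pairs ``{a, b}`` co-occurring in one
  node's label.

The distance between two trees is the size of the symmetric difference of
the two relations, optionally normalized by the size of their unions so
that it lies in [0, 1].  With repeated alterations a pair is present if any
occurrence witnesses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .trees import AlterationVocabulary, PhyloTree, root_path

__all__ = ["ADPairSet", "DistanceMatrix", "ad_pairs", "ad_distance", "pairwise_distance_matrix"]


@dataclass(frozen=True)
class ADPairSet:
    ancestor_pairs: FrozenSet[Tuple[str, str]]
    cocluster_pairs: FrozenSet[FrozenSet[str]]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise tree-distance matrix with aligned labels."""

    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "\t" + "\t".join(f"{x:.10g}" for x in row))
        return "\n".join(lines) + "\n"


def ad_pairs(tree: PhyloTree, vocab: Optional[AlterationVocabulary] = None) -> ADPairSet:
    """Extract the ancestor and co-cluster alteration relations of a tree.

    If ``vocab`` is given, alterations outside it are treated as unknown and
    contribute no pairs (they cannot be matched across trees).
    """

    def known(label):
        if vocab is None:
            return set(label)
        return {a for a in label if a in vocab}

    anc: set = set()
    coc: set = set()
    # Walk the root path of every node once; the path prefix gives all strict
    # ancestors, so a single pass per node covers every (ancestor, node) pair.
    for v in tree.nodes:
        path = root_path(tree, v)
        lv = known(tree.nodes[v].label)
        for a, b in combinations(sorted(lv), 2):
            coc.add(frozenset((a, b)))
        ancestors: set = set()
        for u in path[:-1]:
            ancestors |= known(tree.nodes[u].label)
        for a in ancestors:
            for b in lv:
                if a != b:
                    anc.add((a, b))
    return ADPairSet(ancestor_pairs=frozenset(anc), cocluster_pairs=frozenset(coc))


def ad_distance(
    t1: PhyloTree,
    t2: PhyloTree,
    normalized: bool = True,
    vocab: Optional[AlterationVocabulary] = None,
) -> float:
    """Extended AD distance between two trees (>= 0; in [0,1] if normalized)."""
    p1 = ad_pairs(t1, vocab)
    p2 = ad_pairs(t2, vocab)
    return _pairset_distance(p1, p2, normalized)


def _pairset_distance(p1: ADPairSet, p2: ADPairSet, normalized: bool) -> float:
    diff = len(p1.ancestor_pairs ^ p2.ancestor_pairs) + len(
        p1.cocluster_pairs ^ p2.cocluster_pairs
    )
    if not normalized:
        return float(diff)
    union = len(p1.ancestor_pairs | p2.ancestor_pairs) + len(
        p1.cocluster_pairs | p2.cocluster_pairs
    )
    return diff / union if union else 0.0


def pairwise_distance_matrix(
    trees: Sequence[PhyloTree],
    normalized: bool = True,
    labels: Optional[Sequence[str]] = None,
    vocab: Optional[AlterationVocabulary] = None,
) -> DistanceMatrix:
    """All-pairs AD distances; pair sets are extracted once per tree."""
    if not trees:
        raise ValueError("need at least one tree")
    if labels is None:
        labels = [t.patient_id or f"tree{i}" for i, t in enumerate(trees)]
    pairsets = [ad_pairs(t, vocab) for t in trees]
    n = len(trees)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = _pairset_distance(pairsets[i], pairsets[j], normalized)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(labels), values=values)
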