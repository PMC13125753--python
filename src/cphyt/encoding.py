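"""Node encodings feeding the GNN.

Two integer encodings per node, both of length m+2 where m is the
vocabulary size: column 0 flags the root, columns 1..m indicate known
alterations, and column m+1 counts unknown alterations.

* ``lambda_encoding`` — per-node alteration indicators;
* ``clone_encoding`` — the sum of lambda rows along the root path, i.e. a
  clone-level view of each node (repeated alterations accumulate).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .trees import AlterationVocabulary, PhyloTree

__all__ = [
    "NodeEncodingMatrix",
    "EncodedTree",
    "canonical_node_order",
    "lambda_encoding",
    "clone_encoding",
    "encode_tree",
    "encode_dataset",
]


@dataclass
class NodeEncodingMatrix:
    node_order: List[str]
    matrix: np.ndarray  # |V| x (m+2), non-negative integers

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape[0] != len(self.node_order):
            raise ValueError("row count does not match node order")
        if (self.matrix < 0).any():
            raise ValueError("encoding entries must be non-negative")


@dataclass
class EncodedTree:
    """Clone-based encoding plus topology in row-index space."""

    encoding: NodeEncodingMatrix
    edges: List[Tuple[int, int]]
    root_row: int
    tree_id: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.encoding.node_order)


def canonical_node_order(tree: PhyloTree) -> List[str]:
    """Breadth-first from the root, children in lexicographic id order."""
    order = []
    queue = deque([tree.root])
    while queue:
        v = queue.popleft()
        order.append(v)
        queue.extend(tree.children(v))
    return order


def _lambda_row(tree: PhyloTree, v: str, vocab: AlterationVocabulary) -> np.ndarray:
    row = np.zeros(vocab.m + 2, dtype=np.int64)
    if v == tree.root:
        row[0] = 1
    for alt in tree.nodes[v].label:
        idx = vocab.index_of.get(alt)
        if idx is None:
            row[vocab.m + 1] += 1
        else:
            row[idx] = 1
    return row


def lambda_encoding(
    tree: PhyloTree, vocab: AlterationVocabulary
) -> NodeEncodingMatrix:
    """Alteration-based encoding: one indicator row per node."""
    order = canonical_node_order(tree)
    matrix = np.stack([_lambda_row(tree, v, vocab) for v in order])
    return NodeEncodingMatrix(node_order=order, matrix=matrix)


def clone_encoding(tree: PhyloTree, vocab: AlterationVocabulary) -> NodeEncodingMatrix:
    """Clone-based encoding: sum of lambda rows along each node's root path.

    Computed in one BFS pass: x_v = x_parent(v) + lambda_v.
    """
    order = canonical_node_order(tree)
    pos = {v: i for i, v in enumerate(order)}
    matrix = np.zeros((len(order), vocab.m + 2), dtype=np.int64)
    for v in order:  # BFS order guarantees parents precede children
        row = _lambda_row(tree, v, vocab)
        p = tree.parent(v)
        if p is not None:
            row = row + matrix[pos[p]]
        matrix[pos[v]] = row
    return NodeEncodingMatrix(node_order=order, matrix=matrix)


def encode_tree(
    tree: PhyloTree, vocab: AlterationVocabulary, tree_id: str = ""
) -> EncodedTree:
    enc = clone_encoding(tree, vocab)
    pos = {v: i for i, v in enumerate(enc.node_order)}
    edges = sorted((pos[p], pos[c]) for p, c in tree.edges)
    return EncodedTree(
        encoding=enc, edges=edges, root_row=pos[tree.root], tree_id=tree_id
    )


def encode_dataset(
    trees: Sequence[PhyloTree],
    vocab: AlterationVocabulary,
    tree_ids: Sequence[str] | None = None,
) -> List[EncodedTree]:
    if tree_ids is None:
        tree_ids = [t.patient_id or f"tree{i}" for i, t in enumerate(trees)]
    return [encode_tree(t, vocab, tid) for t, tid in zip(trees, tree_ids)]
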