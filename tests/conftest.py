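import numpy as np
import pytest

from cphyt.trees import (
    AlterationVocabulary,
    PatientTreeSet,
    PhyloNode,
    PhyloTree,
    TreeDataset,
)


def make_tree(edges, labels, root="r", patient_id=None):
    """Build a tree from (parent, child) pairs and {node: iterable} labels."""
    ids = {root} | {x for e in edges for x in e}
    nodes = {
        i: PhyloNode(id=i, label=frozenset(labels.get(i, ()))) for i in sorted(ids)
    }
    return PhyloTree(nodes=nodes, edges=edges, root=root, patient_id=patient_id)


def random_tree(rng, max_nodes=6, n_alterations=5, p_empty=0.2, patient_id=None):
    """Random small tree; labels may be empty or repeat across nodes."""
    n = int(rng.integers(1, max_nodes + 1))
    edges = []
    for i in range(1, n):
        parent = int(rng.integers(0, i))
        edges.append((f"n{parent}", f"n{i}"))
    labels = {}
    alts = [f"a{j}" for j in range(n_alterations)]
    for i in range(1, n):
        if rng.random() < p_empty:
            continue
        k = int(rng.integers(1, 4))
        labels[f"n{i}"] = set(rng.choice(alts, size=k, replace=True).tolist())
    return make_tree(edges, labels, root="n0", patient_id=patient_id)


@pytest.fixture
def chain_tree():
    """r -> a{1} -> b{2,3}"""
    return make_tree([("r", "a"), ("a", "b")], {"a": {"1"}, "b": {"2", "3"}})


@pytest.fixture
def star_tree():
    """r -> a{1}, r -> b{2}"""
    return make_tree([("r", "a"), ("r", "b")], {"a": {"1"}, "b": {"2"}})


@pytest.fixture
def single_node_tree():
    return make_tree([], {})


@pytest.fixture
def vocab3():
    return AlterationVocabulary(index_of={"1": 1, "2": 2, "3": 3}, m=3)


@pytest.fixture
def small_dataset(chain_tree, star_tree):
    c = make_tree([("r", "a"), ("a", "b")], {"a": {"1"}, "b": {"2", "3"}},
                  patient_id="p1")
    s = make_tree([("r", "a"), ("r", "b")], {"a": {"1"}, "b": {"2"}},
                  patient_id="p2")
    return TreeDataset(
        patients=[
            PatientTreeSet(patient_id="p1", trees=[c]),
            PatientTreeSet(patient_id="p2", trees=[s]),
        ]
    )
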