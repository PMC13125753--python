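"""Seeded generators of clustered synthetic phylogenetic-tree datasets.

Five scenarios, each producing clusters of trees that share a property the
embedding should recover:

* I / II  — clusters differ by topology; nodes carry random alteration
            labels (one per node in I, small sets in II);
* III     — clusters differ by topology family and size; all labels empty;
* IV / V  — a single shared topology; clusters differ only in the relation
            between two reserved alterations ``ALT_A`` and ``ALT_B``
            (ancestor/descendant, co-clustered, or incomparable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .trees import (
    PatientTreeSet,
    PhyloNode,
    PhyloTree,
    TreeDataset,
    validate_tree,
)

__all__ = [
    "SimConfig",
    "LabeledDataset",
    "simulate_topology_clusters",
    "simulate_unlabeled_sizes",
    "simulate_fixed_topology_relations",
    "simulate",
]


@dataclass
class SimConfig:
    scenario: str
    n_clusters: int = 2
    trees_per_cluster: int = 10
    n_alterations: int = 20
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("I", "II", "III", "IV", "V"):
            raise ValueError("scenario must be one of I..V")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.trees_per_cluster < 1:
            raise ValueError("need at least 1 tree per cluster")
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValueError("noise_level must be in [0,1]")


@dataclass
class LabeledDataset:
    dataset: TreeDataset
    truth: List[int]  # one cluster label per tree, aligned with all_trees()


# ---------------------------------------------------------------------------
# Topology building blocks.  A topology is a parent vector: entry i >= 1 is
# the parent row of node i; node 0 is the root.
# ---------------------------------------------------------------------------


def _chain(n: int) -> List[int]:
    return [i - 1 for i in range(1, n)]


def _star(n: int) -> List[int]:
    return [0] * (n - 1)


def _balanced_binary(n: int) -> List[int]:
    return [(i - 1) // 2 for i in range(1, n)]


def _caterpillar(n: int) -> List[int]:
    # spine node / leaf alternating: 0->1, 1->2(leaf), 1->3, 3->4(leaf), ...
    parents = []
    spine = 0
    for i in range(1, n):
        if i % 2 == 1:
            parents.append(spine)
            spine = i
        else:
            parents.append(parents[-1])
    return parents


# Non-isomorphic rooted shapes for scenarios I / II.  All have 8 nodes so
# every tree draws the same number of labels; with labels handed out in
# root-to-leaf order, what differs between clusters is the comparability
# structure of the topology, not the label count.
_TOPOLOGY_FAMILY: List[List[int]] = [
    _chain(8),
    _star(8),
    _balanced_binary(8),
    _caterpillar(8),
    [0, 1, 2, 3, 0, 5, 6],       # two chains (4 and 3) off the root
    [0, 1, 2, 3, 3, 3, 3],       # chain ending in a 4-leaf broom
    [0, 0, 0, 1, 2, 3, 4],       # three chains of mixed depth
    [0, 1, 1, 1, 2, 3, 4],       # one spine, wide first level
]

_FAMILIES = {
    "chain": _chain,
    "star": _star,
    "binary": _balanced_binary,
    "caterpillar": _caterpillar,
}

# Distinct (family, base size) combinations for scenario III; every combo
# uses a different family AND a different size, so no two clusters differ
# only by a property that average pooling washes out.
_SIZE_COMBOS: List[Tuple[str, int]] = [
    ("chain", 7),
    ("star", 9),
    ("binary", 11),
    ("caterpillar", 13),
]


def _tree_from_parents(
    parents: Sequence[int],
    labels: Dict[int, frozenset],
    patient_id: str,
) -> PhyloTree:
    n = len(parents) + 1
    nodes = {
        f"n{i}": PhyloNode(id=f"n{i}", label=labels.get(i, frozenset()))
        for i in range(n)
    }
    edges = [(f"n{p}", f"n{i + 1}") for i, p in enumerate(parents)]
    return PhyloTree(nodes=nodes, edges=edges, root="n0", patient_id=patient_id)


def _rewire_one_edge(tree: PhyloTree, rng: np.random.Generator) -> PhyloTree:
    """Detach one non-root node and reattach it under a different node."""
    candidates = sorted(v for v in tree.nodes if v != tree.root)
    rng.shuffle(candidates)
    for v in candidates:
        # nodes in v's subtree cannot become its parent
        sub = {v}
        stack = [v]
        while stack:
            u = stack.pop()
            for c in tree.children(u):
                sub.add(c)
                stack.append(c)
        old_parent = tree.parent(v)
        choices = sorted(set(tree.nodes) - sub - {old_parent})
        if not choices:
            continue
        new_parent = choices[rng.integers(len(choices))]
        edges = {(p, c) for p, c in tree.edges if c != v}
        edges.add((new_parent, v))
        return PhyloTree(
            nodes=dict(tree.nodes), edges=edges, root=tree.root,
            patient_id=tree.patient_id,
        )
    return tree  # cannot rewire (e.g. 2-node tree)


def _finish(trees: List[PhyloTree], truth: List[int], cfg: SimConfig) -> LabeledDataset:
    patients = [PatientTreeSet(patient_id=t.patient_id, trees=[t]) for t in trees]
    ds = TreeDataset(patients=patients, provenance=f"simulated scenario {cfg.scenario}")
    for t in trees:
        assert not validate_tree(t), f"generator produced invalid tree {t.patient_id}"
    return LabeledDataset(dataset=ds, truth=truth)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def simulate_topology_clusters(cfg: SimConfig) -> LabeledDataset:
    """Scenarios I and II: one distinct base topology per cluster."""
    if cfg.scenario not in ("I", "II"):
        raise ValueError("scenario must be I or II")
    if cfg.n_clusters > len(_TOPOLOGY_FAMILY):
        raise ValueError(
            f"at most {len(_TOPOLOGY_FAMILY)} clusters supported (distinct topologies)"
        )
    rng = np.random.default_rng(cfg.seed)
    pool = [f"ALT{i}" for i in range(cfg.n_alterations)]
    topo_idx = rng.choice(len(_TOPOLOGY_FAMILY), size=cfg.n_clusters, replace=False)

    trees: List[PhyloTree] = []
    truth: List[int] = []
    for k in range(cfg.n_clusters):
        parents = _TOPOLOGY_FAMILY[topo_idx[k]]
        n_nonroot = len(parents)
        # scenario I: one alteration per node; scenario II: per-cluster
        # fixed set sizes of 1-2 alterations per node
        sizes = (
            np.ones(n_nonroot, dtype=int)
            if cfg.scenario == "I"
            else rng.integers(1, 3, size=n_nonroot)
        )
        need = int(sizes.sum())
        if need > len(pool):
            raise ValueError("alteration pool too small for requested labels")
        for t in range(cfg.trees_per_cluster):
            # Sort the drawn alterations and hand them out in BFS node order:
            # lower-indexed alterations sit closer to the root, so which
            # ancestor pairs exist is determined by the cluster's topology
            # and the tree distance carries a topology signal even though
            # the alterations themselves are random.
            drawn = np.sort(rng.choice(len(pool), size=need, replace=False))
            labels: Dict[int, frozenset] = {}
            pos = 0
            for i, s in enumerate(sizes):
                labels[i + 1] = frozenset(pool[j] for j in drawn[pos : pos + s])
                pos += s
            tree = _tree_from_parents(parents, labels, f"sim{k}_{t}")
            if rng.random() < cfg.noise_level:
                tree = _rewire_one_edge(tree, rng)
            trees.append(tree)
            truth.append(k)
    return _finish(trees, truth, cfg)


def simulate_unlabeled_sizes(cfg: SimConfig) -> LabeledDataset:
    """Scenario III: unlabeled trees, clusters differ in family and size."""
    if cfg.scenario != "III":
        raise ValueError("scenario must be III")
    if cfg.n_clusters > len(_SIZE_COMBOS):
        raise ValueError(f"at most {len(_SIZE_COMBOS)} clusters supported")
    rng = np.random.default_rng(cfg.seed)
    combo_idx = rng.choice(len(_SIZE_COMBOS), size=cfg.n_clusters, replace=False)

    trees: List[PhyloTree] = []
    truth: List[int] = []
    for k in range(cfg.n_clusters):
        family, base = _SIZE_COMBOS[combo_idx[k]]
        make = _FAMILIES[family]
        for t in range(cfg.trees_per_cluster):
            size = base + int(rng.integers(-1, 2))  # jitter +-1
            parents = make(max(size, 3))
            trees.append(_tree_from_parents(parents, {}, f"sim{k}_{t}"))
            truth.append(k)
    return _finish(trees, truth, cfg)


# Archetype placements for the two reserved alterations on the shared
# topology r -> v1 -> v2 -> v3 with a side branch r -> v4 -> v5.
_SHARED_PARENTS = [0, 1, 2, 0, 4]  # 6 nodes
_ARCHETYPES = [
    {"name": "A_before_B", 1: "ALT_A", 2: "ALT_B"},
    {"name": "B_before_A", 1: "ALT_B", 2: "ALT_A"},
    {"name": "incomparable", 1: "ALT_A", 4: "ALT_B"},
    {"name": "coclustered", 1: ("ALT_A", "ALT_B")},
]


def simulate_fixed_topology_relations(cfg: SimConfig) -> LabeledDataset:
    """Scenarios IV and V: shared topology, cluster-specific A/B relation."""
    if cfg.scenario not in ("IV", "V"):
        raise ValueError("scenario must be IV or V")
    if cfg.scenario == "V":
        if cfg.n_clusters != 2:
            raise ValueError("scenario V uses exactly 2 clusters")
        archetypes = _ARCHETYPES[:2]  # the maximally distinct pair
    else:
        if cfg.n_clusters < 3 or cfg.n_clusters > len(_ARCHETYPES):
            raise ValueError(f"scenario IV needs 3..{len(_ARCHETYPES)} clusters")
        archetypes = _ARCHETYPES[: cfg.n_clusters]

    rng = np.random.default_rng(cfg.seed)
    pool = [f"ALT{i}" for i in range(cfg.n_alterations)]
    n_nonroot = len(_SHARED_PARENTS)

    trees: List[PhyloTree] = []
    truth: List[int] = []
    for k, arch in enumerate(archetypes):
        fixed = {
            node: frozenset(alts if isinstance(alts, tuple) else (alts,))
            for node, alts in arch.items()
            if node != "name"
        }
        free_nodes = [i + 1 for i in range(n_nonroot) if (i + 1) not in fixed]
        for t in range(cfg.trees_per_cluster):
            drawn = rng.choice(len(pool), size=len(free_nodes), replace=False)
            labels = dict(fixed)
            for node, j in zip(free_nodes, drawn):
                labels[node] = frozenset((pool[j],))
            tree = _tree_from_parents(_SHARED_PARENTS, labels, f"sim{k}_{t}")
            if rng.random() < cfg.noise_level:
                tree = _rewire_one_edge(tree, rng)
            trees.append(tree)
            truth.append(k)
    return _finish(trees, truth, cfg)


def simulate(cfg: SimConfig) -> LabeledDataset:
    """Dispatch on the scenario."""
    if cfg.scenario in ("I", "II"):
        return simulate_topology_clusters(cfg)
    if cfg.scenario == "III":
        return simulate_unlabeled_sizes(cfg)
    return simulate_fixed_topology_relations(cfg)
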