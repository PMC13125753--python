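"""Data model, validation and I/O for generalized tumor phylogenetic trees.

A phylogenetic tree here is a rooted directed tree whose nodes carry *sets*
of somatic alteration identifiers.  The root represents the germline state
and is labeled by the empty set.  The infinite-sites assumption is relaxed:
the same alteration may label several nodes of one tree, and non-root nodes
may carry empty labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "PatientTreeSet",
    "TreeDataset",
    "AlterationVocabulary",
    "TreeFormatError",
    "validate_tree",
    "root_path",
    "clone",
    "build_vocabulary",
    "parse_tree_json",
    "write_tree_json",
    "parse_dataset_json",
    "write_dataset_json",
    "parse_edge_list",
    "filter_by_edge_count",
    "collapse_to_gene_level",
]


class TreeFormatError(ValueError):
    """Raised when parsing malformed tree text."""


@dataclass(frozen=True)
class PhyloNode:
    """A clone node: opaque id plus a set of alteration identifiers."""

    id: str
    label: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", frozenset(self.label))


class PhyloTree:
    """Rooted directed tree with alteration-set node labels.

    Parameters
    ----------
    nodes:
        Mapping from node id to :class:`PhyloNode` (or an iterable of nodes).
    edges:
        Ordered ``(parent_id, child_id)`` pairs.
    root:
        Id of the root node.
    patient_id:
        Optional owning-patient identifier.
    """

    def __init__(
        self,
        nodes: Mapping[str, PhyloNode] | Iterable[PhyloNode],
        edges: Iterable[Tuple[str, str]],
        root: str,
        patient_id: Optional[str] = None,
    ) -> None:
        if not isinstance(nodes, Mapping):
            nodes = {n.id: n for n in nodes}
        self.nodes: Dict[str, PhyloNode] = dict(nodes)
        self.edges: Set[Tuple[str, str]] = {(str(p), str(c)) for p, c in edges}
        self.root: str = root
        self.patient_id = patient_id
        self._parent: Dict[str, str] = {}
        for p, c in self.edges:
            # last writer wins on malformed input; validate_tree reports it
            self._parent[c] = p

    # -- structure helpers -------------------------------------------------

    def parent(self, v: str) -> Optional[str]:
        return self._parent.get(v)

    def children(self, v: str) -> List[str]:
        return sorted(c for p, c in self.edges if p == v)

    def n_edges(self) -> int:
        return len(self.edges)

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.root == other.root
            and self.patient_id == other.patient_id
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PhyloTree(n_nodes={len(self.nodes)}, n_edges={len(self.edges)}, "
            f"root={self.root!r}, patient_id={self.patient_id!r})"
        )


@dataclass
class PatientTreeSet:
    """All plausible phylogenetic trees of one patient, plus optional survival."""

    patient_id: str
    trees: List[PhyloTree]
    survival: Optional["object"] = None  # SurvivalRecord; kept loose to avoid a cycle

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("PatientTreeSet requires at least one tree")
        for t in self.trees:
            if t.patient_id is None:
                t.patient_id = self.patient_id
            elif t.patient_id != self.patient_id:
                raise ValueError(
                    f"tree patient_id {t.patient_id!r} != {self.patient_id!r}"
                )


@dataclass
class TreeDataset:
    """Ordered collection of patients, each with one or more trees."""

    patients: List[PatientTreeSet] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate patient_ids in dataset")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def all_trees(self) -> List[PhyloTree]:
        """Flatten to a list of trees in patient order."""
        return [t for p in self.patients for t in p.trees]

    def tree_labels(self) -> List[str]:
        """Stable per-tree identifiers ``<patient_id>:<index>``."""
        return [
            f"{p.patient_id}:{i}" for p in self.patients for i in range(len(p.trees))
        ]


@dataclass
class AlterationVocabulary:
    """Bijection from the m known alterations onto indices 1..m.

    Index 0 is reserved for the root flag and index m+1 for unknown
    alterations; neither is ever assigned to an alteration.
    """

    index_of: Dict[str, int]
    m: int

    def __post_init__(self) -> None:
        if len(self.index_of) != self.m:
            raise ValueError("vocabulary size mismatch")
        if self.m and set(self.index_of.values()) != set(range(1, self.m + 1)):
            raise ValueError("vocabulary indices must be a bijection onto 1..m")

    def __contains__(self, alteration: str) -> bool:
        return alteration in self.index_of

    def to_tsv(self) -> str:
        lines = ["#alteration\tindex"]
        for alt, idx in sorted(self.index_of.items(), key=lambda kv: kv[1]):
            lines.append(f"{alt}\t{idx}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "AlterationVocabulary":
        index_of = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            alt, idx = line.split("\t")
            index_of[alt] = int(idx)
        return cls(index_of=index_of, m=len(index_of))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def validate_tree(tree: PhyloTree) -> List[str]:
    """Check all tree invariants; return human-readable violations (empty = valid)."""
    violations: List[str] = []
    node_ids = set(tree.nodes)
    if tree.root not in node_ids:
        violations.append(f"root {tree.root!r} is not a node")
        return violations

    for p, c in tree.edges:
        if p not in node_ids:
            violations.append(f"edge ({p!r},{c!r}): unknown parent {p!r}")
        if c not in node_ids:
            violations.append(f"edge ({p!r},{c!r}): unknown child {c!r}")

    indeg: Dict[str, int] = {v: 0 for v in node_ids}
    for p, c in tree.edges:
        if c in indeg:
            indeg[c] += 1

    roots = sorted(v for v, d in indeg.items() if d == 0)
    if len(roots) > 1:
        violations.append(f"multiple roots (in-degree-0 nodes): {roots}")
    if indeg.get(tree.root, 1) != 0:
        violations.append(f"root {tree.root!r} has incoming edges")
    for v, d in indeg.items():
        if v != tree.root and d > 1:
            violations.append(f"node {v!r} has in-degree {d} > 1")

    if tree.nodes[tree.root].label:
        violations.append(
            f"root label non-empty: {sorted(tree.nodes[tree.root].label)}"
        )

    # reachability from the root (also detects cycles: cyclic parts unreachable)
    seen = {tree.root}
    stack = [tree.root]
    adj: Dict[str, List[str]] = {}
    for p, c in tree.edges:
        adj.setdefault(p, []).append(c)
    while stack:
        v = stack.pop()
        for c in adj.get(v, []):
            if c not in seen:
                seen.add(c)
                stack.append(c)
    unreachable = sorted(node_ids - seen)
    if unreachable:
        violations.append(f"nodes unreachable from root: {unreachable}")
    return violations


def root_path(tree: PhyloTree, v: str) -> List[str]:
    """Node ids on the unique directed path from the root to ``v``, inclusive."""
    if v not in tree.nodes:
        raise KeyError(f"unknown node id {v!r}")
    path = [v]
    seen = {v}
    while path[-1] != tree.root:
        p = tree.parent(path[-1])
        if p is None or p in seen:
            raise ValueError(f"node {v!r} is not connected to the root")
        path.append(p)
        seen.add(p)
    return path[::-1]


def clone(tree: PhyloTree, v: str) -> frozenset:
    """The clone induced by ``v``: union of labels along the root path."""
    out: Set[str] = set()
    for u in root_path(tree, v):
        out |= tree.nodes[u].label
    return frozenset(out)


def build_vocabulary(dataset: TreeDataset) -> AlterationVocabulary:
    """Index every alteration occurring in the dataset, lexicographically."""
    alts: Set[str] = set()
    for t in dataset.all_trees():
        for node in t.nodes.values():
            alts |= node.label
    ordered = sorted(alts)
    return AlterationVocabulary(
        index_of={a: i + 1 for i, a in enumerate(ordered)}, m=len(ordered)
    )


# -- JSON I/O ---------------------------------------------------------------
#
# Schema: {"patient_id": str?, "root": str,
#          "nodes": [{"id": str, "label": [str, ...]}, ...],
#          "edges": [[parent, child], ...]}


def _tree_from_obj(obj: dict) -> PhyloTree:
    if not isinstance(obj, dict):
        raise TreeFormatError("tree object must be a JSON object")
    for key in ("root", "nodes", "edges"):
        if key not in obj:
            raise TreeFormatError(f"missing required key {key!r}")
    nodes: Dict[str, PhyloNode] = {}
    for nd in obj["nodes"]:
        if "id" not in nd:
            raise TreeFormatError("node object missing 'id'")
        nid = str(nd["id"])
        if nid in nodes:
            raise TreeFormatError(f"duplicate node id {nid!r}")
        raw = [str(x) for x in nd.get("label", [])]
        label = frozenset(raw)
        if len(raw) != len(label):
            warnings.warn(
                f"node {nid!r}: duplicate label entries collapsed to a set",
                stacklevel=3,
            )
        nodes[nid] = PhyloNode(id=nid, label=label)
    edges = [(str(p), str(c)) for p, c in obj["edges"]]
    root = str(obj["root"])
    if root not in nodes:
        raise TreeFormatError(f"root {root!r} not among node ids")
    return PhyloTree(
        nodes=nodes, edges=edges, root=root, patient_id=obj.get("patient_id")
    )


def _tree_to_obj(tree: PhyloTree) -> dict:
    obj = {
        "root": tree.root,
        "nodes": [
            {"id": nid, "label": sorted(tree.nodes[nid].label)}
            for nid in sorted(tree.nodes)
        ],
        "edges": sorted([p, c] for p, c in tree.edges),
    }
    if tree.patient_id is not None:
        obj["patient_id"] = tree.patient_id
    return obj


def parse_tree_json(text: str) -> PhyloTree:
    """Parse a single tree from its JSON object representation."""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TreeFormatError(f"invalid JSON: {exc}") from exc
    return _tree_from_obj(obj)


def write_tree_json(tree: PhyloTree) -> str:
    return json.dumps(_tree_to_obj(tree), indent=1)


def parse_dataset_json(text: str, provenance: str = "") -> TreeDataset:
    """Parse a dataset from a JSON array of tree objects (or JSON-lines).

    Trees sharing a ``patient_id`` are grouped into one patient in order of
    first appearance; trees without a patient id each become their own
    patient, identified positionally.
    """
    text = text.strip()
    try:
        if text.startswith("["):
            objs = json.loads(text)
        else:
            objs = [json.loads(line) for line in text.splitlines() if line.strip()]
    except json.JSONDecodeError as exc:
        raise TreeFormatError(f"invalid JSON: {exc}") from exc

    by_patient: Dict[str, List[PhyloTree]] = {}
    order: List[str] = []
    for i, obj in enumerate(objs):
        t = _tree_from_obj(obj)
        pid = t.patient_id if t.patient_id is not None else f"tree{i}"
        t.patient_id = pid
        if pid not in by_patient:
            by_patient[pid] = []
            order.append(pid)
        by_patient[pid].append(t)
    return TreeDataset(
        patients=[PatientTreeSet(patient_id=pid, trees=by_patient[pid]) for pid in order],
        provenance=provenance,
    )


def write_dataset_json(dataset: TreeDataset) -> str:
    objs = [_tree_to_obj(t) for t in dataset.all_trees()]
    return json.dumps(objs, indent=1)


# -- Edge-list TSV ----------------------------------------------------------
#
# Three tab-separated columns: parent_id, child_id, child_labels
# (semicolon-separated, possibly empty).  The root never appears as a child,
# and its own label is always empty.  Lines starting with '#' are comments.


def parse_edge_list(text: str) -> PhyloTree:
    """Parse one tree from the three-column TSV edge-list dialect."""
    labels: Dict[str, Set[str]] = {}
    edges: List[Tuple[str, str]] = []
    parents: Set[str] = set()
    children: Set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise TreeFormatError(
                f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        parent, child, label_field = parts
        if not parent or not child:
            raise TreeFormatError(f"line {lineno}: empty node id")
        edges.append((parent, child))
        parents.add(parent)
        children.add(child)
        labels.setdefault(parent, set())
        labels[child] = {x for x in label_field.split(";") if x}
    if not edges:
        raise TreeFormatError("edge list contains no edges")
    roots = sorted(parents - children)
    if len(roots) != 1:
        raise TreeFormatError(
            f"cannot infer a unique root; candidates: {roots}"
        )
    nodes = {nid: PhyloNode(id=nid, label=frozenset(lab)) for nid, lab in labels.items()}
    tree = PhyloTree(nodes=nodes, edges=edges, root=roots[0])
    violations = validate_tree(tree)
    if violations:
        raise TreeFormatError("; ".join(violations))
    return tree


# -- Dataset transforms -----------------------------------------------------


def filter_by_edge_count(dataset: TreeDataset, max_edges: int) -> TreeDataset:
    """Drop trees with more than ``max_edges`` edges; drop emptied patients."""
    if max_edges < 0:
        raise ValueError("max_edges must be >= 0")
    patients: List[PatientTreeSet] = []
    for p in dataset.patients:
        kept = [t for t in p.trees if t.n_edges() <= max_edges]
        if kept:
            patients.append(
                PatientTreeSet(patient_id=p.patient_id, trees=kept, survival=p.survival)
            )
    return TreeDataset(patients=patients, provenance=dataset.provenance)


def collapse_to_gene_level(
    dataset: TreeDataset, mapping: Mapping[str, str]
) -> TreeDataset:
    """Replace each alteration by its gene; topology is preserved.

    The same gene may then label multiple nodes of one tree (an
    infinite-sites violation, permitted by the data model).
    """
    patients: List[PatientTreeSet] = []
    for p in dataset.patients:
        new_trees = []
        for t in p.trees:
            new_nodes: Dict[str, PhyloNode] = {}
            for nid, node in t.nodes.items():
                genes = set()
                for alt in node.label:
                    if alt not in mapping:
                        raise KeyError(f"alteration {alt!r} missing from gene mapping")
                    genes.add(mapping[alt])
                new_nodes[nid] = PhyloNode(id=nid, label=frozenset(genes))
            new_trees.append(
                PhyloTree(
                    nodes=new_nodes,
                    edges=set(t.edges),
                    root=t.root,
                    patient_id=t.patient_id,
                )
            )
        patients.append(
            PatientTreeSet(patient_id=p.patient_id, trees=new_trees, survival=p.survival)
        )
    return TreeDataset(patients=patients, provenance=dataset.provenance)
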