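import json

import numpy as np
import pytest

from cphyt.trees import (
    AlterationVocabulary,
    PatientTreeSet,
    PhyloNode,
    PhyloTree,
    TreeDataset,
    TreeFormatError,
    build_vocabulary,
    clone,
    collapse_to_gene_level,
    filter_by_edge_count,
    parse_dataset_json,
    parse_edge_list,
    parse_tree_json,
    root_path,
    validate_tree,
    write_dataset_json,
    write_tree_json,
)

from conftest import make_tree, random_tree


class TestValidateTree:
    def test_minimal_legal_tree(self, single_node_tree):
        assert validate_tree(single_node_tree) == []

    def test_root_label_nonempty(self):
        t = make_tree([("r", "a")], {"r": {"TP53"}, "a": {"x"}})
        violations = validate_tree(t)
        assert len(violations) == 1
        assert "root label non-empty" in violations[0]

    def test_multiple_roots(self):
        nodes = {i: PhyloNode(id=i) for i in ("r", "s", "a")}
        t = PhyloTree(nodes=nodes, edges=[("r", "a")], root="r")
        assert any("roots" in v or "unreachable" in v for v in validate_tree(t))

    def test_in_degree_two(self):
        t = make_tree([("r", "a"), ("r", "b"), ("a", "b")], {})
        assert any("in-degree" in v for v in validate_tree(t))

    def test_cycle_detected_as_unreachable(self):
        nodes = {i: PhyloNode(id=i) for i in ("r", "a", "b")}
        t = PhyloTree(nodes=nodes, edges=[("a", "b"), ("b", "a")], root="r")
        assert any("unreachable" in v for v in validate_tree(t))

    def test_valid_chain(self, chain_tree):
        assert validate_tree(chain_tree) == []


class TestRootPath:
    def test_chain(self, chain_tree):
        assert root_path(chain_tree, "b") == ["r", "a", "b"]

    def test_root_itself(self, chain_tree):
        assert root_path(chain_tree, "r") == ["r"]

    def test_star(self, star_tree):
        assert root_path(star_tree, "a") == ["r", "a"]

    def test_unknown_node(self, chain_tree):
        with pytest.raises(KeyError):
            root_path(chain_tree, "zzz")


class TestClone:
    def test_union_along_path(self, chain_tree):
        assert clone(chain_tree, "b") == {"1", "2", "3"}

    def test_root_clone_empty(self, chain_tree):
        assert clone(chain_tree, "r") == frozenset()

    def test_repeated_alteration_collapses(self):
        t = make_tree([("r", "a"), ("a", "b")], {"a": {"1"}, "b": {"1"}})
        assert clone(t, "b") == {"1"}

    def test_monotone_along_root_paths(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            t = random_tree(rng)
            for v in t.nodes:
                p = t.parent(v)
                if p is not None:
                    assert clone(t, v) >= clone(t, p)


class TestBuildVocabulary:
    def test_lexicographic(self):
        t = make_tree([("r", "a")], {"a": {"B", "A"}}, patient_id="p")
        ds = TreeDataset(patients=[PatientTreeSet(patient_id="p", trees=[t])])
        v = build_vocabulary(ds)
        assert v.m == 2
        assert v.index_of == {"A": 1, "B": 2}

    def test_empty_labels(self, single_node_tree):
        single_node_tree.patient_id = "p"
        ds = TreeDataset(
            patients=[PatientTreeSet(patient_id="p", trees=[single_node_tree])]
        )
        assert build_vocabulary(ds).m == 0

    def test_shared_alteration_one_index(self, small_dataset):
        v = build_vocabulary(small_dataset)
        assert v.m == 3  # alterations 1, 2, 3 across both patients
        assert set(v.index_of.values()) == {1, 2, 3}


class TestJsonRoundTrip:
    def test_round_trip(self, chain_tree):
        assert parse_tree_json(write_tree_json(chain_tree)) == chain_tree

    def test_missing_root_key(self):
        with pytest.raises(TreeFormatError, match="root"):
            parse_tree_json(json.dumps({"nodes": [], "edges": []}))

    def test_duplicate_label_warns(self):
        text = json.dumps(
            {
                "root": "r",
                "nodes": [{"id": "r", "label": []}, {"id": "a", "label": ["x", "x"]}],
                "edges": [["r", "a"]],
            }
        )
        with pytest.warns(UserWarning, match="collapsed"):
            t = parse_tree_json(text)
        assert t.nodes["a"].label == {"x"}

    def test_duplicate_node_id(self):
        text = json.dumps(
            {
                "root": "r",
                "nodes": [{"id": "r"}, {"id": "r"}],
                "edges": [],
            }
        )
        with pytest.raises(TreeFormatError, match="duplicate"):
            parse_tree_json(text)

    def test_dataset_round_trip(self, small_dataset):
        ds = parse_dataset_json(write_dataset_json(small_dataset))
        assert ds.all_trees() == small_dataset.all_trees()

    def test_random_trees_round_trip(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            t = random_tree(rng)
            assert parse_tree_json(write_tree_json(t)) == t


class TestParseEdgeList:
    def test_chain(self):
        t = parse_edge_list("r\ta\t1\na\tb\t2;3\n")
        assert t.root == "r"
        assert t.nodes["a"].label == {"1"}
        assert t.nodes["b"].label == {"2", "3"}

    def test_empty_label_field(self):
        t = parse_edge_list("r\ta\t\n")
        assert t.nodes["a"].label == frozenset()

    def test_cycle_is_error(self):
        with pytest.raises(TreeFormatError):
            parse_edge_list("a\tb\tx\nb\ta\ty\nr\ta\tz\n")

    def test_no_unique_root(self):
        with pytest.raises(TreeFormatError, match="root"):
            parse_edge_list("r\ta\tx\ns\tb\ty\n")

    def test_comment_lines_skipped(self):
        t = parse_edge_list("#parent\tchild\tlabels\nr\ta\t1\n")
        assert len(t.nodes) == 2


def _dataset_with_sizes(sizes):
    patients = []
    for pi, tree_sizes in enumerate(sizes):
        trees = []
        for ti, n_edges in enumerate(tree_sizes):
            edges = [(f"n{j}", f"n{j + 1}") for j in range(n_edges)]
            trees.append(
                make_tree(edges, {}, root="n0", patient_id=f"p{pi}")
                if n_edges
                else make_tree([], {}, root="n0", patient_id=f"p{pi}")
            )
        patients.append(PatientTreeSet(patient_id=f"p{pi}", trees=trees))
    return TreeDataset(patients=patients)


class TestFilterByEdgeCount:
    def test_threshold(self):
        ds = _dataset_with_sizes([[9, 10]])
        out = filter_by_edge_count(ds, 9)
        assert len(out.patients[0].trees) == 1
        assert out.patients[0].trees[0].n_edges() == 9

    def test_patient_dropped(self):
        ds = _dataset_with_sizes([[10, 11], [3]])
        out = filter_by_edge_count(ds, 9)
        assert [p.patient_id for p in out.patients] == ["p1"]

    def test_identity_for_large_threshold(self):
        ds = _dataset_with_sizes([[2, 5], [7]])
        out = filter_by_edge_count(ds, 100)
        assert [len(p.trees) for p in out.patients] == [2, 1]

    def test_idempotent(self):
        ds = _dataset_with_sizes([[2, 5, 9, 12], [7, 20]])
        once = filter_by_edge_count(ds, 8)
        twice = filter_by_edge_count(once, 8)
        assert [p.patient_id for p in once.patients] == [
            p.patient_id for p in twice.patients
        ]
        assert [len(p.trees) for p in once.patients] == [
            len(p.trees) for p in twice.patients
        ]


class TestCollapseToGeneLevel:
    def test_two_variants_same_gene_on_two_nodes(self):
        t = make_tree(
            [("r", "a"), ("a", "b")],
            {"a": {"TP53_p.R175H"}, "b": {"TP53_p.R248Q"}},
            patient_id="p",
        )
        ds = TreeDataset(patients=[PatientTreeSet(patient_id="p", trees=[t])])
        out = collapse_to_gene_level(
            ds, {"TP53_p.R175H": "TP53", "TP53_p.R248Q": "TP53"}
        )
        tree = out.patients[0].trees[0]
        assert tree.nodes["a"].label == {"TP53"}
        assert tree.nodes["b"].label == {"TP53"}
        assert tree.edges == t.edges  # topology preserved

    def test_identity_mapping(self, small_dataset):
        alts = {"1": "1", "2": "2", "3": "3"}
        out = collapse_to_gene_level(small_dataset, alts)
        assert out.all_trees() == small_dataset.all_trees()

    def test_two_variants_one_node_collapse(self):
        t = make_tree([("r", "a")], {"a": {"G_v1", "G_v2"}}, patient_id="p")
        ds = TreeDataset(patients=[PatientTreeSet(patient_id="p", trees=[t])])
        out = collapse_to_gene_level(ds, {"G_v1": "G", "G_v2": "G"})
        assert out.patients[0].trees[0].nodes["a"].label == {"G"}

    def test_unmapped_alteration_raises(self, small_dataset):
        with pytest.raises(KeyError):
            collapse_to_gene_level(small_dataset, {"1": "g1"})


class TestVocabularyTsv:
    def test_round_trip(self, vocab3):
        assert AlterationVocabulary.from_tsv(vocab3.to_tsv()).index_of == vocab3.index_of
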