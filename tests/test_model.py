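import numpy as np
import pytest

from cphyt.distance import DistanceMatrix, pairwise_distance_matrix
from cphyt.encoding import encode_tree
from cphyt.model import (
    Embedding,
    ModelConfig,
    ModelParams,
    TrainConfig,
    dataset_loss,
    embed,
    embed_trees,
    forward,
    init_params,
    load_model,
    pair_loss,
    save_model,
    train_supervised_survival,
    train_unsupervised,
    predict_survival_score,
)
from cphyt.simulate import SimConfig, simulate
from cphyt.survival import SurvivalRecord
from cphyt.trees import AlterationVocabulary, build_vocabulary

from conftest import make_tree, random_tree


@pytest.fixture
def cfg3():
    return ModelConfig(input_dim=5, hidden_dim=8, embedding_dim=4, dropout_rate=0.0, seed=0)


class TestForward:
    def test_zero_weights_bias_only(self, chain_tree, vocab3, cfg3):
        params = init_params(cfg3)
        for name in params.trainable_names():
            params[name] = np.zeros_like(params[name])
        params["b"] = np.ones(cfg3.embedding_dim)
        z = forward(params, cfg3, encode_tree(chain_tree, vocab3))
        assert np.allclose(z.vector, 1.0)

    def test_node_relabeling_invariance(self, vocab3, cfg3):
        t1 = make_tree([("r", "a"), ("a", "b"), ("r", "c")],
                       {"a": {"1"}, "b": {"2"}, "c": {"3"}})
        # same tree, ids renamed so the canonical BFS order differs
        t2 = make_tree([("r", "z"), ("z", "k"), ("r", "m")],
                       {"z": {"1"}, "k": {"2"}, "m": {"3"}})
        params = init_params(cfg3)
        z1 = forward(params, cfg3, encode_tree(t1, vocab3))
        z2 = forward(params, cfg3, encode_tree(t2, vocab3))
        assert np.allclose(z1.vector, z2.vector)

    def test_eval_mode_deterministic(self, chain_tree, vocab3):
        cfg = ModelConfig(input_dim=5, hidden_dim=8, embedding_dim=4,
                          dropout_rate=0.5, seed=1)
        params = init_params(cfg)
        enc = encode_tree(chain_tree, vocab3)
        z1 = forward(params, cfg, enc, training_mode=False)
        z2 = forward(params, cfg, enc, training_mode=False)
        assert (z1.vector == z2.vector).all()

    def test_shape_mismatch_raises(self, chain_tree, cfg3):
        wide_vocab = AlterationVocabulary(
            index_of={str(i): i for i in range(1, 8)}, m=7
        )
        with pytest.raises(ValueError, match="input_dim"):
            forward(init_params(cfg3), cfg3, encode_tree(chain_tree, wide_vocab))

    def test_output_dimension(self, chain_tree, vocab3, cfg3):
        z = forward(init_params(cfg3), cfg3, encode_tree(chain_tree, vocab3))
        assert z.vector.shape == (4,)
        assert np.all(np.isfinite(z.vector))


class TestPairLoss:
    def test_exact_match(self):
        assert pair_loss(np.array([0.0, 0.0]), np.array([2.0, 0.0]), 2.0) == 0.0

    def test_arithmetic(self):
        assert pair_loss(np.array([0.0, 0.0]), np.array([1.0, 0.0]), 3.0) == 2.0

    def test_equal_embeddings_zero_distance(self):
        z = np.array([1.0, 2.0])
        assert pair_loss(z, z, 0.0) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            pair_loss(np.zeros(2), np.zeros(3), 1.0)


class TestDatasetLoss:
    def _embs(self, vectors):
        return [Embedding(vector=np.asarray(v, float), tree_id=f"t{i}")
                for i, v in enumerate(vectors)]

    def test_mean_over_pairs(self):
        # 3 collinear points at 0, 2, 6 with target distances chosen to give
        # pair losses 0, 2, 4 -> mean 2.0
        embs = self._embs([[0.0], [2.0], [6.0]])
        D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        dm = DistanceMatrix(labels=["t0", "t1", "t2"], values=D)
        # pair losses: |2-2|=0, |2-6|=4, |2-4|=2
        assert dataset_loss(embs, dm) == pytest.approx(2.0)

    def test_exactly_realizable_zero(self):
        embs = self._embs([[0.0], [1.0], [3.0]])
        D = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        dm = DistanceMatrix(labels=["t0", "t1", "t2"], values=D)
        assert dataset_loss(embs, dm) == 0.0

    def test_two_trees_single_pair(self):
        embs = self._embs([[0.0], [5.0]])
        dm = DistanceMatrix(labels=["t0", "t1"], values=np.array([[0, 2], [2, 0]], float))
        assert dataset_loss(embs, dm) == pytest.approx(3.0)

    def test_fewer_than_two_raises(self):
        embs = self._embs([[0.0]])
        dm = DistanceMatrix(labels=["t0"], values=np.zeros((1, 1)))
        with pytest.raises(ValueError):
            dataset_loss(embs, dm)


class TestTrainUnsupervised:
    def test_seed_reproducibility(self):
        lab = simulate(SimConfig(scenario="I", n_clusters=2, trees_per_cluster=5,
                                 seed=3, n_alterations=8))
        vocab = build_vocabulary(lab.dataset)
        tc = TrainConfig(epochs=5, seed=42)
        _, log1 = train_unsupervised(lab.dataset, vocab, train_cfg=tc)
        _, log2 = train_unsupervised(lab.dataset, vocab, train_cfg=tc)
        assert log1["epoch_loss"] == log2["epoch_loss"]

    def test_loss_decreases(self):
        lab = simulate(SimConfig(scenario="V", n_clusters=2, trees_per_cluster=10,
                                 seed=0, n_alterations=10))
        vocab = build_vocabulary(lab.dataset)
        _, log = train_unsupervised(
            lab.dataset, vocab,
            train_cfg=TrainConfig(epochs=60, seed=0, learning_rate=3e-3),
        )
        first = np.mean(log["epoch_loss"][:10])
        last = np.mean(log["epoch_loss"][-10:])
        assert last < first

    def test_identical_trees_embed_close_after_training(self):
        from cphyt.trees import PatientTreeSet, TreeDataset

        t1 = make_tree([("r", "a")], {"a": {"x"}}, patient_id="p1")
        t2 = make_tree([("r", "a")], {"a": {"x"}}, patient_id="p2")
        t3 = make_tree([("r", "a"), ("a", "b")], {"a": {"y"}, "b": {"x"}},
                       patient_id="p3")
        ds = TreeDataset(patients=[
            PatientTreeSet(patient_id=p.patient_id, trees=[p]) for p in (t1, t2, t3)
        ])
        vocab = build_vocabulary(ds)
        cfg = ModelConfig(input_dim=vocab.m + 2, hidden_dim=8, embedding_dim=4,
                          dropout_rate=0.0, seed=0)
        params, _ = train_unsupervised(
            ds, vocab, cfg, TrainConfig(epochs=100, seed=0, trees_per_batch=3)
        )
        z1 = embed(params, cfg, t1, vocab)
        z2 = embed(params, cfg, t2, vocab)
        # identical trees -> identical embeddings, distance exactly 0
        assert np.allclose(z1.vector, z2.vector)

    def test_too_few_trees_raises(self, chain_tree, vocab3):
        from cphyt.trees import PatientTreeSet, TreeDataset

        chain_tree.patient_id = "p"
        ds = TreeDataset(patients=[PatientTreeSet(patient_id="p", trees=[chain_tree])])
        with pytest.raises(ValueError):
            train_unsupervised(ds, vocab3)


class TestEmbed:
    def test_unseen_alteration_is_finite(self, vocab3, cfg3):
        t = make_tree([("r", "a")], {"a": {"NEVER_SEEN_BEFORE"}})
        z = embed(init_params(cfg3), cfg3, t, vocab3)
        assert np.all(np.isfinite(z.vector))

    def test_matches_forward(self, chain_tree, vocab3, cfg3):
        params = init_params(cfg3)
        z1 = embed(params, cfg3, chain_tree, vocab3)
        z2 = forward(params, cfg3, encode_tree(chain_tree, vocab3))
        assert (z1.vector == z2.vector).all()

    def test_batch_embed_matches_single(self, vocab3, cfg3):
        rng = np.random.default_rng(0)
        trees = [random_tree(rng) for _ in range(4)]
        params = init_params(cfg3)
        batch = embed_trees(params, cfg3, trees, vocab3)
        for t, zb in zip(trees, batch):
            zs = embed(params, cfg3, t, vocab3)
            assert np.allclose(zb.vector, zs.vector)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, chain_tree, vocab3, cfg3):
        params = init_params(cfg3)
        save_model(params, cfg3, vocab3, str(tmp_path / "ckpt"))
        p2, c2, v2 = load_model(str(tmp_path / "ckpt"))
        assert c2 == cfg3
        assert v2.index_of == vocab3.index_of
        z1 = embed(params, cfg3, chain_tree, vocab3)
        z2 = embed(p2, c2, chain_tree, vocab3)
        assert np.allclose(z1.vector, z2.vector)


def _survival_dataset(seed=0, n=40):
    """Clone count determines survival time (larger clone = shorter life)."""
    from cphyt.trees import PatientTreeSet, TreeDataset

    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n):
        depth = int(rng.integers(1, 6))
        edges = [(f"n{j}", f"n{j + 1}") for j in range(depth)]
        labels = {f"n{j + 1}": {f"m{j}"} for j in range(depth)}
        t = make_tree(edges, labels, root="n0", patient_id=f"p{i}")
        time = 100.0 / depth * float(np.exp(rng.normal(scale=0.1)))
        patients.append(
            PatientTreeSet(
                patient_id=f"p{i}",
                trees=[t],
                survival=SurvivalRecord(time=time, event=1),
            )
        )
    return TreeDataset(patients=patients)


class TestSupervisedSurvival:
    def test_recovers_separable_risk(self):
        from cphyt.survival import concordance_index_censored

        ds = _survival_dataset(seed=0)
        vocab = build_vocabulary(ds)
        cfg = ModelConfig(input_dim=vocab.m + 2, seed=0)
        params = train_supervised_survival(
            ds, vocab, cfg, TrainConfig(epochs=100, seed=0, learning_rate=3e-3)
        )
        test = _survival_dataset(seed=1, n=20)
        scores = [
            predict_survival_score(params, cfg, p.trees[0], vocab)
            for p in test.patients
        ]
        cidx = concordance_index_censored(scores, [p.survival for p in test.patients])
        assert cidx > 0.8

    def test_all_censored_same_time_completes(self):
        from cphyt.trees import PatientTreeSet, TreeDataset

        patients = []
        for i in range(4):
            t = make_tree([("r", "a")], {"a": {f"x{i}"}}, patient_id=f"p{i}")
            patients.append(
                PatientTreeSet(
                    patient_id=f"p{i}", trees=[t],
                    survival=SurvivalRecord(time=5.0, event=0),
                )
            )
        ds = TreeDataset(patients=patients)
        vocab = build_vocabulary(ds)
        cfg = ModelConfig(input_dim=vocab.m + 2, hidden_dim=4, embedding_dim=2, seed=0)
        params = train_supervised_survival(
            ds, vocab, cfg, TrainConfig(epochs=3, seed=0)
        )
        s = predict_survival_score(params, cfg, patients[0].trees[0], vocab)
        assert np.isfinite(s)

    def test_head_required_for_prediction(self, chain_tree, vocab3, cfg3):
        params = init_params(cfg3)  # no head
        with pytest.raises(ValueError, match="head"):
            predict_survival_score(params, cfg3, chain_tree, vocab3)

    def test_identical_trees_same_score(self, vocab3, cfg3):
        params = init_params(cfg3, with_head=True)
        t1 = make_tree([("r", "a")], {"a": {"1"}})
        t2 = make_tree([("r", "a")], {"a": {"1"}})
        s1 = predict_survival_score(params, cfg3, t1, vocab3)
        s2 = predict_survival_score(params, cfg3, t2, vocab3)
        assert s1 == s2

    def test_missing_survival_raises(self, small_dataset, vocab3):
        with pytest.raises(ValueError, match="survival"):
            train_supervised_survival(small_dataset, vocab3)
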