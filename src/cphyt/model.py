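"""Distance-matching GNN over phylogenetic trees, in plain NumPy.

Architecture: two graph-convolutional layers (each followed by batch
normalization and ReLU), dropout before the second convolution, average
pooling over nodes, dropout, and a final linear map to the embedding space
R^q.  Training minimizes the mean absolute difference between pairwise
embedding distances and precomputed tree distances; forward and backward
passes are implemented directly on dense/sparse arrays so no deep-learning
framework is required.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .distance import DistanceMatrix, pairwise_distance_matrix
from .encoding import EncodedTree, encode_dataset, encode_tree
from .trees import AlterationVocabulary, PhyloTree, TreeDataset

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ModelParams",
    "Embedding",
    "init_params",
    "forward",
    "pair_loss",
    "dataset_loss",
    "train_unsupervised",
    "embed",
    "embed_trees",
    "train_supervised_survival",
    "predict_survival_score",
    "save_model",
    "load_model",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class ModelConfig:
    input_dim: int
    hidden_dim: int = 64
    embedding_dim: int = 32
    dropout_rate: float = 0.2
    undirected_messages: bool = True
    # "gcn": symmetric degree-normalized propagation (with self-loops).
    # "mean": plain mean over self + neighbors.  The gcn variant is the
    # default because mean aggregation maps constant node features to
    # constant node features, which makes unlabeled trees of different
    # shapes indistinguishable.
    aggregation: str = "gcn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim < 1 or self.embedding_dim < 1:
            raise ValueError("hidden_dim and embedding_dim must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.aggregation not in ("gcn", "mean"):
            raise ValueError("aggregation must be 'gcn' or 'mean'")


@dataclass
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-3
    trees_per_batch: int = 64
    optimizer: str = "adam"
    seed: int = 0
    distance_normalized: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.trees_per_batch < 2:
            raise ValueError("trees_per_batch must be >= 2")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


class ModelParams:
    """Flat mapping name -> ndarray of all learnable tensors and BN stats."""

    TRAINABLE = (
        "W1", "b1", "bn1_gamma", "bn1_beta",
        "W2", "b2", "bn2_gamma", "bn2_beta",
        "W", "b",
    )
    HEAD = ("head_w", "head_b")

    def __init__(self, tensors: Dict[str, np.ndarray]):
        self.tensors = {k: np.asarray(v, dtype=np.float64) for k, v in tensors.items()}

    def __getitem__(self, key: str) -> np.ndarray:
        return self.tensors[key]

    def __setitem__(self, key: str, value: np.ndarray) -> None:
        self.tensors[key] = np.asarray(value, dtype=np.float64)

    def __contains__(self, key: str) -> bool:
        return key in self.tensors

    @property
    def has_head(self) -> bool:
        return "head_w" in self.tensors

    def trainable_names(self, include_head: bool = False) -> List[str]:
        names = [n for n in self.TRAINABLE]
        if include_head and self.has_head:
            names += list(self.HEAD)
        return names

    def copy(self) -> "ModelParams":
        return ModelParams({k: v.copy() for k, v in self.tensors.items()})


@dataclass
class Embedding:
    vector: np.ndarray
    tree_id: str = ""

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding has non-finite entries")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(
    config: ModelConfig,
    rng: Optional[np.random.Generator] = None,
    with_head: bool = False,
) -> ModelParams:
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d, p, q = config.input_dim, config.hidden_dim, config.embedding_dim
    tensors = {
        "W1": _glorot(rng, d, p),
        "b1": np.zeros(p),
        "bn1_gamma": np.ones(p),
        "bn1_beta": np.zeros(p),
        "bn1_mean": np.zeros(p),
        "bn1_var": np.ones(p),
        "W2": _glorot(rng, p, p),
        "b2": np.zeros(p),
        "bn2_gamma": np.ones(p),
        "bn2_beta": np.zeros(p),
        "bn2_mean": np.zeros(p),
        "bn2_var": np.ones(p),
        "W": _glorot(rng, p, q).T,  # stored (q, p)
        "b": np.zeros(q),
    }
    if with_head:
        tensors["head_w"] = _glorot(rng, q, 1).ravel()
        tensors["head_b"] = np.zeros(1)
    return ModelParams(tensors)


# ---------------------------------------------------------------------------
# Graph batching
# ---------------------------------------------------------------------------


def _propagation_matrix(encoded: Sequence[EncodedTree], config: ModelConfig) -> sp.csr_matrix:
    """Block-diagonal propagation matrix for a batch of trees."""
    rows: List[int] = []
    cols: List[int] = []
    offset = 0
    n_total = sum(e.n_nodes for e in encoded)
    for e in encoded:
        n = e.n_nodes
        for i in range(n):  # self-loops
            rows.append(offset + i)
            cols.append(offset + i)
        for u, v in e.edges:
            rows.append(offset + v)
            cols.append(offset + u)
            if config.undirected_messages:
                rows.append(offset + u)
                cols.append(offset + v)
        offset += n
    data = np.ones(len(rows))
    A = sp.csr_matrix((data, (rows, cols)), shape=(n_total, n_total))
    deg = np.asarray(A.sum(axis=1)).ravel()
    if config.aggregation == "gcn":
        dinv = 1.0 / np.sqrt(deg)
        A = sp.diags(dinv) @ A @ sp.diags(dinv)
    else:  # mean over self + in-neighborhood
        A = sp.diags(1.0 / deg) @ A
    return sp.csr_matrix(A)


def _batch_arrays(
    encoded: Sequence[EncodedTree], config: ModelConfig
) -> Tuple[np.ndarray, sp.csr_matrix, np.ndarray]:
    X = np.concatenate([e.encoding.matrix for e in encoded]).astype(np.float64)
    if X.shape[1] != config.input_dim:
        raise ValueError(
            f"encoding width {X.shape[1]} != configured input_dim {config.input_dim}"
        )
    A = _propagation_matrix(encoded, config)
    seg = np.concatenate(
        [np.full(e.n_nodes, i, dtype=np.int64) for i, e in enumerate(encoded)]
    )
    return X, A, seg


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------


def _bn_forward(x, gamma, beta, run_mean, run_var, training, update=None):
    if training:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        if update is not None:
            update[0] *= 1 - _BN_MOMENTUM
            update[0] += _BN_MOMENTUM * mu
            n = x.shape[0]
            unbiased = var * n / max(n - 1, 1)
            update[1] *= 1 - _BN_MOMENTUM
            update[1] += _BN_MOMENTUM * unbiased
    else:
        mu, var = run_mean, run_var
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mu) * inv_std
    return gamma * xhat + beta, (xhat, inv_std)


def _bn_backward(dy, gamma, cache, training):
    xhat, inv_std = cache
    dgamma = (dy * xhat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    if training:
        dx = (gamma * inv_std) * (
            dy - dy.mean(axis=0) - xhat * (dy * xhat).mean(axis=0)
        )
    else:
        dx = dy * gamma * inv_std
    return dx, dgamma, dbeta


def _forward_batch(
    params: ModelParams,
    config: ModelConfig,
    X: np.ndarray,
    A: sp.csr_matrix,
    seg: np.ndarray,
    training: bool,
    rng: Optional[np.random.Generator] = None,
):
    """Batched forward pass; returns embeddings (B x q) and a backprop cache."""
    t = params.tensors
    n_trees = int(seg.max()) + 1 if seg.size else 0
    counts = np.bincount(seg, minlength=n_trees).astype(np.float64)

    S1 = A @ X
    Z1 = S1 @ t["W1"] + t["b1"]
    upd1 = [t["bn1_mean"], t["bn1_var"]] if training else None
    Y1, bn1_cache = _bn_forward(
        Z1, t["bn1_gamma"], t["bn1_beta"], t["bn1_mean"], t["bn1_var"], training, upd1
    )
    H1 = np.maximum(Y1, 0.0)

    if training and config.dropout_rate > 0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        mask1 = (rng.random(H1.shape) >= config.dropout_rate) / (
            1 - config.dropout_rate
        )
    else:
        mask1 = None
    D1 = H1 * mask1 if mask1 is not None else H1

    S2 = A @ D1
    Z2 = S2 @ t["W2"] + t["b2"]
    upd2 = [t["bn2_mean"], t["bn2_var"]] if training else None
    Y2, bn2_cache = _bn_forward(
        Z2, t["bn2_gamma"], t["bn2_beta"], t["bn2_mean"], t["bn2_var"], training, upd2
    )
    H2 = np.maximum(Y2, 0.0)

    # average pooling per tree
    P = np.zeros((n_trees, H2.shape[1]))
    np.add.at(P, seg, H2)
    P /= counts[:, None]

    if training and config.dropout_rate > 0:
        mask2 = (rng.random(P.shape) >= config.dropout_rate) / (1 - config.dropout_rate)
    else:
        mask2 = None
    D2 = P * mask2 if mask2 is not None else P

    Z = D2 @ t["W"].T + t["b"]
    cache = {
        "X": X, "A": A, "seg": seg, "counts": counts,
        "S1": S1, "bn1": bn1_cache, "Y1": Y1, "mask1": mask1,
        "S2": S2, "bn2": bn2_cache, "Y2": Y2,
        "D2": D2, "mask2": mask2, "training": training,
    }
    return Z, cache


def _backward_batch(
    params: ModelParams, config: ModelConfig, dZ: np.ndarray, cache
) -> Dict[str, np.ndarray]:
    t = params.tensors
    grads: Dict[str, np.ndarray] = {}
    training = cache["training"]

    grads["W"] = dZ.T @ cache["D2"]
    grads["b"] = dZ.sum(axis=0)
    dD2 = dZ @ t["W"]
    dP = dD2 * cache["mask2"] if cache["mask2"] is not None else dD2

    dH2 = dP[cache["seg"]] / cache["counts"][cache["seg"], None]
    dY2 = dH2 * (cache["Y2"] > 0)
    dZ2, grads["bn2_gamma"], grads["bn2_beta"] = _bn_backward(
        dY2, t["bn2_gamma"], cache["bn2"], training
    )
    grads["W2"] = cache["S2"].T @ dZ2
    grads["b2"] = dZ2.sum(axis=0)
    dS2 = dZ2 @ t["W2"].T
    dD1 = cache["A"].T @ dS2
    dH1 = dD1 * cache["mask1"] if cache["mask1"] is not None else dD1
    dY1 = dH1 * (cache["Y1"] > 0)
    dZ1, grads["bn1_gamma"], grads["bn1_beta"] = _bn_backward(
        dY1, t["bn1_gamma"], cache["bn1"], training
    )
    grads["W1"] = cache["S1"].T @ dZ1
    grads["b1"] = dZ1.sum(axis=0)
    return grads


def forward(
    params: ModelParams,
    config: ModelConfig,
    encoded: EncodedTree,
    training_mode: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Embedding:
    """Embed one encoded tree (evaluation mode unless stated otherwise)."""
    X, A, seg = _batch_arrays([encoded], config)
    Z, _ = _forward_batch(params, config, X, A, seg, training_mode, rng)
    return Embedding(vector=Z[0], tree_id=encoded.tree_id)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def pair_loss(z_i: Embedding | np.ndarray, z_j: Embedding | np.ndarray, d_ij: float) -> float:
    """|d_ij - ||z_i - z_j||_2|, the per-pair distance-matching loss."""
    vi = z_i.vector if isinstance(z_i, Embedding) else np.asarray(z_i, dtype=float)
    vj = z_j.vector if isinstance(z_j, Embedding) else np.asarray(z_j, dtype=float)
    if vi.shape != vj.shape:
        raise ValueError("embedding dimension mismatch")
    if d_ij < 0:
        raise ValueError("distance must be non-negative")
    return float(abs(d_ij - np.linalg.norm(vi - vj)))


def dataset_loss(embeddings: Sequence[Embedding], dmatrix: DistanceMatrix) -> float:
    """Mean pair loss over all unordered pairs."""
    n = len(embeddings)
    if n < 2:
        raise ValueError("need at least two trees")
    if n != len(dmatrix.labels):
        raise ValueError("embeddings not aligned with distance matrix")
    Z = np.stack([e.vector for e in embeddings])
    loss, _ = _pairwise_loss_and_grad(Z, dmatrix.values)
    return loss


def _pairwise_loss_and_grad(Z: np.ndarray, D: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean |D_ij - ||z_i - z_j||| over i<j, and its (sub)gradient wrt Z."""
    n = Z.shape[0]
    diff = Z[:, None, :] - Z[None, :, :]
    norms = np.sqrt((diff ** 2).sum(axis=2))
    err = D - norms
    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])
    loss = float(np.abs(err[iu]).mean())
    # d|err|/dz_i = -sign(err_ij) * (z_i - z_j)/norm_ij  (0 where norm is 0)
    sign = np.sign(err)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(norms[:, :, None] > 0, diff / norms[:, :, None], 0.0)
    coeff = -sign[:, :, None] * unit
    np.fill_diagonal(coeff[:, :, 0], 0.0)
    dZ = coeff.sum(axis=1) / n_pairs  # both (i,j) and (j,i) contribute to z_i
    return loss, dZ


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, names, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {n: None for n in names}
        self.v = {n: None for n in names}
        self.t = 0

    def step(self, params: ModelParams, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        for name in self.m:
            g = grads.get(name)
            if g is None:
                continue
            if self.m[name] is None:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g ** 2
            mhat = self.m[name] / (1 - self.b1 ** self.t)
            vhat = self.v[name] / (1 - self.b2 ** self.t)
            params[name] = params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, names, lr):
        self.lr = lr
        self.names = names

    def step(self, params, grads):
        for name in self.names:
            g = grads.get(name)
            if g is not None:
                params[name] = params[name] - self.lr * g


def _make_optimizer(train_cfg: TrainConfig, names):
    if train_cfg.optimizer == "adam":
        return _Adam(names, train_cfg.learning_rate)
    return _SGD(names, train_cfg.learning_rate)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_unsupervised(
    dataset: TreeDataset,
    vocab: AlterationVocabulary,
    model_cfg: Optional[ModelConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    dmatrix: Optional[DistanceMatrix] = None,
) -> Tuple[ModelParams, Dict[str, list]]:
    """Fit the embedding network by matching pairwise tree distances.

    Every tree of every patient enters training independently.  Returns the
    trained parameters and a log with the per-epoch mean batch loss.
    """
    train_cfg = train_cfg or TrainConfig()
    trees = dataset.all_trees()
    labels = dataset.tree_labels()
    if len(trees) < 2:
        raise ValueError("need at least two trees to train")
    if model_cfg is None:
        model_cfg = ModelConfig(input_dim=vocab.m + 2, seed=train_cfg.seed)
    if dmatrix is None:
        dmatrix = pairwise_distance_matrix(
            trees, normalized=train_cfg.distance_normalized, labels=labels, vocab=vocab
        )
    D = dmatrix.values

    encoded = encode_dataset(trees, vocab, labels)
    rng = np.random.default_rng(train_cfg.seed)
    params = init_params(model_cfg, rng)
    opt = _make_optimizer(train_cfg, params.trainable_names())

    n = len(trees)
    B = min(train_cfg.trees_per_batch, n)
    log: Dict[str, list] = {"epoch_loss": []}
    for _epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, B):
            idx = order[start : start + B]
            if len(idx) < 2:
                continue
            batch = [encoded[i] for i in idx]
            X, A, seg = _batch_arrays(batch, model_cfg)
            Z, cache = _forward_batch(params, model_cfg, X, A, seg, True, rng)
            loss, dZ = _pairwise_loss_and_grad(Z, D[np.ix_(idx, idx)])
            grads = _backward_batch(params, model_cfg, dZ, cache)
            opt.step(params, grads)
            losses.append(loss)
        log["epoch_loss"].append(float(np.mean(losses)))
    return params, log


def embed(
    params: ModelParams,
    config: ModelConfig,
    tree: PhyloTree,
    vocab: AlterationVocabulary,
) -> Embedding:
    """Evaluation-mode embedding of one (possibly unseen) tree."""
    tid = tree.patient_id or ""
    return forward(params, config, encode_tree(tree, vocab, tid), training_mode=False)


def embed_trees(
    params: ModelParams,
    config: ModelConfig,
    trees: Sequence[PhyloTree],
    vocab: AlterationVocabulary,
    tree_ids: Optional[Sequence[str]] = None,
) -> List[Embedding]:
    encoded = encode_dataset(trees, vocab, tree_ids)
    X, A, seg = _batch_arrays(encoded, config)
    Z, _ = _forward_batch(params, config, X, A, seg, training=False)
    return [Embedding(vector=z, tree_id=e.tree_id) for z, e in zip(Z, encoded)]


def patient_embeddings(
    params: ModelParams,
    config: ModelConfig,
    dataset: TreeDataset,
    vocab: AlterationVocabulary,
) -> List[Embedding]:
    """One embedding per patient: the mean over the patient's trees."""
    out = []
    for p in dataset.patients:
        vecs = [embed(params, config, t, vocab).vector for t in p.trees]
        out.append(Embedding(vector=np.mean(vecs, axis=0), tree_id=p.patient_id))
    return out


# ---------------------------------------------------------------------------
# Supervised survival variant
# ---------------------------------------------------------------------------


def _ranking_loss_and_grad(scores: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Censoring-aware pairwise hinge: pairs (i,j) with t_i < t_j, event_i=1
    contribute max(0, 1 - (s_i - s_j)); higher score = higher risk."""
    n = len(scores)
    loss = 0.0
    ds = np.zeros(n)
    n_pairs = 0
    for i in range(n):
        if events[i] != 1:
            continue
        later = times > times[i]
        margins = 1.0 - (scores[i] - scores[later])
        active = margins > 0
        n_pairs += int(later.sum())
        loss += float(margins[active].sum())
        ds[i] -= float(active.sum())
        idx = np.where(later)[0][active]
        ds[idx] += 1.0
    if n_pairs == 0:
        return 0.0, ds
    return loss / n_pairs, ds / n_pairs


def train_supervised_survival(
    dataset: TreeDataset,
    vocab: AlterationVocabulary,
    model_cfg: Optional[ModelConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
) -> ModelParams:
    """Train trunk + single-neuron head against (time, event) labels.

    Each tree of a patient enters with its patient's survival pair.
    """
    train_cfg = train_cfg or TrainConfig()
    for p in dataset.patients:
        if p.survival is None:
            raise ValueError(f"patient {p.patient_id} has no survival record")
    trees, times, events = [], [], []
    for p in dataset.patients:
        for t in p.trees:
            trees.append(t)
            times.append(p.survival.time)
            events.append(p.survival.event)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if model_cfg is None:
        model_cfg = ModelConfig(input_dim=vocab.m + 2, seed=train_cfg.seed)

    encoded = encode_dataset(trees, vocab)
    rng = np.random.default_rng(train_cfg.seed)
    params = init_params(model_cfg, rng, with_head=True)
    opt = _make_optimizer(train_cfg, params.trainable_names(include_head=True))

    n = len(trees)
    B = min(train_cfg.trees_per_batch, n)
    for _epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, B):
            idx = order[start : start + B]
            if len(idx) < 2:
                continue
            batch = [encoded[i] for i in idx]
            X, A, seg = _batch_arrays(batch, model_cfg)
            Z, cache = _forward_batch(params, model_cfg, X, A, seg, True, rng)
            scores = Z @ params["head_w"] + params["head_b"][0]
            _, ds = _ranking_loss_and_grad(scores, times[idx], events[idx])
            dZ = ds[:, None] * params["head_w"][None, :]
            grads = _backward_batch(params, model_cfg, dZ, cache)
            grads["head_w"] = Z.T @ ds
            grads["head_b"] = np.array([ds.sum()])
            opt.step(params, grads)
    return params


def predict_survival_score(
    params: ModelParams,
    config: ModelConfig,
    tree: PhyloTree,
    vocab: AlterationVocabulary,
) -> float:
    """Scalar risk score (higher = shorter predicted survival)."""
    if not params.has_head:
        raise ValueError("model has no survival head")
    z = embed(params, config, tree, vocab)
    return float(z.vector @ params["head_w"] + params["head_b"][0])


# ---------------------------------------------------------------------------
# Checkpointing (JSON; text-only on purpose)
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_model(
    params: ModelParams,
    config: ModelConfig,
    vocab: AlterationVocabulary,
    directory: str,
) -> None:
    os.makedirs(directory, exist_ok=True)
    payload = {
        "version": _CHECKPOINT_VERSION,
        "config": asdict(config),
        "tensors": {k: v.tolist() for k, v in params.tensors.items()},
    }
    with open(os.path.join(directory, "model.json"), "w") as fh:
        json.dump(payload, fh)
    with open(os.path.join(directory, "vocab.tsv"), "w") as fh:
        fh.write(vocab.to_tsv())


def load_model(directory: str) -> Tuple[ModelParams, ModelConfig, AlterationVocabulary]:
    with open(os.path.join(directory, "model.json")) as fh:
        payload = json.load(fh)
    if payload.get("version") != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {payload.get('version')}")
    config = ModelConfig(**payload["config"])
    params = ModelParams({k: np.array(v) for k, v in payload["tensors"].items()})
    with open(os.path.join(directory, "vocab.tsv")) as fh:
        vocab = AlterationVocabulary.from_tsv(fh.read())
    return params, config, vocab
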