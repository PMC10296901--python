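"""Graph-convolutional autoencoder for bipartite link prediction.

Encoder: two graph-convolution layers with the symmetric normalisation of
Kipf & Welling, Â = D̃^(−1/2)(A + I)D̃^(−1/2), a ReLU + dropout between the
layers, and identity input features (the network carries no node
attributes, so layer 1 acts as a free per-node embedding table):

    Z = Â · dropout(ReLU(Â · W1)) · W2

Decoder: inner product — the probability that gene i and disease j are
associated is logistic(h_i · h_j).  Training minimises binary cross-entropy
over the training edges plus an equal number of freshly sampled negative
pairs per epoch, with full-batch Adam updates.

Everything is plain numpy/scipy: adjacency and message passing use
scipy.sparse, gradients are derived in closed form, and a fixed seed gives
bitwise-reproducible runs on one thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .edge_split import EdgeSplit, sample_training_negatives
from .errors import ConvergenceError, ValidationError
from .graph_io import BipartiteGraph
from .metrics import ScoredLabels, auc, average_precision

_EPS = 1e-15  # probability clamp for the cross-entropy


@dataclass
class ModelConfig:
    """Hyperparameters of the two-layer convolutional autoencoder.

    feature_size is the embedding dimension (default 50); the hidden layer
    defaults to twice that.  dropout_p follows the standard 0.5, epochs 100.
    """

    feature_size: int = 50
    hidden_size: int | None = None
    dropout_p: float = 0.5
    epochs: int = 100
    learning_rate: float = 0.01
    seed: int = 42
    n_layers: int = 2  # fixed; kept explicit for serialization

    def __post_init__(self) -> None:
        if self.hidden_size is None:
            self.hidden_size = 2 * self.feature_size
        if self.feature_size < 1 or self.hidden_size < 1:
            raise ValidationError("feature_size and hidden_size must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValidationError("dropout_p must lie in [0, 1)")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.n_layers != 2:
            raise ValidationError("architecture is fixed at 2 convolutional layers")

    def to_dict(self) -> dict:
        return {
            "feature_size": self.feature_size,
            "hidden_size": self.hidden_size,
            "dropout_p": self.dropout_p,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "n_layers": self.n_layers,
        }


@dataclass
class ModelWeights:
    """Learned layer matrices: W1 (n × hidden), W2 (hidden × feature)."""

    W1: np.ndarray
    W2: np.ndarray

    def validate(self, n_nodes: int, config: ModelConfig) -> None:
        if self.W1.shape != (n_nodes, config.hidden_size):
            raise ValidationError(f"W1 shape {self.W1.shape} mismatches config")
        if self.W2.shape != (config.hidden_size, config.feature_size):
            raise ValidationError(f"W2 shape {self.W2.shape} mismatches config")
        if not (np.isfinite(self.W1).all() and np.isfinite(self.W2).all()):
            raise ValidationError("non-finite weight entries")


@dataclass
class TrainingHistory:
    """Per-epoch loss and validation metrics, plus final test metrics."""

    loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    val_ap: list[float] = field(default_factory=list)
    test_auc: float = float("nan")
    test_ap: float = float("nan")

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("epoch\tloss\tval_auc\tval_ap\n")
            for e, (l, a, p) in enumerate(zip(self.loss, self.val_auc, self.val_ap), 1):
                fh.write(f"{e}\t{l!r}\t{a!r}\t{p!r}\n")


def relu(x: np.ndarray) -> np.ndarray:
    """Pointwise rectifier max(0, x)."""
    return np.maximum(x, 0.0)


def dropout(
    x: np.ndarray,
    p: float,
    training: bool,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Inverted dropout: zero elements w.p. p, scale survivors by 1/(1−p).

    Identity at inference time or at p = 0; E[dropout(x)] = x during
    training, so activations keep their scale.
    """
    if not 0.0 <= p < 1.0:
        raise ValidationError("dropout probability must lie in [0, 1)")
    if not training or p == 0.0:
        return x
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mask = rng.random(x.shape) >= p
    return x * (mask / (1.0 - p))


def normalize_adjacency(
    graph: BipartiteGraph, train_edges: np.ndarray | None = None
) -> sp.csr_matrix:
    """Symmetric-normalised adjacency with self-loops, Â = D̃^(−1/2)(A+I)D̃^(−1/2).

    Built from ``train_edges`` only (defaults to all edges), so held-out
    associations never enter message passing.  Entry (i, j) is
    w_ij / sqrt(d̃_i · d̃_j) with d̃ the degree of A + I; an isolated node
    reduces to Â[i, i] = 1.
    """
    n = graph.n
    if train_edges is None:
        edges, weights = graph.edges, graph.weights
    else:
        edges = np.asarray(train_edges, dtype=np.int64).reshape(-1, 2)
        key_to_w = dict(zip(map(tuple, graph.edges.tolist()), graph.weights))
        try:
            weights = np.array([key_to_w[tuple(e)] for e in edges.tolist()])
        except KeyError as exc:
            raise ValidationError(f"train edge {exc} not present in graph") from exc

    rows = np.r_[edges[:, 0], edges[:, 1], np.arange(n)]
    cols = np.r_[edges[:, 1], edges[:, 0], np.arange(n)]
    vals = np.r_[weights, weights, np.ones(n)]
    a_tilde = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    return sp.diags(inv_sqrt) @ a_tilde @ sp.diags(inv_sqrt)


def init_weights(n_nodes: int, config: ModelConfig, rng: np.random.Generator) -> ModelWeights:
    """Glorot-uniform initialisation of both layer matrices."""

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return ModelWeights(
        W1=glorot(n_nodes, config.hidden_size),
        W2=glorot(config.hidden_size, config.feature_size),
    )


def encode(
    a_hat: sp.csr_matrix,
    weights: ModelWeights,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Forward pass: Z = Â · dropout(ReLU(Â · W1)) · W2.

    Input features are the identity, so Â·X·W1 collapses to Â·W1.  With
    ``training=False`` (dropout off) this is a pure function of the weights.
    When ``return_cache`` is set, the intermediates needed for closed-form
    backprop are returned alongside Z.
    """
    if a_hat.shape[0] != weights.W1.shape[0]:
        raise ValidationError(
            f"adjacency ({a_hat.shape[0]} nodes) mismatches W1 {weights.W1.shape}"
        )
    s = a_hat @ weights.W1  # layer-1 pre-activation
    h = relu(s)
    if training and config.dropout_p > 0.0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        keep = rng.random(h.shape) >= config.dropout_p
        scale = keep / (1.0 - config.dropout_p)
    else:
        scale = None
    h_drop = h if scale is None else h * scale
    msg = a_hat @ h_drop
    z = msg @ weights.W2
    if return_cache:
        return z, {"s": s, "scale": scale, "h_drop": h_drop, "msg": msg}
    return z


def decode_pair(z: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Raw dot-product score and logistic probability for one node pair."""
    n = z.shape[0]
    if not (0 <= i < n and 0 <= j < n):
        raise ValidationError(f"node index out of range: ({i}, {j}) with n={n}")
    if i == j:
        raise ValidationError("decode_pair requires two distinct nodes")
    raw = float(z[i] @ z[j])
    return raw, float(1.0 / (1.0 + np.exp(-raw)))


def decode_pairs(z: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Raw dot products for an array of index pairs (batched einsum)."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return np.einsum("ij,ij->i", z[pairs[:, 0]], z[pairs[:, 1]])


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def reconstruction_loss(
    z: np.ndarray, pos_edges: np.ndarray, neg_edges: np.ndarray
) -> float:
    """Binary cross-entropy between the observed and reconstructed adjacency.

    −mean log p over positive pairs − mean log(1−p) over negative pairs,
    probabilities clamped to [1e−15, 1−1e−15].
    """
    if len(pos_edges) == 0 or len(neg_edges) == 0:
        raise ValidationError("loss needs non-empty positive and negative sets")
    p_pos = np.clip(sigmoid(decode_pairs(z, pos_edges)), _EPS, 1 - _EPS)
    p_neg = np.clip(sigmoid(decode_pairs(z, neg_edges)), _EPS, 1 - _EPS)
    return float(-np.mean(np.log(p_pos)) - np.mean(np.log(1.0 - p_neg)))


def _loss_grad_z(
    z: np.ndarray, pos_edges: np.ndarray, neg_edges: np.ndarray
) -> np.ndarray:
    """dL/dZ for the BCE loss; accumulates (p − y)/batch · h_partner per pair."""
    grad = np.zeros_like(z)
    for pairs, y in ((pos_edges, 1.0), (neg_edges, 0.0)):
        p = sigmoid(decode_pairs(z, pairs))
        coef = (p - y) / len(pairs)
        np.add.at(grad, pairs[:, 0], coef[:, None] * z[pairs[:, 1]])
        np.add.at(grad, pairs[:, 1], coef[:, None] * z[pairs[:, 0]])
    return grad


class _Adam:
    """Standard Adam with bias correction (β1=0.9, β2=0.999, ε=1e−8)."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    graph: BipartiteGraph,
    split: EdgeSplit,
    config: ModelConfig | None = None,
) -> tuple[ModelWeights, np.ndarray, TrainingHistory]:
    """Train the autoencoder; return weights, final embeddings, history.

    Each epoch does a full-batch forward pass with dropout, computes the
    cross-entropy on the training edges plus an equal number of freshly
    sampled negatives, applies one Adam update, and records validation
    AUC/AP (dropout off).  Final embeddings and test metrics use the
    trained weights with dropout off.
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(config.seed)
    neg_rng = np.random.default_rng(rng.integers(2**31))
    a_hat = normalize_adjacency(graph, split.train_pos)
    weights = init_weights(graph.n, config, rng)
    opt = _Adam([weights.W1, weights.W2], config.learning_rate)
    history = TrainingHistory()

    val_pairs = np.vstack([split.val_pos, split.val_neg]) if len(split.val_pos) else None
    if val_pairs is not None:
        val_labels = np.r_[
            np.ones(len(split.val_pos), dtype=int),
            np.zeros(len(split.val_neg), dtype=int),
        ]

    for _ in range(config.epochs):
        neg = sample_training_negatives(graph, split, len(split.train_pos), neg_rng)
        z, cache = encode(
            a_hat, weights, config, training=True, rng=rng, return_cache=True
        )
        loss = reconstruction_loss(z, split.train_pos, neg)
        if not np.isfinite(loss):
            raise ConvergenceError(
                f"non-finite loss at epoch {len(history.loss) + 1}: {loss}"
            )

        # closed-form backprop through Z = Â·H·W2, H = drop(relu(Â·W1))
        g_z = _loss_grad_z(z, split.train_pos, neg)
        g_w2 = cache["msg"].T @ g_z
        g_h = a_hat @ (g_z @ weights.W2.T)  # Â symmetric
        if cache["scale"] is not None:
            g_h = g_h * cache["scale"]
        g_s = g_h * (cache["s"] > 0)
        g_w1 = a_hat @ g_s

        opt.step([weights.W1, weights.W2], [g_w1, g_w2])

        history.loss.append(loss)
        if val_pairs is not None:
            z_eval = encode(a_hat, weights, config, training=False)
            scored = ScoredLabels(decode_pairs(z_eval, val_pairs), val_labels)
            history.val_auc.append(auc(scored))
            history.val_ap.append(average_precision(scored))
        else:
            history.val_auc.append(float("nan"))
            history.val_ap.append(float("nan"))

    z_final = encode(a_hat, weights, config, training=False)
    if len(split.test_pos):
        test_pairs = np.vstack([split.test_pos, split.test_neg])
        test_labels = np.r_[
            np.ones(len(split.test_pos), dtype=int),
            np.zeros(len(split.test_neg), dtype=int),
        ]
        scored = ScoredLabels(decode_pairs(z_final, test_pairs), test_labels)
        history.test_auc = auc(scored)
        history.test_ap = average_precision(scored)
    return weights, z_final, history


def save_model(
    weights: ModelWeights,
    embeddings: np.ndarray,
    config: ModelConfig,
    graph: BipartiteGraph,
    outdir: str | Path,
) -> None:
    """Arrays to .npz with a JSON sidecar (config + node-index hash)."""
    import hashlib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez(outdir / "model.npz", W1=weights.W1, W2=weights.W2, Z=embeddings)
    node_hash = hashlib.sha256("\n".join(graph.node_ids).encode()).hexdigest()
    sidecar = {"config": config.to_dict(), "node_index_sha256": node_hash}
    (outdir / "model.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_model(outdir: str | Path) -> tuple[ModelWeights, np.ndarray, dict]:
    outdir = Path(outdir)
    arrays = np.load(outdir / "model.npz")
    sidecar = json.loads((outdir / "model.json").read_text())
    return (
        ModelWeights(W1=arrays["W1"], W2=arrays["W2"]),
        arrays["Z"],
        sidecar,
    )
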