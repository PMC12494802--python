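"""Graph autoencoder: two-layer GCN encoder with an inner-product decoder.

Default encoder stack: ``P @ X @ W1 + b1`` -> layer norm -> ReLU ->
dropout (p = 0.1, train mode only) -> ``P @ H @ W2 + b2`` -> linear
64-dimensional embeddings.  The decoder scores a directed pair (i, j) as
``sigmoid(z_i . z_j)``; training minimizes mean binary cross-entropy over
the train positives plus an equal number of freshly resampled negatives
per epoch, with Adam (lr 0.01, weight decay 5e-4 on the weight matrices,
100 full-batch epochs) and early stopping on validation loss (patience 10).

Normalizing the hidden layer pre-activation while leaving the output
layer linear is deliberate: output-side normalization equalizes node
norms (destroying the norm/centrality alignment this model is evaluated
on), and an output ReLU lets entire nodes die irrecoverably, capping
reconstruction AUC far below what this architecture otherwise reaches.
Both alternatives remain available through ``GAEConfig`` flags
(``output_layer_norm``, ``output_relu``, ``layer_norm_position``).

Everything is plain NumPy with hand-written exact gradients; the test
suite checks them against central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    Adam,
    dropout_forward,
    glorot_uniform,
    layer_norm_backward,
    layer_norm_forward,
    relu,
    sigmoid,
)
from .graph_prep import EdgeSplit, sample_negative_edges
from .regnet_io import RegulatoryGraph

__all__ = [
    "GAEConfig",
    "EmbeddingMatrix",
    "TrainingHistory",
    "init_params",
    "gcn_layer",
    "encode",
    "decode_edges",
    "bce_loss",
    "train_gae",
]

_CLIP = 1e-12


@dataclass
class GAEConfig:
    hidden_dim: int = 128
    embed_dim: int = 64
    dropout: float = 0.1
    lr: float = 0.01
    weight_decay: float = 5e-4
    epochs: int = 100
    patience: int = 10
    hidden_layer_norm: bool = True
    output_layer_norm: bool = False
    output_relu: bool = False
    layer_norm_position: str = "pre_activation"  # or "post_activation"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layer_norm_position not in ("pre_activation", "post_activation"):
            raise ValueError(f"bad layer_norm_position: {self.layer_norm_position!r}")


@dataclass
class EmbeddingMatrix:
    """n_nodes x d embedding, row order = graph node order."""

    values: np.ndarray
    model_tag: str  # "GAE" | "GAN" | "QUANTUM"

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


def init_params(input_dim: int, config: GAEConfig) -> dict[str, np.ndarray]:
    """Seeded Glorot-uniform weights; unit/zero layer-norm gain/shift."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6AE1]))
    return {
        "W1": glorot_uniform(rng, input_dim, config.hidden_dim),
        "b1": np.zeros(config.hidden_dim),
        "g1": np.ones(config.hidden_dim),
        "s1": np.zeros(config.hidden_dim),
        "W2": glorot_uniform(rng, config.hidden_dim, config.embed_dim),
        "b2": np.zeros(config.embed_dim),
        "g2": np.ones(config.embed_dim),
        "s2": np.zeros(config.embed_dim),
    }


def gcn_layer(
    h: np.ndarray,
    p: np.ndarray,
    w: np.ndarray,
    bias: np.ndarray,
    gain: np.ndarray | None = None,
    shift: np.ndarray | None = None,
    norm: bool = True,
    norm_position: str = "pre_activation",
    activation: bool = True,
) -> np.ndarray:
    """One GCN layer: propagate, optionally layer-normalize, optionally ReLU.

    ``norm_position`` selects whether normalization wraps the
    pre-activation (default) or the activated output.
    """
    if gain is None:
        gain = np.ones(w.shape[1])
    if shift is None:
        shift = np.zeros(w.shape[1])
    out = p @ h @ w + bias
    if norm and norm_position == "pre_activation":
        out, _ = layer_norm_forward(out, gain, shift)
    if activation:
        out = relu(out)
    if norm and norm_position == "post_activation":
        out, _ = layer_norm_forward(out, gain, shift)
    return out


def _forward(params, p, x, config: GAEConfig, train: bool,
             rng: np.random.Generator | None = None):
    """Full encoder forward; returns (z, cache) with cache for backprop."""
    pre_norm = config.layer_norm_position == "pre_activation"
    pre1 = p @ x @ params["W1"] + params["b1"]
    if config.hidden_layer_norm and pre_norm:
        n1, ln1_cache = layer_norm_forward(pre1, params["g1"], params["s1"])
    else:
        n1, ln1_cache = pre1, None
    a1 = relu(n1)
    if config.hidden_layer_norm and not pre_norm:
        h1_base, ln1_cache = layer_norm_forward(a1, params["g1"], params["s1"])
    else:
        h1_base = a1
    if train and config.dropout > 0:
        if rng is None:
            raise ValueError("train-mode forward needs an rng for dropout")
        h1, mask = dropout_forward(h1_base, config.dropout, rng)
    else:
        h1, mask = h1_base, None
    ph1 = p @ h1
    pre2 = ph1 @ params["W2"] + params["b2"]
    if config.output_layer_norm and pre_norm:
        n2, ln2_cache = layer_norm_forward(pre2, params["g2"], params["s2"])
    else:
        n2, ln2_cache = pre2, None
    a2 = relu(n2) if config.output_relu else n2
    if config.output_layer_norm and not pre_norm:
        z, ln2_cache = layer_norm_forward(a2, params["g2"], params["s2"])
    else:
        z = a2
    cache = (pre1, n1, ln1_cache, a1, mask, ph1, n2, ln2_cache, a2)
    return z, cache


def _backward(dz, params, p, x, cache, config: GAEConfig):
    """Exact parameter gradients given dLoss/dZ (mirrors ``_forward``)."""
    pre_norm = config.layer_norm_position == "pre_activation"
    pre1, n1, ln1_cache, a1, mask, ph1, n2, ln2_cache, a2 = cache
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    d = dz
    if config.output_layer_norm and not pre_norm:
        d, grads["g2"], grads["s2"] = layer_norm_backward(d, ln2_cache)
    if config.output_relu:
        d = d * (n2 > 0)
    if config.output_layer_norm and pre_norm:
        d, grads["g2"], grads["s2"] = layer_norm_backward(d, ln2_cache)
    grads["W2"] = ph1.T @ d
    grads["b2"] = d.sum(axis=0)
    d = p.T @ (d @ params["W2"].T)
    if mask is not None:
        d = d * mask
    if config.hidden_layer_norm and not pre_norm:
        d, grads["g1"], grads["s1"] = layer_norm_backward(d, ln1_cache)
    d = d * (n1 > 0)
    if config.hidden_layer_norm and pre_norm:
        d, grads["g1"], grads["s1"] = layer_norm_backward(d, ln1_cache)
    grads["W1"] = (p @ x).T @ d
    grads["b1"] = d.sum(axis=0)
    return grads


def encode(params, features: np.ndarray, p: np.ndarray,
           config: GAEConfig | None = None, mode: str = "eval",
           rng: np.random.Generator | None = None) -> EmbeddingMatrix:
    """Run the encoder; ``eval`` mode is deterministic (no dropout)."""
    config = config or GAEConfig(hidden_dim=params["W1"].shape[1],
                                 embed_dim=params["W2"].shape[1])
    for key, value in params.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"non-finite parameter {key}")
    z, _ = _forward(params, p, features, config, train=(mode == "train"), rng=rng)
    return EmbeddingMatrix(values=z, model_tag="GAE")


def decode_edges(z: np.ndarray | EmbeddingMatrix, pairs) -> np.ndarray:
    """sigmoid(z_i . z_j) per (i, j) pair."""
    values = z.values if isinstance(z, EmbeddingMatrix) else z
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        return np.zeros(0)
    if pairs.max() >= values.shape[0] or pairs.min() < 0:
        raise IndexError("edge index out of range")
    logits = np.einsum("ij,ij->i", values[pairs[:, 0]], values[pairs[:, 1]])
    return sigmoid(logits)


def bce_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy with epsilon clipping at 1e-12."""
    s = np.clip(np.asarray(scores, dtype=float), _CLIP, 1.0 - _CLIP)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    return float(-np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))


def _loss_and_dz(z: np.ndarray, pairs: np.ndarray, labels: np.ndarray):
    """BCE over decoded pairs and its exact gradient with respect to z."""
    scores = decode_edges(z, pairs)
    loss = bce_loss(scores, labels)
    coeff = (scores - labels) / len(labels)  # d(mean BCE)/d(logit)
    dz = np.zeros_like(z)
    np.add.at(dz, pairs[:, 0], coeff[:, None] * z[pairs[:, 1]])
    np.add.at(dz, pairs[:, 1], coeff[:, None] * z[pairs[:, 0]])
    return loss, dz


def _eval_loss(params, p, x, config, pairs, labels) -> float:
    z, _ = _forward(params, p, x, config, train=False)
    return bce_loss(decode_edges(z, pairs), labels)


def train_gae(
    graph: RegulatoryGraph,
    features: np.ndarray,
    split: EdgeSplit,
    config: GAEConfig | None = None,
    propagation: np.ndarray | None = None,
) -> tuple[dict, TrainingHistory, EmbeddingMatrix]:
    """Full-batch training with per-epoch negative resampling.

    Returns the best-validation-loss parameters, the per-epoch history,
    and eval-mode embeddings under those parameters.  Deterministic under
    ``config.seed``.
    """
    from .graph_prep import propagation_matrix  # local to avoid cycle at import

    config = config or GAEConfig()
    p = propagation if propagation is not None else propagation_matrix(graph)
    x = features
    params = init_params(x.shape[1], config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6AE2]))
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay,
               decay_keys=("W1", "W2"))

    train_pos = np.asarray(split.train_pos, dtype=int)
    val_pairs = np.asarray(split.val_pos + split.val_neg, dtype=int)
    val_labels = np.concatenate(
        [np.ones(len(split.val_pos)), np.zeros(len(split.val_neg))]
    )

    history = TrainingHistory()
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    since_best = 0

    for epoch in range(config.epochs):
        negs = np.asarray(
            sample_negative_edges(graph, len(train_pos), rng), dtype=int
        )
        pairs = np.concatenate([train_pos, negs], axis=0)
        labels = np.concatenate([np.ones(len(train_pos)), np.zeros(len(negs))])

        z, cache = _forward(params, p, x, config, train=True, rng=rng)
        loss, dz = _loss_and_dz(z, pairs, labels)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training loss diverged at epoch {epoch}")
        grads = _backward(dz, params, p, x, cache, config)
        opt.step(grads)

        val_loss = (
            _eval_loss(params, p, x, config, val_pairs, val_labels)
            if len(val_pairs)
            else loss
        )
        history.train_loss.append(loss)
        history.val_loss.append(val_loss)
        history.stopped_epoch = epoch

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    embeddings = encode(best_params, x, p, config, mode="eval")
    return best_params, history, embeddings
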