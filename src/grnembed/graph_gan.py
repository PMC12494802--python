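"""Adversarial generator/discriminator over the 64-dimensional embedding space.

The generator maps 64-d Gaussian noise through fully connected layers
(128 then 64 hidden units, batch norm + LeakyReLU slope 0.2) to synthetic
64-d embeddings.  The discriminator (hidden 64 then 32, LeakyReLU 0.2,
dropout 0.3) emits one probability.  Training: Adam lr 2e-4 betas
(0.5, 0.999), 100 epochs, batch size 64, binary cross-entropy with
smoothed targets (real 0.9, fake 0.1); one discriminator step then one
generator step per mini-batch.  Real data are trained-autoencoder
embeddings.

Per-node "GAN embeddings" are produced unconditionally and assigned to
nodes by index — the generator has no notion of node identity, so any
downstream link-level score is expected to sit near chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    Adam,
    batch_norm_backward,
    batch_norm_forward,
    dropout_forward,
    glorot_uniform,
    leaky_relu,
    leaky_relu_grad,
    sigmoid,
)
from .gae import EmbeddingMatrix, bce_loss

__all__ = [
    "GANConfig",
    "GANHistory",
    "init_generator",
    "init_discriminator",
    "generator_forward",
    "discriminator_forward",
    "train_gan",
    "generate_node_embeddings",
]

_SLOPE = 0.2
_CLIP = 1e-12


@dataclass
class GANConfig:
    embed_dim: int = 64
    noise_dim: int = 64
    gen_hidden: tuple[int, int] = (128, 64)
    disc_hidden: tuple[int, int] = (64, 32)
    disc_dropout: float = 0.3
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 100
    batch_size: int = 64
    label_smooth: tuple[float, float] = (0.9, 0.1)  # (real target, fake target)
    bn_momentum: float = 0.1
    seed: int = 0


@dataclass
class GANHistory:
    gen_loss: list[float] = field(default_factory=list)
    disc_loss: list[float] = field(default_factory=list)
    real_score: list[float] = field(default_factory=list)
    fake_score: list[float] = field(default_factory=list)


def init_generator(config: GANConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E4]))
    h1, h2 = config.gen_hidden
    return {
        "W1": glorot_uniform(rng, config.noise_dim, h1), "b1": np.zeros(h1),
        "gamma1": np.ones(h1), "beta1": np.zeros(h1),
        "rm1": np.zeros(h1), "rv1": np.ones(h1),
        "W2": glorot_uniform(rng, h1, h2), "b2": np.zeros(h2),
        "gamma2": np.ones(h2), "beta2": np.zeros(h2),
        "rm2": np.zeros(h2), "rv2": np.ones(h2),
        "W3": glorot_uniform(rng, h2, config.embed_dim),
        "b3": np.zeros(config.embed_dim),
    }


def init_discriminator(config: GANConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD15C]))
    h1, h2 = config.disc_hidden
    return {
        "W1": glorot_uniform(rng, config.embed_dim, h1), "b1": np.zeros(h1),
        "W2": glorot_uniform(rng, h1, h2), "b2": np.zeros(h2),
        "W3": glorot_uniform(rng, h2, 1), "b3": np.zeros(1),
    }


def generator_forward(params, noise: np.ndarray, mode: str = "eval",
                      config: GANConfig | None = None, return_cache: bool = False):
    """Noise -> synthetic embeddings.  Train mode uses batch statistics
    (batch >= 2 required) and updates running stats in place; eval mode is
    deterministic given the noise."""
    config = config or GANConfig()
    train = mode == "train"
    pre1 = noise @ params["W1"] + params["b1"]
    bn1, bn1_cache = batch_norm_forward(pre1, params["gamma1"], params["beta1"],
                                        params["rm1"], params["rv1"], train,
                                        config.bn_momentum)
    act1 = leaky_relu(bn1, _SLOPE)
    pre2 = act1 @ params["W2"] + params["b2"]
    bn2, bn2_cache = batch_norm_forward(pre2, params["gamma2"], params["beta2"],
                                        params["rm2"], params["rv2"], train,
                                        config.bn_momentum)
    act2 = leaky_relu(bn2, _SLOPE)
    out = act2 @ params["W3"] + params["b3"]
    if return_cache:
        return out, (noise, bn1, bn1_cache, act1, bn2, bn2_cache, act2)
    return out


def _generator_backward(dout, params, cache):
    noise, bn1, bn1_cache, act1, bn2, bn2_cache, act2 = cache
    grads = {}
    grads["W3"] = act2.T @ dout
    grads["b3"] = dout.sum(axis=0)
    d_act2 = dout @ params["W3"].T
    d_bn2 = d_act2 * leaky_relu_grad(bn2, _SLOPE)
    d_pre2, grads["gamma2"], grads["beta2"] = batch_norm_backward(d_bn2, bn2_cache)
    grads["W2"] = act1.T @ d_pre2
    grads["b2"] = d_pre2.sum(axis=0)
    d_act1 = d_pre2 @ params["W2"].T
    d_bn1 = d_act1 * leaky_relu_grad(bn1, _SLOPE)
    d_pre1, grads["gamma1"], grads["beta1"] = batch_norm_backward(d_bn1, bn1_cache)
    grads["W1"] = noise.T @ d_pre1
    grads["b1"] = d_pre1.sum(axis=0)
    return grads


def discriminator_forward(params, embeddings: np.ndarray, mode: str = "eval",
                          config: GANConfig | None = None,
                          rng: np.random.Generator | None = None,
                          return_cache: bool = False):
    """Embeddings -> probability in (0, 1); dropout only in train mode."""
    config = config or GANConfig()
    if embeddings.shape[1] != params["W1"].shape[0]:
        raise ValueError(
            f"expected {params['W1'].shape[0]}-d embeddings, got {embeddings.shape[1]}"
        )
    train = mode == "train"
    pre1 = embeddings @ params["W1"] + params["b1"]
    act1 = leaky_relu(pre1, _SLOPE)
    if train and config.disc_dropout > 0:
        if rng is None:
            raise ValueError("train-mode discriminator needs an rng for dropout")
        h1, mask1 = dropout_forward(act1, config.disc_dropout, rng)
    else:
        h1, mask1 = act1, None
    pre2 = h1 @ params["W2"] + params["b2"]
    act2 = leaky_relu(pre2, _SLOPE)
    if train and config.disc_dropout > 0:
        h2, mask2 = dropout_forward(act2, config.disc_dropout, rng)
    else:
        h2, mask2 = act2, None
    logit = (h2 @ params["W3"] + params["b3"]).ravel()
    prob = sigmoid(logit)
    if return_cache:
        return prob, (embeddings, pre1, mask1, h1, pre2, mask2, h2)
    return prob


def _discriminator_backward(dlogit, params, cache, want_dinput=False):
    x, pre1, mask1, h1, pre2, mask2, h2 = cache
    dlogit = dlogit[:, None]
    grads = {}
    grads["W3"] = h2.T @ dlogit
    grads["b3"] = dlogit.sum(axis=0)
    d_h2 = dlogit @ params["W3"].T
    if mask2 is not None:
        d_h2 = d_h2 * mask2
    d_pre2 = d_h2 * leaky_relu_grad(pre2, _SLOPE)
    grads["W2"] = h1.T @ d_pre2
    grads["b2"] = d_pre2.sum(axis=0)
    d_h1 = d_pre2 @ params["W2"].T
    if mask1 is not None:
        d_h1 = d_h1 * mask1
    d_pre1 = d_h1 * leaky_relu_grad(pre1, _SLOPE)
    grads["W1"] = x.T @ d_pre1
    grads["b1"] = d_pre1.sum(axis=0)
    dinput = d_pre1 @ params["W1"].T if want_dinput else None
    return grads, dinput


def _smoothed_bce_and_dlogit(prob: np.ndarray, target: float):
    """Mean BCE against a constant smoothed target and d/dlogit."""
    s = np.clip(prob, _CLIP, 1.0 - _CLIP)
    loss = float(-np.mean(target * np.log(s) + (1 - target) * np.log(1 - s)))
    dlogit = (prob - target) / len(prob)
    return loss, dlogit


def train_gan(real_embeddings: EmbeddingMatrix | np.ndarray,
              config: GANConfig | None = None):
    """Alternating adversarial training on autoencoder embeddings.

    Returns (generator params, discriminator params, history); history
    holds per-epoch mean losses and mean real/fake discriminator scores.
    Deterministic under ``config.seed``.
    """
    config = config or GANConfig()
    real = real_embeddings.values if isinstance(real_embeddings, EmbeddingMatrix) else real_embeddings
    if real.shape[1] != config.embed_dim:
        raise ValueError(f"real embeddings must be {config.embed_dim}-dimensional")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6A9]))
    gen = init_generator(config)
    disc = init_discriminator(config)
    gen_keys = [k for k in gen if not k.startswith(("rm", "rv"))]
    opt_g = Adam({k: gen[k] for k in gen_keys}, lr=config.lr, betas=config.betas)
    opt_d = Adam(disc, lr=config.lr, betas=config.betas)
    real_t, fake_t = config.label_smooth
    history = GANHistory()

    for epoch in range(config.epochs):
        order = rng.permutation(real.shape[0])
        ep = {"g": [], "d": [], "rs": [], "fs": []}
        for start in range(0, len(order), config.batch_size):
            batch = real[order[start:start + config.batch_size]]
            if len(batch) < 2:
                continue  # batch norm cannot run on a single sample
            noise = rng.standard_normal((len(batch), config.noise_dim))

            # --- discriminator step (generator output detached)
            fake = generator_forward(gen, noise, "train", config)
            p_real, cache_r = discriminator_forward(disc, batch, "train", config,
                                                    rng, return_cache=True)
            p_fake, cache_f = discriminator_forward(disc, fake, "train", config,
                                                    rng, return_cache=True)
            loss_r, dl_r = _smoothed_bce_and_dlogit(p_real, real_t)
            loss_f, dl_f = _smoothed_bce_and_dlogit(p_fake, fake_t)
            d_loss = 0.5 * (loss_r + loss_f)
            g_r, _ = _discriminator_backward(0.5 * dl_r, disc, cache_r)
            g_f, _ = _discriminator_backward(0.5 * dl_f, disc, cache_f)
            opt_d.step({k: g_r[k] + g_f[k] for k in g_r})

            # --- generator step (non-saturating: push fakes toward real target)
            noise2 = rng.standard_normal((len(batch), config.noise_dim))
            fake2, gcache = generator_forward(gen, noise2, "train", config,
                                              return_cache=True)
            p_fake2, dcache = discriminator_forward(disc, fake2, "train", config,
                                                    rng, return_cache=True)
            g_loss, dl_g = _smoothed_bce_and_dlogit(p_fake2, real_t)
            _, dfake = _discriminator_backward(dl_g, disc, dcache, want_dinput=True)
            g_grads = _generator_backward(dfake, gen, gcache)
            opt_g.step(g_grads)

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise FloatingPointError(f"non-finite GAN loss at epoch {epoch}")
            ep["d"].append(d_loss)
            ep["g"].append(g_loss)
            ep["rs"].append(float(p_real.mean()))
            ep["fs"].append(float(p_fake.mean()))

        history.disc_loss.append(float(np.mean(ep["d"])))
        history.gen_loss.append(float(np.mean(ep["g"])))
        history.real_score.append(float(np.mean(ep["rs"])))
        history.fake_score.append(float(np.mean(ep["fs"])))
    return gen, disc, history


def generate_node_embeddings(gen_params, n_nodes: int, seed: int = 0,
                             config: GANConfig | None = None) -> EmbeddingMatrix:
    """Unconditional per-node embeddings: row k of seeded noise -> node k."""
    config = config or GANConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x90DE]))
    noise = rng.standard_normal((n_nodes, config.noise_dim))
    values = generator_forward(gen_params, noise, "eval", config)
    return EmbeddingMatrix(values=values, model_tag="GAN")
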