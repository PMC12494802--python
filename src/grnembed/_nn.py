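"""Minimal NumPy neural-net primitives shared by the autoencoder and the GAN.

Forward functions return caches consumed by the matching backward
functions; all gradients are exact (verified by finite differences in the
test suite).
"""

from __future__ import annotations

import numpy as np

LN_EPS = 1e-5
BN_EPS = 1e-5


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x):
    return np.maximum(x, 0.0)


def leaky_relu(x, slope=0.2):
    return np.where(x >= 0, x, slope * x)


def leaky_relu_grad(x, slope=0.2):
    return np.where(x >= 0, 1.0, slope)


# ---------------------------------------------------------------- layer norm

def layer_norm_forward(x: np.ndarray, gain: np.ndarray, shift: np.ndarray):
    """Normalize each row over its features, then scale/shift."""
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + LN_EPS)
    xhat = (x - mu) * inv_std
    return gain * xhat + shift, (xhat, inv_std, gain)


def layer_norm_backward(dy: np.ndarray, cache):
    xhat, inv_std, gain = cache
    dgain = (dy * xhat).sum(axis=0)
    dshift = dy.sum(axis=0)
    dxhat = dy * gain
    m1 = dxhat.mean(axis=1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
    dx = inv_std * (dxhat - m1 - xhat * m2)
    return dx, dgain, dshift


# ---------------------------------------------------------------- batch norm

def batch_norm_forward(
    x: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    train: bool,
    momentum: float = 0.1,
):
    """Column-wise batch normalization.

    In train mode batch statistics are used and the running statistics are
    updated in place (momentum convention: new = (1-m)*old + m*batch).
    Eval mode uses the frozen running statistics and returns no cache.
    """
    if train:
        if x.shape[0] < 2:
            raise ValueError("batch norm needs a batch of at least 2 in train mode")
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * x.shape[0] / max(x.shape[0] - 1, 1)
        inv_std = 1.0 / np.sqrt(var + BN_EPS)
        xhat = (x - mu) * inv_std
        return gamma * xhat + beta, (xhat, inv_std, gamma)
    inv_std = 1.0 / np.sqrt(running_var + BN_EPS)
    return gamma * (x - running_mean) * inv_std + beta, None


def batch_norm_backward(dy: np.ndarray, cache):
    xhat, inv_std, gamma = cache
    n = dy.shape[0]
    dgamma = (dy * xhat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    dxhat = dy * gamma
    dx = inv_std / n * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
    return dx, dgamma, dbeta


def dropout_forward(x: np.ndarray, p: float, rng: np.random.Generator):
    """Inverted dropout; returns (output, mask)."""
    if p <= 0:
        return x, None
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask, mask


# --------------------------------------------------------------------- adam

class Adam:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decay_keys: tuple[str, ...] = ()):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_keys = set(decay_keys)
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            if self.weight_decay and k in self.decay_keys:
                g = g + self.weight_decay * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
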