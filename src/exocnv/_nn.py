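"""Low-level neural-network math: forward/backward pairs and Adam.

Everything is plain numpy; backward passes are hand-derived and verified
against finite differences in the test suite.  Activations are float32,
reductions in float32 (batch sizes are small enough that accumulation
error is negligible next to the training noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

_LN_EPS = 1e-5
_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x * _INV_SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x * _INV_SQRT2)) + x * _INV_SQRT2PI * np.exp(-0.5 * x * x)


def layernorm_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray):
    """Normalize over the last axis. Returns (y, cache)."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = np.mean(xc * xc, axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv_std
    return gamma * xhat + beta, (xhat, inv_std, gamma)


def layernorm_backward(dy: np.ndarray, cache):
    xhat, inv_std, gamma = cache
    dgamma = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gamma
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv_std * (dxhat - m1 - xhat * m2)
    return dx, dgamma, dbeta


def linear_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, x


def linear_backward(dy: np.ndarray, x: np.ndarray, W: np.ndarray):
    dx = dy @ W.T
    dW = np.tensordot(x, dy, axes=(tuple(range(x.ndim - 1)), tuple(range(dy.ndim - 1))))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, dW.astype(W.dtype), db


def masked_softmax(scores: np.ndarray, key_mask: np.ndarray) -> np.ndarray:
    """Softmax over the last axis with False keys excluded exactly.

    ``scores``: (B, nh, T, T); ``key_mask``: (B, T) booleans (True = attend).
    """
    neg = np.where(key_mask[:, None, None, :], 0.0, -np.inf).astype(scores.dtype)
    s = scores + neg
    s -= s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def softmax(x: np.ndarray) -> np.ndarray:
    s = x - x.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray, class_weights=None):
    """Weighted mean cross-entropy and its gradient w.r.t. logits.

    Returns (loss, dlogits); weights default to 1 per class.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    logp = np.log(np.maximum(p[np.arange(n), labels], 1e-300))
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
    wsum = w.sum()
    loss = float(-(w * logp).sum() / wsum)
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(np.float32)


@dataclass
class Adam:
    """Adam over a dict of named parameter arrays."""

    lr: float = 5e-5
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict, grads: dict, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k], dtype=np.float32)
                self.v[k] = np.zeros_like(params[k], dtype=np.float32)
            m = self.m[k]
            v = self.v[k]
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            params[k] -= (lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(np.float32)


def cosine_lr(lr_initial: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from ``lr_initial`` to 0 over the epoch budget."""
    return lr_initial * 0.5 * (1.0 + math.cos(math.pi * epoch / max(total_epochs, 1)))
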