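"""Losses and optimizer for the NumPy network engine.

Losses return ``(scalar loss, gradient w.r.t. the logits)`` so training
loops stay explicit.  All reductions are means, so loss scales are
comparable across batch and image sizes.
"""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["sigmoid", "bce_with_logits", "soft_dice_loss", "Adam", "minibatches"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; numerically stable."""
    z = z.astype(np.float32)
    t = t.astype(np.float32)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - t) / z.size
    return float(loss.mean()), dz


def soft_dice_loss(z: np.ndarray, t: np.ndarray, eps: float = 1.0) -> tuple[float, np.ndarray]:
    """Per-sample soft Dice loss on sigmoid probabilities, averaged over batch.

    ``z`` and ``t`` are ``(N, C, H, W)``; Dice is computed per sample over
    all remaining axes.
    """
    p = sigmoid(z)
    t = t.astype(np.float32)
    axes = tuple(range(1, z.ndim))
    inter = (p * t).sum(axis=axes)
    tot = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2.0 * inter + eps) / (tot + eps)
    loss = float((1.0 - dice).mean())
    # d(1 - dice)/dp = -(2 t (tot + eps) - (2 inter + eps)) / (tot + eps)^2
    shape = (-1,) + (1,) * (z.ndim - 1)
    num = (2.0 * inter + eps).reshape(shape)
    den = (tot + eps).reshape(shape)
    dp = -(2.0 * t * den - num) / (den * den)
    dz = dp * p * (1.0 - p) / z.shape[0]
    return loss, dz.astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield shuffled index arrays covering ``range(n)`` once."""
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]
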