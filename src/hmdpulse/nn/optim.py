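"""Optimizers and loss functions for the numpy backend."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "SGD", "mse_loss", "euclidean_loss", "bce_with_logits"]


class Adam:
    """Adaptive-moment estimation (the optimizer chosen for both models)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad ** 2 - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2):
        self.params = list(params)
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def mse_loss(pred: Tensor, target: np.ndarray | Tensor) -> Tensor:
    target = target if isinstance(target, Tensor) else Tensor(target)
    diff = pred - target
    return (diff * diff).mean()


def euclidean_loss(pred: Tensor, target: np.ndarray | Tensor) -> Tensor:
    """Mean per-sample Euclidean distance between prediction and target.

    For scalar targets this is the mean absolute error; for vector targets
    the mean L2 norm of the residual.
    """
    target = target if isinstance(target, Tensor) else Tensor(target)
    diff = pred - target
    if diff.ndim == 1:
        diff = diff.reshape(-1, 1)
    return (((diff * diff).sum(axis=-1) + 1e-12) ** 0.5).mean()


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on raw logits."""
    z, t = logits.data, np.asarray(target, dtype=float)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits._accumulate(g * (sig - t) / n)

    return Tensor._make(np.array(loss.mean()), (logits,), backward)
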