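"""AdamW optimiser and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["AdamW", "cosine_lr"]


class AdamW:
    """Adam with decoupled weight decay.

    Defaults mirror the training protocol used throughout the package:
    lr 1e-4, weight decay 0.01, betas (0.9, 0.999).
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        weight_decay: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        no_decay_params: list[Tensor] | None = None,
    ):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        no_decay = {id(p) for p in (no_decay_params or [])}
        self.decay_mask = [0.0 if id(p) in no_decay else 1.0 for p in self.params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v, dm in zip(self.params, self.m, self.v, self.decay_mask):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + dm * self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(epoch: int, max_epochs: int, lr: float, min_lr: float) -> float:
    """Cosine annealing from ``lr`` (epoch 0) down to ``min_lr`` (last epoch)."""
    if max_epochs <= 1:
        return lr
    frac = min(epoch / (max_epochs - 1), 1.0)
    return min_lr + 0.5 * (lr - min_lr) * (1.0 + np.cos(np.pi * frac))
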