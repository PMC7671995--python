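"""Adam optimizer and the cyclic halving learning-rate schedule.

The schedule starts at 1e-4, halves every epoch, and resets to 1e-4 every
five epochs: rate(e) = 1e-4 * 0.5 ** (e mod 5).
"""

from __future__ import annotations

import numpy as np

__all__ = ["lr_schedule", "Adam"]

BASE_LR = 1e-4


def lr_schedule(epoch: int, base_lr: float = BASE_LR) -> float:
    """Learning rate for 0-indexed ``epoch``: base_lr * 0.5^(epoch mod 5)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return base_lr * 0.5 ** (epoch % 5)


class Adam:
    """Adam with the framework-default moments (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = BASE_LR,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
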