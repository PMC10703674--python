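"""Optimizers and learning-rate schedules."""
from __future__ import annotations

import math

import numpy as np


class SGD:
    """Momentum SGD over ``(name, value, grad)`` parameter triples."""

    def __init__(self, params, lr: float = 0.1, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(v) for _, v, _ in self.params]

    def step(self):
        for (name, v, g), vel in zip(self.params, self.velocity):
            upd = g
            if self.weight_decay and not name.endswith(("gamma", "beta", "b")):
                upd = g + self.weight_decay * v
            vel *= self.momentum
            vel += upd
            v -= self.lr * vel


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(v) for _, v, _ in self.params]
        self.v = [np.zeros_like(v) for _, v, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for (name, p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def warmup_cosine_schedule(base_lr: float, total_steps: int,
                           warmup_frac: float = 0.05):
    """Linear ramp to ``base_lr`` then cosine decay to zero."""
    warmup = max(1, int(total_steps * warmup_frac))

    def lr_at(step: int) -> float:
        if step < warmup:
            return base_lr * (step + 1) / warmup
        if total_steps <= warmup:
            return base_lr
        t = (step - warmup) / (total_steps - warmup)
        return base_lr * 0.5 * (1.0 + math.cos(math.pi * min(t, 1.0)))

    return lr_at
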