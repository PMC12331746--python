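"""Adam optimizer and the warm-restarted cosine learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

from .layers import Parameter

__all__ = ["Adam", "WarmupCosine"]


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class WarmupCosine:
    """Linear warmup over a fraction of the cycle, then cosine decay to ~0.

    Re-warming on a loss change is achieved by constructing a fresh schedule
    (and optimizer) at the start of each training phase.
    """

    def __init__(self, base_lr: float, total_steps: int,
                 warmup_frac: float = 0.05, min_lr: float = 0.0):
        self.base_lr = base_lr
        self.total_steps = max(1, int(total_steps))
        self.warmup_steps = max(1, int(round(warmup_frac * self.total_steps)))
        self.min_lr = min_lr

    def lr_at(self, step: int) -> float:
        if step < self.warmup_steps:
            return self.base_lr * (step + 1) / self.warmup_steps
        frac = (step - self.warmup_steps) / max(
            1, self.total_steps - self.warmup_steps)
        frac = min(1.0, frac)
        return self.min_lr + 0.5 * (self.base_lr - self.min_lr) * (
            1.0 + math.cos(math.pi * frac))

    def apply(self, opt: Adam, step: int) -> float:
        lr = self.lr_at(step)
        opt.lr = lr
        return lr
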