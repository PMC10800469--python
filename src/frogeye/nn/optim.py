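"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD:
    def __init__(self, params, lr=1e-2, momentum=0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            b *= self.momentum
            b += p.grad
            p.data -= self.lr * b

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def step_decay(base_lr: float, epoch: int, milestones, gamma: float) -> float:
    """Piecewise-constant decay: lr is multiplied by gamma at each milestone."""
    lr = base_lr
    for m in milestones:
        if epoch >= m:
            lr *= gamma
    return lr


def exp_decay(base_lr: float, epoch: int, gamma: float) -> float:
    """Per-epoch exponential decay lr = base * gamma**epoch."""
    return base_lr * gamma ** epoch
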