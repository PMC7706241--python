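"""Optimizers for the NumPy layer stack: SGD with Nesterov momentum and Adam."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class SGD:
    """SGD with (optionally Nesterov) momentum and decoupled L2 weight decay.

    Update rule (torch convention):
        v <- mu * v + g
        w <- w - lr * (g + mu * v)   if nesterov
        w <- w - lr * v              otherwise
    where g includes the weight-decay term ``l2 * w``.
    """

    def __init__(self, params: list[Parameter], lr: float = 0.002,
                 momentum: float = 0.9, nesterov: bool = True,
                 weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr, self.momentum, self.nesterov = lr, momentum, nesterov
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            if self.nesterov:
                p.value -= self.lr * (g + self.momentum * v)
            else:
                p.value -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
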