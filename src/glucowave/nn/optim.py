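"""Momentum stochastic gradient descent."""

from __future__ import annotations

import numpy as np

from glucowave.nn.layers import Param


class SGD:
    """Classic momentum SGD: ``v = mu * v + g; p -= lr * v``."""

    def __init__(self, params: list[Param], lr: float = 0.01, momentum: float = 0.9):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
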