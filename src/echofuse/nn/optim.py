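"""Stochastic gradient descent with momentum and weight decay."""

from __future__ import annotations

import numpy as np


class SGD:
    def __init__(self, parameters, lr: float, momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.parameters = list(parameters)
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.parameters]

    def step(self) -> None:
        for p, v in zip(self.parameters, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad[...] = 0.0
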