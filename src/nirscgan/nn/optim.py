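"""First-order optimizers over a network's (layer, name) parameter items."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "RMSprop"]


class _Optimizer:
    def __init__(self, param_items, lr: float) -> None:
        self.items = list(param_items)
        self.lr = lr
        self.t = 0

    def step(self) -> None:
        raise NotImplementedError


class Adam(_Optimizer):
    """Adaptive-moment optimizer; β1=0.5 is the DCGAN-style default."""

    def __init__(self, param_items, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        super().__init__(param_items, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.items]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.items]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for (layer, name), m, v in zip(self.items, self.m, self.v):
            g = layer.grads[name]
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            layer.params[name] -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class RMSprop(_Optimizer):
    def __init__(self, param_items, lr: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-8) -> None:
        super().__init__(param_items, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.items]

    def step(self) -> None:
        self.t += 1
        for (layer, name), v in zip(self.items, self.v):
            g = layer.grads[name]
            v[...] = self.rho * v + (1 - self.rho) * g * g
            layer.params[name] -= self.lr * g / (np.sqrt(v) + self.eps)
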