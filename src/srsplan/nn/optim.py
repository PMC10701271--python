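"""Adam optimizer for the layer-parameter lists used by the networks."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adaptive-moment gradient descent over ``(layer, key)`` parameter pairs."""

    def __init__(self, parameters, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.parameters = list(parameters)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.params[k]) for l, k in self.parameters]
        self.v = [np.zeros_like(l.params[k]) for l, k in self.parameters]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for i, (layer, key) in enumerate(self.parameters):
            g = layer.grads[key]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
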