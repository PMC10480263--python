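"""Adam optimiser over the trainable layers of a network."""

from __future__ import annotations

import numpy as np


class Adam:
    """First-order moment / RMS adaptive optimiser (the conditional-GAN
    translation recipe's defaults: lr 2e-4, beta1 0.5, beta2 0.999)."""

    def __init__(self, layers, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.parameterized]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, layer in enumerate(self.layers):
            if not layer.trainable:
                continue
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / b1t
                vhat = self.v[i][k] / b2t
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()
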