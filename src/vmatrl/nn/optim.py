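"""Adam optimizer with global gradient-norm clipping."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, grad_clip_norm: float | None = 1.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.grad_clip_norm = grad_clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.grad_clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.grad_clip_norm and total > 0:
                scale = self.grad_clip_norm / total
                grads = [g * scale for g in grads]
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
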