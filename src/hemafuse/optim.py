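"""Optimizers.  AdamW: Adam with decoupled weight decay."""

from __future__ import annotations

import numpy as np

from .nn import Parameter

__all__ = ["AdamW"]


class AdamW:
    """Adam with decoupled weight decay.

    Decay is applied directly to the weights (``w -= lr * wd * w``) rather than
    folded into the gradient, so the effective regularisation is independent of
    the adaptive step size.  ``lr`` may be reassigned between steps to follow a
    schedule.
    """

    def __init__(self, params: list[Parameter], lr: float = 6.25e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 5e-4):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
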