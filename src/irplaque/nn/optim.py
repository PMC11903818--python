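"""RMSprop with the conventional exponentially weighted squared-gradient cache."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["RMSprop"]


class RMSprop:
    """RMSprop with optional global gradient-norm clipping.

    Clipping guards against the gradient spikes the clamped cross-entropy
    terms can produce (1/(T+eps) near the transfer-function dead zones).
    """

    def __init__(self, params: list[Param], lr: float = 5e-4, rho: float = 0.9,
                 eps: float = 1e-8, clip_norm: float | None = 1.0):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.clip_norm = clip_norm
        self.cache = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads
                                if g is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                grads = [None if g is None else g * scale for g in grads]
        for p, c, g in zip(self.params, self.cache, grads):
            if g is None:
                continue
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p.data -= (self.lr * g / (np.sqrt(c) + self.eps)).astype(p.data.dtype)
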