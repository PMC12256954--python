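"""RMSprop, the optimizer used for both training phases."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class RMSprop:
    """Root-mean-square propagation with the conventional defaults
    (decay 0.99, eps 1e-8).  Operates in place on the tensors' ``.data``.
    """

    def __init__(self, params: list[Tensor], lr: float, alpha: float = 0.99,
                 eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self._sq = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, sq in zip(self.params, self._sq):
            if p.grad is None:
                continue
            g = p.grad
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            p.data -= self.lr * g / (np.sqrt(sq) + self.eps)
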