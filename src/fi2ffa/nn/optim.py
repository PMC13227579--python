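"""RMSProp optimizer (the optimizer used for all six networks)."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class RMSProp:
    """Gradient-magnitude-normalized SGD.

    v <- alpha * v + (1 - alpha) * g^2 ;  p <- p - lr * g / (sqrt(v) + eps)
    """

    def __init__(self, params, lr: float = 2e-4, alpha: float = 0.99, eps: float = 1e-8):
        self.params: list[Tensor] = list(params)
        self.lr = float(lr)
        self.alpha = float(alpha)
        self.eps = float(eps)
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p.data = p.data - self.lr * g / (np.sqrt(v) + self.eps)

    def state_dict(self) -> dict:
        return {
            "lr": self.lr,
            "alpha": self.alpha,
            "eps": self.eps,
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, sd: dict) -> None:
        self.lr = float(sd["lr"])
        self.alpha = float(sd["alpha"])
        self.eps = float(sd["eps"])
        if len(sd["v"]) != len(self.v):
            raise ValueError("optimizer state length mismatch")
        self.v = [np.asarray(v, dtype=np.float32).copy() for v in sd["v"]]
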