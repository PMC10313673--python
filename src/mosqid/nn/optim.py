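"""Adam optimizer with per-group learning rates.

The network exposes three parameter groups (backbone, embedder, classifier)
that train at different rates; `Adam` accepts a list of
``{"params": [...], "lr": float}`` dictionaries mirroring that split.
Weight decay is the classic L2 form added to the gradient before the moment
updates.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam"]


class Adam:
    def __init__(self, param_groups, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.groups = []
        for g in param_groups:
            params = list(g["params"])
            self.groups.append({
                "params": params,
                "lr": float(g["lr"]),
                "m": [np.zeros_like(p.data) for p in params],
                "v": [np.zeros_like(p.data) for p in params],
            })
        self.beta1, self.beta2 = beta1, beta2
        self.eps, self.weight_decay = eps, weight_decay
        self.t = 0

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for g in self.groups:
            if g["lr"] == 0.0:
                continue  # frozen group: parameters stay bit-identical
            for p, m, v in zip(g["params"], g["m"], g["v"]):
                if p.grad is None:
                    continue
                grad = p.grad
                if self.weight_decay:
                    grad = grad + self.weight_decay * p.data
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad * grad
                p.data -= g["lr"] * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def gradient_check(f, params: list[Tensor], h: float = 1e-6) -> float:
    """Max relative error between analytic and central-difference gradients.

    `f` rebuilds the scalar loss Tensor from current parameter values; used
    by the test suite to validate every layer's backward pass.
    """
    loss = f()
    for p in params:
        p.grad = None
    loss.backward()
    worst = 0.0
    for p in params:
        flat = p.data.ravel()
        gflat = p.grad.ravel() if p.grad is not None else np.zeros_like(flat)
        idx = np.linspace(0, flat.size - 1, min(flat.size, 10), dtype=int)
        for i in idx:
            orig = flat[i]
            flat[i] = orig + h
            lp = f().data.item()
            flat[i] = orig - h
            lm = f().data.item()
            flat[i] = orig
            num = (lp - lm) / (2 * h)
            denom = max(abs(num), abs(gflat[i]), 1e-8)
            worst = max(worst, abs(num - gflat[i]) / denom)
    return worst
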