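"""Optimizers. AdamW keeps weight decay decoupled from the adaptive step."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class AdamW:
    """AdamW with decoupled weight decay (applied to every parameter).

    Parameters follow the common defaults: betas (0.9, 0.999), eps 1e-8,
    weight_decay 1e-2. ``lr`` may be changed between steps by a schedule.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            step = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (step + self.weight_decay * p.data)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(a, dtype=np.float32) for a in state["m"]]
        self.v = [np.asarray(a, dtype=np.float32) for a in state["v"]]
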