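"""AdamW with decoupled weight decay and the warmup + polynomial-decay schedule."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW", "WarmupPolySchedule"]


class AdamW:
    def __init__(self, params: list[Tensor], lr: float = 6e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if g is None:
                g = np.zeros_like(p.data)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            # decoupled decay, then Adam update
            p.data -= lr * self.weight_decay * p.data
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class WarmupPolySchedule:
    """Linear warmup from ``base_lr * warmup_factor`` followed by poly decay.

    lr(t) = base_lr * (1 - (t - warmup) / (total - warmup)) ** power  for
    t >= warmup; during warmup the rate rises linearly from the warmup floor.
    """

    def __init__(self, base_lr: float, total_iters: int, warmup_iters: int = 1500,
                 power: float = 1.0, warmup_factor: float = 0.1):
        if total_iters <= 0:
            raise ValueError("total_iters must be positive")
        self.base_lr = base_lr
        self.total_iters = total_iters
        self.warmup_iters = min(warmup_iters, total_iters)
        self.power = power
        self.warmup_factor = warmup_factor

    def __call__(self, it: int) -> float:
        if self.warmup_iters > 0 and it < self.warmup_iters:
            alpha = it / self.warmup_iters
            return self.base_lr * (self.warmup_factor + (1 - self.warmup_factor) * alpha)
        denom = max(self.total_iters - self.warmup_iters, 1)
        frac = min(max((it - self.warmup_iters) / denom, 0.0), 1.0)
        return self.base_lr * (1.0 - frac) ** self.power
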