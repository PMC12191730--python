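"""AdamW and the linear warmup/decay learning-rate schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "linear_warmup_decay"]


def linear_warmup_decay(step: int, total_steps: int, warmup_steps: int, peak_lr: float) -> float:
    """LR rises linearly to ``peak_lr`` over warmup, then decays linearly to 0."""
    if warmup_steps >= total_steps:
        raise ValueError("warmup_steps must be < total_steps")
    if step < warmup_steps:
        return peak_lr * (step + 1) / warmup_steps
    return peak_lr * max(0.0, (total_steps - step) / (total_steps - warmup_steps))


class AdamW:
    """Decoupled weight decay Adam over a dict of named parameter tensors.

    Layer norms and biases are excluded from weight decay, following the
    usual transformer training convention.
    """

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.98),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if self.weight_decay and not k.endswith(("bias", "gamma", "beta")):
                update = update + self.weight_decay * p.data
            p.data = p.data - lr * update
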