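"""AdamW (decoupled weight decay) with linear warmup / linear decay."""

from __future__ import annotations

import numpy as np

from ._autograd import DTYPE, Tensor


class AdamW:
    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
        total_steps: int | None = None,
        warmup_fraction: float = 0.1,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.total_steps = total_steps
        self.warmup_steps = max(1, int(warmup_fraction * total_steps)) if total_steps else 0
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def current_lr(self) -> float:
        """Linear warmup over the first 10% of steps, then linear decay to 0."""
        if not self.total_steps:
            return self.lr
        step = min(self.t, self.total_steps)
        if step < self.warmup_steps:
            return self.lr * (step + 1) / self.warmup_steps
        remaining = self.total_steps - self.warmup_steps
        if remaining <= 0:
            return self.lr
        return self.lr * max(0.0, (self.total_steps - step) / remaining)

    def step(self):
        lr = self.current_lr()
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / bias1
            v_hat = self.v[name] / bias2
            update = m_hat / (np.sqrt(v_hat) + self.eps)
            # decoupled weight decay: skip biases and layer-norm scales
            if self.weight_decay and p.data.ndim > 1:
                update = update + self.weight_decay * p.data
            p.data = (p.data - lr * update).astype(DTYPE)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
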