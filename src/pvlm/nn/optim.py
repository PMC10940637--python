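"""Optimization utilities: AdamW, gradient clipping, LR / ramp schedules, EMA."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Parameter


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.02):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / bc1
            v_hat = self.v[i] / bc2
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


def warmup_cosine_lr(step: int, total_steps: int, warmup_steps: int,
                     peak_lr: float = 1e-4, final_lr: float = 1e-5) -> float:
    """Linear warmup to ``peak_lr`` then cosine decay to ``final_lr``.

    ``step`` is 0-based; the end of warmup (step == warmup_steps) returns
    exactly ``peak_lr`` and the last step returns exactly ``final_lr``.
    """
    if warmup_steps > 0 and step < warmup_steps:
        return peak_lr * step / warmup_steps
    span = max(total_steps - warmup_steps, 1)
    frac = min((step - warmup_steps) / span, 1.0)
    return final_lr + 0.5 * (peak_lr - final_lr) * (1.0 + math.cos(math.pi * frac))


def alpha_ramp(step: int, steps_per_epoch: int, alpha_max: float = 0.4) -> float:
    """Pseudo-label mixing weight: linear 0 -> alpha_max across epoch 1, then flat."""
    if steps_per_epoch <= 0:
        return alpha_max
    return alpha_max * min(step / steps_per_epoch, 1.0)


def ema_update(student_state: dict[str, np.ndarray] | list[Parameter],
               teacher_state: dict[str, np.ndarray] | list[Parameter],
               lam: float):
    """w_teacher <- (1 - lam) * w_student + lam * w_teacher, elementwise.

    Accepts parallel parameter lists or name->array dicts; raises on mismatch.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("EMA coefficient must lie in [0, 1]")
    if isinstance(student_state, dict):
        if set(student_state) != set(teacher_state):
            raise ValueError("parameter-set mismatch between student and teacher")
        items = [(student_state[k], teacher_state[k]) for k in student_state]
    else:
        if len(student_state) != len(teacher_state):
            raise ValueError("parameter-count mismatch between student and teacher")
        items = list(zip(student_state, teacher_state))
    for s, t in items:
        s_arr = s.data if isinstance(s, Parameter) else s
        t_arr = t.data if isinstance(t, Parameter) else t
        if s_arr.shape != t_arr.shape:
            raise ValueError("parameter shape mismatch between student and teacher")
        t_arr *= lam
        t_arr += (1.0 - lam) * s_arr
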