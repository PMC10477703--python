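"""Lion optimizer (sign-momentum with decoupled weight decay), plus Adam.

Lion keeps one momentum buffer per parameter and updates with the sign of an
interpolated gradient:

    c      = β₁·m + (1−β₁)·g
    θ_new  = θ − η·(sign(c) + λ·θ)
    m_new  = β₂·m + (1−β₂)·g

Weight decay is decoupled (applied to θ, not folded into the gradient), and by
convention biases and batch-norm parameters are exempt from it. Defaults are
the training settings of this pipeline: β₁=0.95, β₂=0.98, η=1e-4, λ=0.015.

Adam is provided for the optimizer ablation (β=(0.9, 0.999), same learning
rate); with no deep-learning framework underneath, it is implemented here in
the same in-place style.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor

__all__ = ["LionHyper", "lion_step", "Lion", "Adam"]


@dataclasses.dataclass
class LionHyper:
    beta1: float = 0.95
    beta2: float = 0.98
    lr: float = 1e-4
    weight_decay: float = 0.015

    def __post_init__(self):
        if not (0.0 <= self.beta1 < 1.0 and 0.0 <= self.beta2 < 1.0):
            raise ValueError("betas must lie in [0, 1)")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be nonnegative")


def lion_step(theta: np.ndarray, grad: np.ndarray, m: np.ndarray,
              hyper: LionHyper, apply_decay: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """One functional Lion update; returns (theta_new, m_new). sign(0) = 0."""
    if theta.shape != grad.shape or theta.shape != m.shape:
        raise ValueError("theta, grad and momentum must share a shape")
    if np.isnan(grad).any():
        raise ValueError("NaN in gradient")
    c = hyper.beta1 * m + (1.0 - hyper.beta1) * grad
    decay = hyper.weight_decay * theta if apply_decay else 0.0
    theta_new = theta - hyper.lr * (np.sign(c) + decay)
    m_new = hyper.beta2 * m + (1.0 - hyper.beta2) * grad
    return theta_new, m_new


class Lion:
    """In-place Lion over a dict of named parameter Tensors.

    ``decay_mask[name] = False`` exempts a parameter from weight decay.
    """

    def __init__(self, params: dict[str, Tensor], hyper: LionHyper | None = None,
                 decay_mask: dict[str, bool] | None = None):
        self.params = params
        self.hyper = hyper or LionHyper()
        self.decay_mask = decay_mask or {}
        self.state = {name: np.zeros_like(t.data) for name, t in params.items()}

    def step(self) -> None:
        for name, t in self.params.items():
            if t.grad is None:
                continue
            theta, m = lion_step(t.data, t.grad, self.state[name], self.hyper,
                                 apply_decay=self.decay_mask.get(name, True))
            t.data[...] = theta
            self.state[name][...] = m


class Adam:
    """Standard Adam (no weight decay), for the optimizer ablation."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {n: np.zeros_like(t.data) for n, t in params.items()}
        self.v = {n: np.zeros_like(t.data) for n, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            if np.isnan(g).any():
                raise ValueError("NaN in gradient")
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / b1t
            vhat = self.v[name] / b2t
            p.data[...] = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
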