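"""First-order optimizers with the standard published update rules.

All seven optimizers the training protocol compares are provided; "sgdm"
is stochastic gradient descent with momentum 0.9. Default hyperparameters:
learning rate 0.001, beta1 0.9, beta2 0.999, epsilon 1e-07, rho 0.95
(adadelta) / 0.9 (rmsprop), momentum 0.9.
"""

from __future__ import annotations

import numpy as np

from tumorseg.core_io import ValidationError
from tumorseg.nn.layers import Param

__all__ = ["Optimizer", "make_optimizer", "OPTIMIZERS"]


class Optimizer:
    name = "base"

    def __init__(self, lr: float = 0.001, eps: float = 1e-7):
        self.lr = lr
        self.eps = eps
        self.t = 0

    def step(self, params: list[Param]) -> None:
        self.t += 1
        for p in params:
            if p.trainable:
                self._update(p)

    def _update(self, p: Param) -> None:
        raise NotImplementedError


class SGDM(Optimizer):
    name = "sgdm"

    def __init__(self, lr: float = 0.001, momentum: float = 0.9, **kw):
        super().__init__(lr=lr)
        self.momentum = momentum

    def _update(self, p: Param) -> None:
        v = p.state.setdefault("v", np.zeros_like(p.value))
        v *= self.momentum
        v -= self.lr * p.grad
        p.value += v


class Adam(Optimizer):
    name = "adam"

    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7, **kw):
        super().__init__(lr=lr, eps=eps)
        self.b1, self.b2 = beta1, beta2

    def _update(self, p: Param) -> None:
        m = p.state.setdefault("m", np.zeros_like(p.value))
        v = p.state.setdefault("v", np.zeros_like(p.value))
        m += (1 - self.b1) * (p.grad - m)
        v += (1 - self.b2) * (p.grad**2 - v)
        mhat = m / (1 - self.b1**self.t)
        vhat = v / (1 - self.b2**self.t)
        p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(Optimizer):
    name = "adamax"

    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7, **kw):
        super().__init__(lr=lr, eps=eps)
        self.b1, self.b2 = beta1, beta2

    def _update(self, p: Param) -> None:
        m = p.state.setdefault("m", np.zeros_like(p.value))
        u = p.state.setdefault("u", np.zeros_like(p.value))
        m += (1 - self.b1) * (p.grad - m)
        np.maximum(self.b2 * u, np.abs(p.grad), out=u)
        p.value -= (self.lr / (1 - self.b1**self.t)) * m / (u + self.eps)


class Adagrad(Optimizer):
    name = "adagrad"

    def __init__(self, lr: float = 0.001, eps: float = 1e-7, **kw):
        super().__init__(lr=lr, eps=eps)

    def _update(self, p: Param) -> None:
        a = p.state.setdefault("a", np.zeros_like(p.value))
        a += p.grad**2
        p.value -= self.lr * p.grad / (np.sqrt(a) + self.eps)


class Adadelta(Optimizer):
    name = "adadelta"

    def __init__(self, lr: float = 0.001, rho: float = 0.95, eps: float = 1e-7, **kw):
        super().__init__(lr=lr, eps=eps)
        self.rho = rho

    def _update(self, p: Param) -> None:
        eg = p.state.setdefault("eg", np.zeros_like(p.value))
        ed = p.state.setdefault("ed", np.zeros_like(p.value))
        eg *= self.rho
        eg += (1 - self.rho) * p.grad**2
        dx = np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * p.grad
        ed *= self.rho
        ed += (1 - self.rho) * dx**2
        p.value -= self.lr * dx


class RMSprop(Optimizer):
    name = "rmsprop"

    def __init__(self, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-7, **kw):
        super().__init__(lr=lr, eps=eps)
        self.rho = rho

    def _update(self, p: Param) -> None:
        eg = p.state.setdefault("eg", np.zeros_like(p.value))
        eg *= self.rho
        eg += (1 - self.rho) * p.grad**2
        p.value -= self.lr * p.grad / (np.sqrt(eg) + self.eps)


class Nadam(Optimizer):
    name = "nadam"

    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7, **kw):
        super().__init__(lr=lr, eps=eps)
        self.b1, self.b2 = beta1, beta2

    def _update(self, p: Param) -> None:
        m = p.state.setdefault("m", np.zeros_like(p.value))
        v = p.state.setdefault("v", np.zeros_like(p.value))
        m += (1 - self.b1) * (p.grad - m)
        v += (1 - self.b2) * (p.grad**2 - v)
        mhat = m / (1 - self.b1 ** (self.t + 1))
        vhat = v / (1 - self.b2**self.t)
        # Nesterov lookahead on the first moment
        update = self.b1 * mhat + (1 - self.b1) * p.grad / (1 - self.b1**self.t)
        p.value -= self.lr * update / (np.sqrt(vhat) + self.eps)


OPTIMIZERS = {cls.name: cls for cls in (SGDM, Adam, Adamax, Adagrad, Adadelta, RMSprop, Nadam)}


def make_optimizer(name: str, **hyper) -> Optimizer:
    """Build an optimizer by (case-insensitive) name with optional overrides."""
    key = name.lower()
    if key not in OPTIMIZERS:
        raise ValidationError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    return OPTIMIZERS[key](**hyper)
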