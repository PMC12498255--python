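"""Stochastic gradient descent with classical momentum.

The update is ``v <- mu*v + grad``, ``theta <- theta - lr*v``; with ``mu=0``
this is the plain SGD rule ``theta <- theta - lr*grad``.
"""

from __future__ import annotations

import numpy as np


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            if not np.all(np.isfinite(p.grad)):
                raise FloatingPointError("non-finite gradient encountered")
            if self.momentum:
                v *= self.momentum
                v += p.grad
                p.data -= (self.lr * v).astype(p.data.dtype, copy=False)
            else:
                p.data -= (self.lr * p.grad).astype(p.data.dtype, copy=False)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def sgd_step(theta: np.ndarray, grad: np.ndarray, lr: float,
             velocity: np.ndarray | None = None, momentum: float = 0.0):
    """Functional single-parameter update; returns (theta', velocity')."""
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite gradient encountered")
    if velocity is None:
        velocity = np.zeros_like(np.asarray(theta, dtype=float))
    velocity = momentum * velocity + grad
    return theta - lr * velocity, velocity
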