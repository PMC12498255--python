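"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray``,
records its parents and a vector-Jacobian closure when it is produced by an
operation, and :meth:`Tensor.backward` replays the tape in reverse
topological order.  Only the operations the segmentation models need are
implemented (see :mod:`trunet.nn.functional`).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjps=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        # parents: tensors this one was computed from; vjps: per-parent
        # closures mapping the incoming gradient to that parent's gradient.
        self._parents = tuple(parents)
        self._vjps = tuple(vjps)

    # -- convenience -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    # -- autodiff --------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in zip(node._parents, node._vjps):
                if vjp is None:
                    continue
                pg = vjp(g)
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # free the tape (parents) so big graphs can be garbage collected early
    def release(self):
        self._parents = ()
        self._vjps = ()


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)
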