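"""Layer/module abstractions on top of the autodiff tensor.

Every layer knows three things: how to run forward, how many trainable
scalars it owns, and how many multiply-accumulates it spends at a given
spatial size.  The MAC convention matches the usual analytic profilers:
convolutions and transposed convolutions count Cin*Cout*k^2 per output
(resp. input) position; elementwise ops, batch norm, activations and
pooling are free.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    """Base class with attribute-walking parameter discovery."""

    def __init__(self):
        self.training = True

    # -- traversal -------------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield (prefix + name, value)
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield (prefix + name, getattr(self, name))
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    # -- modes -----------------------------------------------------------
    def train(self, flag: bool = True):
        self.training = flag
        for _, child in self._children():
            child.train(flag)
        return self

    def eval(self):
        return self.train(False)

    # -- bookkeeping -----------------------------------------------------
    def param_count(self) -> int:
        """Number of trainable scalars (BN running statistics excluded)."""
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {name: np.array(p.data) for name, p in self.named_parameters()}
        out.update({name: np.array(b) for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=p.data.dtype)
        for name, _ in self.named_buffers():
            parts = name.split(".")
            obj = self
            for part in parts[:-1]:
                obj = obj[int(part)] if isinstance(obj, (list, tuple)) else getattr(obj, part)
            buf = getattr(obj, parts[-1])
            buf[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x

    @staticmethod
    def macs(hw):
        return 0, hw


def _out_hw(hw, kernel, stride, padding):
    h, w = hw
    return ((h + 2 * padding - kernel) // stride + 1,
            (w + 2 * padding - kernel) // stride + 1)


class Conv2d(Module):
    """Standard conv; ``padding=None`` means 'same' for odd kernels at stride 1
    and the conventional k//2 halving pad at stride 2."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.kernel, self.stride = cin, cout, kernel, stride
        self.padding = kernel // 2 if padding is None else padding
        std = np.sqrt(2.0 / (cin * kernel * kernel))
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, kernel, kernel)).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)

    def macs(self, hw):
        oh, ow = _out_hw(hw, self.kernel, self.stride, self.padding)
        return self.cin * self.cout * self.kernel ** 2 * oh * ow, (oh, ow)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 2, stride: int = 2,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.kernel, self.stride = cin, cout, kernel, stride
        std = np.sqrt(2.0 / (cin * kernel * kernel))
        self.weight = Tensor(rng.normal(0.0, std, (cin, cout, kernel, kernel)).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)

    def macs(self, hw):
        h, w = hw
        oh = (h - 1) * self.stride + self.kernel
        ow = (w - 1) * self.stride + self.kernel
        return self.cin * self.cout * self.kernel ** 2 * h * w, (oh, ow)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Tensor(np.ones(c, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x):
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)

    @staticmethod
    def macs(hw):
        return 0, hw


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)

    def macs(self, hw):
        return 0, _out_hw(hw, self.kernel, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def macs(self, hw):
        total = 0
        for m in self.mods:
            c, hw = m.macs(hw)
            total += c
        return total, hw
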