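"""Differentiable operations used by the segmentation models.

All convolutions use the shift-and-matmul strategy: the kernel footprint is
looped over (k*k BLAS calls) instead of materialising a full im2col buffer,
which keeps memory flat for the deep encoder at desk-scale sizes.
Layout is NCHW throughout.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b),
                 vjps=(lambda g, s=a.shape: _unbroadcast(g, s),
                       lambda g, s=b.shape: _unbroadcast(g, s)))
    return out


def sub(a: Tensor, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(a.data - b.data, parents=(a, b),
                  vjps=(lambda g, s=a.shape: _unbroadcast(g, s),
                        lambda g, s=b.shape: _unbroadcast(-g, s)))


def mul(a: Tensor, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(a.data * b.data, parents=(a, b),
                  vjps=(lambda g, o=b.data, s=a.shape: _unbroadcast(g * o, s),
                        lambda g, o=a.data, s=b.shape: _unbroadcast(g * o, s)))


def div(a: Tensor, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(a.data / b.data, parents=(a, b),
                  vjps=(lambda g, o=b.data, s=a.shape: _unbroadcast(g / o, s),
                        lambda g, x=a.data, o=b.data, s=b.shape:
                        _unbroadcast(-g * x / (o * o), s)))


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, parents=(a,), vjps=(lambda g: -g,))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=(x,), vjps=(lambda g, m=mask: g * m,))


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(y, parents=(x,), vjps=(lambda g, y=y: g * y * (1.0 - y),))


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    return Tensor(y, parents=(x,), vjps=(lambda g, y=y: g * (1.0 - y * y),))


def tsum(x: Tensor) -> Tensor:
    return Tensor(np.asarray(x.data.sum()), parents=(x,),
                  vjps=(lambda g, s=x.shape, d=x.dtype:
                        np.broadcast_to(np.asarray(g, dtype=d), s).copy(),))


def mean(x: Tensor, axis, keepdims: bool = True) -> Tensor:
    axis = tuple(np.atleast_1d(axis))
    n = int(np.prod([x.shape[a] for a in axis]))
    y = x.data.mean(axis=axis, keepdims=keepdims)

    def vjp(g, axis=axis, keepdims=keepdims, shape=x.shape, n=n):
        if not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g / n, shape).copy()

    return Tensor(y, parents=(x,), vjps=(vjp,))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g, i=i):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return g[tuple(sl)]
        return vjp

    return Tensor(data, parents=tuple(tensors),
                  vjps=tuple(make_vjp(i) for i in range(len(tensors))))


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis."""
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def vjp(g, sl=sl, shape=x.shape):
        out = np.zeros(shape, dtype=g.dtype)
        out[sl] = g
        return out

    return Tensor(x.data[sl], parents=(x,), vjps=(vjp,))


def reshape(x: Tensor, shape) -> Tensor:
    return Tensor(x.data.reshape(shape), parents=(x,),
                  vjps=(lambda g, s=x.shape: g.reshape(s),))


# ---------------------------------------------------------------------------
# spatial operators
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, weight layout (Cout, Cin, KH, KW)."""
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, Ci, KH, KW = wd.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Ci}")
    OH = (H + 2 * padding - KH) // stride + 1
    OW = (W + 2 * padding - KW) // stride + 1
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else xd
    out = np.zeros((N, OH, OW, O), dtype=xd.dtype)
    for i in range(KH):
        for j in range(KW):
            xs = xp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride]
            out += np.tensordot(xs, wd[:, :, i, j], axes=([1], [1]))
    y = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)

    def vjp_x(gy, xp_shape=xp.shape):
        gyt = gy.transpose(0, 2, 3, 1)
        gxp = np.zeros(xp_shape, dtype=gy.dtype)
        for i in range(KH):
            for j in range(KW):
                gxp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride] += \
                    np.tensordot(gyt, wd[:, :, i, j], axes=([3], [0])).transpose(0, 3, 1, 2)
        if padding:
            return gxp[:, :, padding:padding + H, padding:padding + W]
        return gxp

    def vjp_w(gy):
        gyt = gy.transpose(0, 2, 3, 1)
        gw = np.zeros_like(wd)
        for i in range(KH):
            for j in range(KW):
                xs = xp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride]
                gw[:, :, i, j] = np.tensordot(gyt, xs, axes=([0, 1, 2], [0, 2, 3]))
        return gw

    parents = [x, w]
    vjps = [vjp_x, vjp_w]
    if b is not None:
        parents.append(b)
        vjps.append(lambda gy: gy.sum(axis=(0, 2, 3)))
    return Tensor(y, parents=tuple(parents), vjps=tuple(vjps))


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution, weight layout (Cin, Cout, K, K), no padding.

    With kernel size == stride (the decoder's k=2, s=2 case) this is exact
    learned upsampling with non-overlapping blocks, but the implementation is
    general for K >= stride.
    """
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    Ci, O, KH, KW = wd.shape
    if Ci != C:
        raise ValueError(f"conv_transpose2d channel mismatch: input {C}, weight expects {Ci}")
    OH = (H - 1) * stride + KH
    OW = (W - 1) * stride + KW
    y = np.zeros((N, O, OH, OW), dtype=xd.dtype)
    for i in range(KH):
        for j in range(KW):
            contrib = np.tensordot(xd, wd[:, :, i, j], axes=([1], [0]))  # N,H,W,O
            y[:, :, i:i + stride * H:stride, j:j + stride * W:stride] += \
                contrib.transpose(0, 3, 1, 2)
    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)

    def vjp_x(gy):
        gx = np.zeros_like(xd)
        for i in range(KH):
            for j in range(KW):
                gs = gy[:, :, i:i + stride * H:stride, j:j + stride * W:stride]
                gx += np.tensordot(gs, wd[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
        return gx

    def vjp_w(gy):
        gw = np.zeros_like(wd)
        for i in range(KH):
            for j in range(KW):
                gs = gy[:, :, i:i + stride * H:stride, j:j + stride * W:stride]
                gw[:, :, i, j] = np.tensordot(xd, gs, axes=([0, 2, 3], [0, 2, 3]))
        return gw

    parents = [x, w]
    vjps = [vjp_x, vjp_w]
    if b is not None:
        parents.append(b)
        vjps.append(lambda gy: gy.sum(axis=(0, 2, 3)))
    return Tensor(y, parents=tuple(parents), vjps=tuple(vjps))


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    xd = x.data
    N, C, H, W = xd.shape
    OH = (H + 2 * padding - kernel) // stride + 1
    OW = (W + 2 * padding - kernel) // stride + 1
    fill = -np.inf if np.issubdtype(xd.dtype, np.floating) else np.iinfo(xd.dtype).min
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=fill) if padding else xd
    out = np.full((N, C, OH, OW), fill, dtype=xd.dtype)
    for i in range(kernel):
        for j in range(kernel):
            np.maximum(out, xp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride],
                       out=out)

    def vjp(gy):
        gxp = np.zeros_like(xp)
        assigned = np.zeros(out.shape, dtype=bool)
        for i in range(kernel):
            for j in range(kernel):
                xs = xp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride]
                m = (xs == out) & ~assigned
                assigned |= m
                gxp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride] += gy * m
        if padding:
            return gxp[:, :, padding:padding + H, padding:padding + W]
        return gxp

    return Tensor(out, parents=(x,), vjps=(vjp,))


def avg_pool_to(x: Tensor, out_size: int) -> Tensor:
    """Adaptive average pooling to (out_size, out_size); input must divide evenly."""
    N, C, H, W = x.shape
    if H % out_size or W % out_size:
        raise ValueError(f"avg_pool_to: {H}x{W} not divisible by {out_size}")
    fh, fw = H // out_size, W // out_size
    y = x.data.reshape(N, C, out_size, fh, out_size, fw).mean(axis=(3, 5))

    def vjp(gy, fh=fh, fw=fw):
        g = gy[:, :, :, None, :, None] / (fh * fw)
        return np.broadcast_to(g, (N, C, out_size, fh, out_size, fw)).reshape(N, C, H, W).copy()

    return Tensor(y, parents=(x,), vjps=(vjp,))


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    if factor == 1:
        return x
    y = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def vjp(gy, f=factor):
        N, C, H, W = x.shape
        return gy.reshape(N, C, H, f, W, f).sum(axis=(3, 5))

    return Tensor(y, parents=(x,), vjps=(vjp,))


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    xd = x.data
    N, C, H, W = xd.shape
    if training:
        axes = (0, 2, 3)
        m = N * H * W
        mu = xd.mean(axis=axes)
        var = xd.var(axis=axes)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        # unbiased running variance, as is conventional
        running_var += momentum * var * (m / max(m - 1, 1))
        std = np.sqrt(var + eps)
        xhat = (xd - mu.reshape(1, C, 1, 1)) / std.reshape(1, C, 1, 1)
        y = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

        def vjp_x(gy):
            dxhat = gy * gamma.data.reshape(1, C, 1, 1)
            s1 = dxhat.sum(axis=axes).reshape(1, C, 1, 1)
            s2 = (dxhat * xhat).sum(axis=axes).reshape(1, C, 1, 1)
            return (dxhat - s1 / m - xhat * s2 / m) / std.reshape(1, C, 1, 1)

        vjps = (vjp_x,
                lambda gy: (gy * xhat).sum(axis=(0, 2, 3)),
                lambda gy: gy.sum(axis=(0, 2, 3)))
    else:
        scale = gamma.data / np.sqrt(running_var + eps)
        y = scale.reshape(1, C, 1, 1) * (xd - running_mean.reshape(1, C, 1, 1)) \
            + beta.data.reshape(1, C, 1, 1)
        xhat_e = (xd - running_mean.reshape(1, C, 1, 1)) / \
            np.sqrt(running_var + eps).reshape(1, C, 1, 1)
        vjps = (lambda gy: gy * scale.reshape(1, C, 1, 1),
                lambda gy: (gy * xhat_e).sum(axis=(0, 2, 3)),
                lambda gy: gy.sum(axis=(0, 2, 3)))
    return Tensor(y, parents=(x, gamma, beta), vjps=vjps)
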