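"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the trainable classifier: a small tape-based
engine supporting exactly the operations the network needs (dense and
convolutional products, gated-recurrence arithmetic, pooling, batch
normalisation, dropout and the softmax cross-entropy loss). Gradients are
accumulated by topological traversal of the recorded graph. Everything is
float32 unless the caller passes float64 inputs.

The engine is deliberately small rather than general: no in-place ops, no
higher-order gradients, no graph retention across backward calls.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "tanh",
    "conv2d",
    "maxpool2d",
    "softmax",
    "softmax_cross_entropy",
    "dropout",
    "batch_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # Leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32 if np.asarray(data).dtype != np.float64 else np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # Break closure<->node reference cycles so memory frees by refcount
        # (single-use tape: no second backward through the same graph).
        for node in topo:
            node._backward = None
            node._parents = ()

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, _as_tensor(-1.0)))

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        src_shape = self.data.shape

        def _bwd():
            self._accumulate(out.grad.reshape(src_shape))

        out._backward = _bwd
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        out = _node(np.transpose(self.data, axes), (self,))
        inv = np.argsort(axes)

        def _bwd():
            self._accumulate(np.transpose(out.grad, inv))

        out._backward = _bwd
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = _node(self.data[idx], (self,))

        def _bwd():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accumulate(g)

        out._backward = _bwd
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        src_shape = self.data.shape

        def _bwd():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, src_shape).copy())

        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        # Split ties evenly so the gradient stays well-defined.
        mask = mask / mask.sum(axis=axis, keepdims=True)
        out = _node(out_data if keepdims else np.squeeze(out_data, axis=axis), (self,))

        def _bwd():
            g = out.grad if keepdims else np.expand_dims(out.grad, axis)
            self._accumulate(mask * g)

        out._backward = _bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def release(t: Tensor) -> None:
    """Drop a forward graph without running backward (inference outputs).

    Tensor nodes and their backward closures reference each other; releasing
    explicitly lets plain refcounting reclaim large activations immediately.
    """
    stack = [t]
    seen = set()
    while stack:
        node = stack.pop()
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.extend(node._parents)
        node._backward = None
        node._parents = ()


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Iterable[Tensor]) -> Tensor:
    t = Tensor.__new__(Tensor)
    t.data = data
    t.grad = None
    t.requires_grad = any(p.requires_grad or p._parents for p in parents)
    t._backward = None
    t._parents = tuple(parents)
    return t


# -- elementwise and linear ops -----------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = _node(a.data + b.data, (a, b))

    def _bwd():
        a._accumulate(_unbroadcast(out.grad, a.data.shape))
        b._accumulate(_unbroadcast(out.grad, b.data.shape))

    out._backward = _bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = _node(a.data * b.data, (a, b))

    def _bwd():
        a._accumulate(_unbroadcast(out.grad * b.data, a.data.shape))
        b._accumulate(_unbroadcast(out.grad * a.data, b.data.shape))

    out._backward = _bwd
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = _node(a.data @ b.data, (a, b))

    def _bwd():
        ga = out.grad @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ out.grad
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = _bwd
    return out


def relu(a: Tensor) -> Tensor:
    out = _node(np.maximum(a.data, 0), (a,))

    def _bwd():
        a._accumulate(out.grad * (a.data > 0))

    out._backward = _bwd
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = _node(s, (a,))

    def _bwd():
        a._accumulate(out.grad * s * (1.0 - s))

    out._backward = _bwd
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = _node(t, (a,))

    def _bwd():
        a._accumulate(out.grad * (1.0 - t * t))

    out._backward = _bwd
    return out


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(out.grad[tuple(sl)])

    out._backward = _bwd
    return out


def stack(tensors: Sequence[Tensor], axis: int) -> Tensor:
    out = _node(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def _bwd():
        for i, t in enumerate(tensors):
            t._accumulate(np.take(out.grad, i, axis=axis))

    out._backward = _bwd
    return out


# -- convolution / pooling ----------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """(N, C, H, W) -> (N, C*kh*kw, OH*OW) patch matrix, valid padding."""
    n, c, h, w = x.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, oh, ow, kh, kw),
        strides=(s0, s1, s2 * sh, s3 * sw, s2, s3),
        writeable=False,
    )
    col = view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(col), oh, ow


def _col2im(col: np.ndarray, x_shape, kh: int, kw: int, sh: int, sw: int, oh: int, ow: int) -> np.ndarray:
    n, c, h, w = x_shape
    col = col.reshape(n, c, kh, kw, oh, ow)
    out = np.zeros(x_shape, dtype=col.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += col[:, :, i, j]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: tuple[int, int]) -> Tensor:
    """Valid 2-D cross-correlation. x: (N,C,H,W); weight: (O,C,kh,kw); bias: (O,)."""
    n, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {ci}")
    if h < kh or w < kw:
        raise ValueError(f"conv2d spatial dims {h}x{w} smaller than kernel {kh}x{kw}")
    sh, sw = stride
    col, oh, ow = _im2col(x.data, kh, kw, sh, sw)  # (N, C*kh*kw, OH*OW)
    wmat = weight.data.reshape(o, c * kh * kw)
    out_data = np.matmul(wmat, col).reshape(n, o, oh, ow)
    if bias is not None:
        out_data += bias.data.reshape(1, o, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _node(out_data, parents)

    def _bwd():
        g = out.grad.reshape(n, o, oh * ow)
        gw = np.tensordot(g, col, axes=([0, 2], [0, 2])).reshape(weight.data.shape)
        weight._accumulate(gw)
        if bias is not None:
            bias._accumulate(out.grad.sum(axis=(0, 2, 3)))
        gcol = np.matmul(wmat.T, g)
        x._accumulate(_col2im(gcol, x.data.shape, kh, kw, sh, sw, oh, ow))

    out._backward = _bwd
    return out


def maxpool2d(x: Tensor, pool: tuple[int, int]) -> Tensor:
    """Non-overlapping max pooling with floor division (trailing rows/cols dropped)."""
    n, c, h, w = x.data.shape
    ph, pw = pool
    oh, ow = h // ph, w // pw
    trimmed = x.data[:, :, : oh * ph, : ow * pw]
    blocks = trimmed.reshape(n, c, oh, ph, ow, pw)
    out_data = blocks.max(axis=(3, 5))
    # argmax mask; ties split evenly
    mask = blocks == out_data[:, :, :, None, :, None]
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)
    out = _node(out_data, (x,))

    def _bwd():
        g = mask * out.grad[:, :, :, None, :, None]
        gx = np.zeros_like(x.data)
        gx[:, :, : oh * ph, : ow * pw] = g.reshape(n, c, oh * ph, ow * pw)
        x._accumulate(gx)

    out._backward = _bwd
    return out


# -- stochastic / normalisation layers ----------------------------------------

def dropout(x: Tensor, rate: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode needs a random generator")
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
    return mul(x, Tensor(mask))


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.99,
    eps: float = 1e-3,
    steps: np.ndarray | None = None,
) -> Tensor:
    """Batch normalisation over all axes except channel axis 1.

    `running_mean`/`running_var` are plain arrays updated in place during
    training (exponential moving average with the given momentum). If a
    `steps` counter array is supplied, the very first training batch seeds
    the running statistics directly (instead of blending with the 0/1
    initialisation), so short training runs still produce usable
    inference-mode statistics.
    """
    axes = (0,) + tuple(range(2, x.data.ndim))
    shape = (1, x.data.shape[1]) + (1,) * (x.data.ndim - 2)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        if steps is not None and steps[0] == 0:
            running_mean[...] = mean
            running_var[...] = var
        else:
            running_mean *= momentum
            running_mean += (1.0 - momentum) * mean
            running_var *= momentum
            running_var += (1.0 - momentum) * var
        if steps is not None:
            steps[0] += 1
        m = float(np.prod([x.data.shape[a] for a in axes]))
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mean.reshape(shape)) * inv_std.reshape(shape)
        out = _node(gamma.data.reshape(shape) * xhat + beta.data.reshape(shape), (x, gamma, beta))

        def _bwd():
            g = out.grad
            gamma._accumulate((g * xhat).sum(axis=axes))
            beta._accumulate(g.sum(axis=axes))
            gxhat = g * gamma.data.reshape(shape)
            # standard BN backward through batch statistics
            gvar = (gxhat * (x.data - mean.reshape(shape))).sum(axis=axes) * (-0.5) * inv_std**3
            gmean = (-gxhat * inv_std.reshape(shape)).sum(axis=axes) + gvar * (-2.0 / m) * (
                x.data - mean.reshape(shape)
            ).sum(axis=axes)
            gx = (
                gxhat * inv_std.reshape(shape)
                + (gvar.reshape(shape) * 2.0 / m) * (x.data - mean.reshape(shape))
                + gmean.reshape(shape) / m
            )
            x._accumulate(gx)

        out._backward = _bwd
        return out
    inv_std = 1.0 / np.sqrt(running_var + eps)
    scale = gamma.data * inv_std
    shift = beta.data - running_mean * scale
    out = _node(x.data * scale.reshape(shape) + shift.reshape(shape), (x, gamma, beta))

    def _bwd():
        g = out.grad
        gamma._accumulate((g * (x.data - running_mean.reshape(shape)) * inv_std.reshape(shape)).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        x._accumulate(g * scale.reshape(shape))

    out._backward = _bwd
    return out


# -- losses --------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = _node(p, (x,))

    def _bwd():
        g = out.grad
        dot = (g * p).sum(axis=axis, keepdims=True)
        x._accumulate(p * (g - dot))

    out._backward = _bwd
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels against softmax(logits); (N, K) input."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    out = _node(np.asarray(loss, dtype=logits.data.dtype), (logits,))

    def _bwd():
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate(out.grad * p / n)

    out._backward = _bwd
    return out
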