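"""A small reverse-mode automatic differentiation engine over numpy arrays.

This is the package's compute backbone for building and training the
segmentation networks.  It provides exactly the operator set the
encoder-decoder architectures need -- 2D (transposed) convolution, pooling,
batch normalisation, channel-axis 1D convolution, elementwise nonlinearities,
axis reductions/permutations, and a fused weighted softmax cross-entropy --
each with a hand-written backward pass.  Everything runs in float64 on a
single CPU and is bit-deterministic: identical seeds yield identical
training trajectories.

Gradient correctness of every operator is pinned by central finite-difference
tests in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "tanh",
    "scale",
    "reshape",
    "transpose",
    "concat",
    "mean_axes",
    "max_axes",
    "conv2d",
    "conv_transpose2d",
    "maxpool2d",
    "upsample_nearest2",
    "batchnorm2d",
    "channel_conv1d",
    "softmax",
    "weighted_softmax_cross_entropy",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward_fn = _backward_fn

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ----------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward_fn is not None:
                node._backward_fn(node.grad)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- convenience operators --------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return scale(self, -1.0)

    def __sub__(self, other):
        return add(self, scale(as_tensor(other), -1.0))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward_fn) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=tuple(parents) if req else (),
                  _backward_fn=backward_fn if req else None)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    out_data = a.data * s

    def backward(g):
        a.accumulate(g * s)

    return _make(out_data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        a.accumulate(g * mask)

    return _make(out_data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward(g):
        a.accumulate(g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        a.accumulate(g.reshape(old))

    return _make(out_data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = a.data.transpose(axes)

    def backward(g):
        a.accumulate(g.transpose(inv))

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(p)

    return _make(out_data, tensors, backward)


def mean_axes(a: Tensor, axes, keepdims: bool = False) -> Tensor:
    axes = tuple(axes)
    out_data = a.data.mean(axis=axes, keepdims=keepdims)
    count = int(np.prod([a.data.shape[ax] for ax in axes]))

    def backward(g):
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axes)
        a.accumulate(np.broadcast_to(gg, a.data.shape) / count)

    return _make(out_data, (a,), backward)


def max_axes(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    out_full = a.data.max(axis=axis, keepdims=True)
    mask = a.data == out_full
    counts = mask.sum(axis=axis, keepdims=True)
    out_data = out_full if keepdims else np.squeeze(out_full, axis=axis)

    def backward(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        a.accumulate(mask * (gg / counts))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# convolution / pooling (NCHW layout)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2D cross-correlation: ``x`` (N,C,H,W) with ``w`` (O,C,kh,kw)."""
    kh, kw = w.data.shape[2], w.data.shape[3]
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = sliding_window_view(xd, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out_data = np.einsum("nchwkl,ockl->nohw", cols, w.data, optimize=True)
    parents = [x, w]
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
        parents.append(b)
    n, _, ho, wo = out_data.shape
    in_h, in_w = x.data.shape[2], x.data.shape[3]

    def backward(g):
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w.accumulate(np.einsum("nohw,nchwkl->ockl", g, cols, optimize=True))
        if x.requires_grad:
            gcols = np.einsum("nohw,ockl->nchwkl", g, w.data, optimize=True)
            gxp = np.zeros_like(xd)
            for k in range(kh):
                for l in range(kw):
                    gxp[:, :, k:k + stride * ho:stride, l:l + stride * wo:stride] += \
                        gcols[:, :, :, :, k, l]
            if padding:
                gxp = gxp[:, :, padding:padding + in_h, padding:padding + in_w]
            x.accumulate(gxp)

    return _make(out_data, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b=None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling).

    ``x`` is (N,C,H,W), ``w`` is (C,O,2,2); output is (N,O,2H,2W).
    """
    n, c, h, wdt = x.data.shape
    o = w.data.shape[1]
    t = np.einsum("nchw,cokl->nohwkl", x.data, w.data, optimize=True)
    out_data = t.transpose(0, 1, 2, 4, 3, 5).reshape(n, o, 2 * h, 2 * wdt)
    parents = [x, w]
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
        parents.append(b)

    def backward(g):
        gr = g.reshape(n, o, h, 2, wdt, 2).transpose(0, 1, 2, 4, 3, 5)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w.accumulate(np.einsum("nchw,nohwkl->cokl", x.data, gr, optimize=True))
        if x.requires_grad:
            x.accumulate(np.einsum("nohwkl,cokl->nchw", gr, w.data, optimize=True))

    return _make(out_data, parents, backward)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; ties share the gradient equally."""
    n, c, h, w = x.data.shape
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = r.max(axis=(3, 5))
    mask = r == out_data[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5), keepdims=True)

    def backward(g):
        gr = mask * (g[:, :, :, None, :, None] / counts)
        x.accumulate(gr.reshape(n, c, h, w))

    return _make(out_data, (x,), backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    n, c, h, w = x.data.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        x.accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over an (N,C,H,W) tensor.

    Batch statistics during training (running statistics updated in place
    with exponential ``momentum``), running statistics at inference.
    """
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = xd.shape[0] * xd.shape[2] * xd.shape[3]

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gamma.data[None, :, None, None]
            if training:
                # full backward through the batch statistics
                s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gxhat - s1 / m - xhat * s2 / m) * inv_std[None, :, None, None]
            else:
                gx = gxhat * inv_std[None, :, None, None]
            x.accumulate(gx)

    return _make(out_data, (x, gamma, beta), backward)


def channel_conv1d(v: Tensor, w: Tensor) -> Tensor:
    """1D cross-correlation of an (N, C) channel vector batch with a length-k
    kernel, zero same-padding at the channel ends."""
    k = w.data.shape[0]
    p = k // 2
    n, c = v.data.shape
    vp = np.pad(v.data, ((0, 0), (p, p)))
    windows = sliding_window_view(vp, k, axis=1)  # (N, C, k)
    out_data = windows @ w.data

    def backward(g):
        if w.requires_grad:
            w.accumulate(np.einsum("nc,nck->k", g, windows, optimize=True))
        if v.requires_grad:
            gvp = np.zeros_like(vp)
            for j in range(k):
                gvp[:, j:j + c] += g * w.data[j]
            v.accumulate(gvp[:, p:p + c])

    return _make(out_data, (v, w), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax on a plain numpy array."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_softmax_cross_entropy(
    logits: Tensor,
    target: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> Tensor:
    """Fused class-weighted categorical cross-entropy over pixels.

    ``logits`` is (N, C, H, W); ``target`` is an (N, H, W) integer class map.
    The per-pixel loss ``-w_t * log(p_t)`` is averaged over all pixels, the
    predicted probability being clamped at 1e-12.
    """
    target = np.asarray(target)
    n, c, h, w = logits.data.shape
    if target.shape != (n, h, w):
        raise ValueError(f"target shape {target.shape} does not match logits {logits.data.shape}")
    p = softmax(logits.data, axis=1)
    idx = np.expand_dims(target, 1)
    pt = np.take_along_axis(p, idx, axis=1)[:, 0]
    if class_weights is None:
        wmap = np.ones_like(pt)
    else:
        wmap = np.asarray(class_weights, dtype=np.float64)[target]
    npix = n * h * w
    loss = float((-wmap * np.log(np.clip(pt, 1e-12, None))).sum() / npix)

    def backward(g):
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, idx, 1.0, axis=1)
        glogits = (p - onehot) * wmap[:, None] * (float(g) / npix)
        logits.accumulate(glogits)

    return _make(np.asarray(loss), (logits,), backward)
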