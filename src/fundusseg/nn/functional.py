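"""Differentiable operations for the segmentation networks (NHWC layout)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "add",
    "sub",
    "mul",
    "div",
    "power",
    "tsum",
    "relu",
    "sigmoid",
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "mean_pool2d",
    "concat",
    "upsample_nearest",
    "dropout",
    "softmax",
    "softmax_cross_entropy",
]


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- elementwise ---------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return Tensor(out, _parents=(a, b), _backward=backward)


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data - b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)

    return Tensor(out, _parents=(a, b), _backward=backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return Tensor(out, _parents=(a, b), _backward=backward)


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data / b.data

    def backward(g):
        ga = _unbroadcast(g / b.data, a.shape)
        gb = _unbroadcast(-g * a.data / (b.data ** 2), b.shape)
        return ga, gb

    return Tensor(out, _parents=(a, b), _backward=backward)


def power(a, exponent: float):
    a = _as_tensor(a)
    out = a.data ** exponent

    def backward(g):
        return (g * exponent * a.data ** (exponent - 1),)

    return Tensor(out, _parents=(a,), _backward=backward)


def tsum(a, axis=None):
    """Sum reduction (name avoids shadowing the builtin)."""
    a = _as_tensor(a)
    out = a.data.sum(axis=axis)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return Tensor(out, _parents=(a,), _backward=backward)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0
    out = np.where(mask, a.data, 0)

    def backward(g):
        return (g * mask,)

    return Tensor(out, _parents=(a,), _backward=backward)


def sigmoid(a):
    a = _as_tensor(a)
    out = np.empty_like(a.data)
    pos = a.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    e = np.exp(a.data[~pos])
    out[~pos] = e / (1.0 + e)

    def backward(g):
        return (g * out * (1.0 - out),)

    return Tensor(out, _parents=(a,), _backward=backward)


# -- convolutions ---------------------------------------------------------

def conv2d(x, w, b):
    """Same-padding stride-1 convolution.

    ``x``: (N, H, W, Cin); ``w``: (kh, kw, Cin, F); ``b``: (F,).
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    N, H, W_, C = x.shape
    kh, kw, Cin, F = w.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel {Cin}")
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    else:
        xp = x.data
    # (N, H, W, C, kh, kw) -> (N*H*W, kh*kw*C)
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        N * H * W_, kh * kw * C
    )
    w2 = w.data.reshape(kh * kw * C, F)
    out = (cols @ w2 + b.data).reshape(N, H, W_, F)

    def backward(g):
        g2 = g.reshape(N * H * W_, F)
        gw = (cols.T @ g2).reshape(kh, kw, C, F)
        gb = g2.sum(axis=0)
        gcols = (g2 @ w2.T).reshape(N, H, W_, kh, kw, C)
        gxp = np.zeros((N, H + 2 * ph, W_ + 2 * pw, C), dtype=g.dtype)
        for a_ in range(kh):
            for b_ in range(kw):
                gxp[:, a_ : a_ + H, b_ : b_ + W_, :] += gcols[:, :, :, a_, b_, :]
        gx = gxp[:, ph : ph + H, pw : pw + W_, :] if (ph or pw) else gxp
        return gx, gw, gb

    return Tensor(out, _parents=(x, w, b), _backward=backward)


def conv_transpose2d(x, w, b):
    """2x2 stride-2 transposed convolution (doubles H and W).

    ``w``: (2, 2, Cin, F).
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    N, H, W_, C = x.shape
    kh, kw, Cin, F = w.shape
    if (kh, kw) != (2, 2):
        raise ValueError("conv_transpose2d implements the 2x2 stride-2 case only")
    if Cin != C:
        raise ValueError(f"conv_transpose2d channel mismatch: {C} vs {Cin}")
    xm = x.data.reshape(N * H * W_, C)
    w2 = w.data.transpose(2, 0, 1, 3).reshape(C, kh * kw * F)
    out = (xm @ w2).reshape(N, H, W_, kh, kw, F)
    out = out.transpose(0, 1, 3, 2, 4, 5).reshape(N, H * kh, W_ * kw, F) + b.data

    def backward(g):
        gcols = (
            g.reshape(N, H, kh, W_, kw, F)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(N * H * W_, kh * kw * F)
        )
        gw = (xm.T @ gcols).reshape(C, kh, kw, F).transpose(1, 2, 0, 3)
        gb = g.sum(axis=(0, 1, 2))
        gx = (gcols @ w2.T).reshape(N, H, W_, C)
        return gx, gw, gb

    return Tensor(out, _parents=(x, w, b), _backward=backward)


def max_pool2d(x):
    """2x2 stride-2 max pooling; H and W must be even."""
    x = _as_tensor(x)
    N, H, W_, C = x.shape
    if H % 2 or W_ % 2:
        raise ValueError("max_pool2d requires even spatial dimensions")
    r = x.data.reshape(N, H // 2, 2, W_ // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
    r = r.reshape(N, H // 2, W_ // 2, C, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((N, H // 2, W_ // 2, C, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (
            gr.reshape(N, H // 2, W_ // 2, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(N, H, W_, C)
        )
        return (gx,)

    return Tensor(out, _parents=(x,), _backward=backward)


def mean_pool2d_array(x: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool a plain array by an integer factor (image-pyramid helper)."""
    if x.ndim == 3:
        x = x[None]
        squeeze = True
    else:
        squeeze = False
    N, H, W_, C = x.shape
    out = x.reshape(N, H // factor, factor, W_ // factor, factor, C).mean(axis=(2, 4))
    return out[0] if squeeze else out


def mean_pool2d(x):
    """Differentiable 2x2 mean pooling."""
    x = _as_tensor(x)
    N, H, W_, C = x.shape
    out = x.data.reshape(N, H // 2, 2, W_ // 2, 2, C).mean(axis=(2, 4))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) / 4.0
        return (gx,)

    return Tensor(out, _parents=(x,), _backward=backward)


def concat(tensors):
    """Concatenate along the channel axis."""
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[-1] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=-1)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=-1))

    return Tensor(out, _parents=tuple(tensors), _backward=backward)


def upsample_nearest(x, factor: int):
    x = _as_tensor(x)
    N, H, W_, C = x.shape
    out = np.repeat(np.repeat(x.data, factor, axis=1), factor, axis=2)

    def backward(g):
        gx = g.reshape(N, H, factor, W_, factor, C).sum(axis=(2, 4))
        return (gx,)

    return Tensor(out, _parents=(x,), _backward=backward)


def dropout(x, rate: float, rng: np.random.Generator, training: bool):
    """Inverted dropout; identity when not training or rate == 0."""
    x = _as_tensor(x)
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep

    def backward(g):
        return (g * mask,)

    return Tensor(x.data * mask, _parents=(x,), _backward=backward)


# -- heads and objectives -------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain-array softmax (inference path; no graph)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits, onehot: np.ndarray):
    """Mean per-pixel categorical cross-entropy with fused softmax.

    ``logits``: (N, H, W, K) tensor; ``onehot``: same-shape plain array.
    """
    logits = _as_tensor(logits)
    p = softmax(logits.data, axis=-1)
    n_pix = int(np.prod(logits.shape[:-1]))
    eps = np.finfo(p.dtype).tiny
    loss = -(onehot * np.log(p + eps)).sum() / n_pix

    def backward(g):
        return ((p - onehot) * (g / n_pix),)

    return Tensor(loss, _parents=(logits,), _backward=backward)
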