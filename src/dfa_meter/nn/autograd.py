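"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the segmentation networks need are provided: broadcasted
addition, ReLU/ReLU6, dense and depthwise 2-D convolution (stride, padding,
dilation), batch normalization, bilinear resizing and adaptive average
pooling (both expressed as separable linear maps), 2x2 max pooling, channel
concatenation, and softmax cross-entropy.  Gradients are accumulated on a
tape and released by a topological backward pass.

All computation is float32.  Convolutions use an im2col strided view plus a
batched matmul; their input gradients are scattered back with one strided
add per kernel tap, which keeps the backward pass fully vectorized.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            # free graph references as we go
            t._backward = None
            t._parents = ()


class Parameter(Tensor):
    """Trainable tensor (always requires grad)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _make(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    data = np.maximum(x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    return _make(data, (x,), backward)


def relu6(x: Tensor) -> Tensor:
    data = np.clip(x.data, 0.0, 6.0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * ((x.data > 0) & (x.data < 6)))

    return _make(data, (x,), backward)


def _conv_geometry(H, W, k, stride, pad, dil):
    eff = dil * (k - 1) + 1
    oh = (H + 2 * pad - eff) // stride + 1
    ow = (W + 2 * pad - eff) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError("convolution output would be empty")
    return oh, ow


def _im2col_view(xp, k, stride, dil, oh, ow):
    """Strided (B, C, k, k, oh, ow) window view of padded input ``xp``."""
    B, C, Hp, Wp = xp.shape
    s0, s1, s2, s3 = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(B, C, k, k, oh, ow),
        strides=(s0, s1, s2 * dil, s3 * dil, s2 * stride, s3 * stride),
        writeable=False,
    )


def _pad2d(x, pad):
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _scatter_cols(dview, shape, pad, k, stride, dil, oh, ow):
    """Inverse of the im2col view: strided add of (B,C,k,k,oh,ow) grads."""
    B, C, H, W = shape
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            dxp[
                :,
                :,
                i * dil : i * dil + oh * stride : stride,
                j * dil : j * dil + ow * stride : stride,
            ] += dview[:, :, i, j]
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, w: Tensor, b, stride=1, padding=0, dilation=1) -> Tensor:
    """Dense 2-D convolution; ``w`` has shape (Cout, Cin, k, k)."""
    B, C, H, W = x.data.shape
    Cout, Cin, k, _ = w.data.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cin}")
    oh, ow = _conv_geometry(H, W, k, stride, padding, dilation)
    xp = _pad2d(x.data, padding)
    view = _im2col_view(xp, k, stride, dilation, oh, ow)
    cols = view.reshape(B, C * k * k, oh * ow)
    wmat = w.data.reshape(Cout, C * k * k)
    out = np.matmul(wmat, cols).reshape(B, Cout, oh, ow)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        gmat = g.reshape(B, Cout, oh * ow)
        if w.requires_grad:
            dw = np.einsum("bol,bkl->ok", gmat, cols, optimize=True)
            w._accumulate(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, gmat)  # (B, C*k*k, L)
            dview = dcols.reshape(B, C, k, k, oh, ow)
            x._accumulate(
                _scatter_cols(dview, x.data.shape, padding, k, stride, dilation, oh, ow)
            )

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b, stride=1, padding=0, dilation=1) -> Tensor:
    """Depthwise 2-D convolution; ``w`` has shape (C, k, k)."""
    B, C, H, W = x.data.shape
    Cw, k, _ = w.data.shape
    if Cw != C:
        raise ValueError(f"depthwise channel mismatch: input {C}, weight {Cw}")
    oh, ow = _conv_geometry(H, W, k, stride, padding, dilation)
    xp = _pad2d(x.data, padding)
    view = _im2col_view(xp, k, stride, dilation, oh, ow)
    out = np.einsum("bcijhw,cij->bchw", view, w.data, optimize=True)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bcijhw,bchw->cij", view, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dview = np.einsum("bchw,cij->bcijhw", g, w.data, optimize=True)
            x._accumulate(
                _scatter_cols(dview, x.data.shape, padding, k, stride, dilation, oh, ow)
            )

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean,
    running_var,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if training:
                B, C, H, W = x.data.shape
                n = B * H * W
                sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                scale = (gamma.data * inv_std)[None, :, None, None]
                dx = scale * (g - sum_g / n - xhat * sum_gx / n)
            else:
                dx = g * (gamma.data * inv_std)[None, :, None, None]
            x._accumulate(dx.astype(np.float32))

    return _make(out.astype(np.float32), (x, gamma, beta), backward)


_resize_cache: dict = {}


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) align-corners bilinear interpolation matrix."""
    key = ("bilinear", n_in, n_out)
    if key not in _resize_cache:
        M = np.zeros((n_out, n_in), dtype=np.float32)
        if n_out == 1 or n_in == 1:
            M[:, :] = 1.0 / n_in
        else:
            src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
            lo = np.floor(src).astype(int)
            hi = np.minimum(lo + 1, n_in - 1)
            frac = (src - lo).astype(np.float32)
            M[np.arange(n_out), lo] += 1.0 - frac
            M[np.arange(n_out), hi] += frac
        _resize_cache[key] = M
    return _resize_cache[key]


def _avg_pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) adaptive average-pooling matrix (floor/ceil bins)."""
    key = ("avg", n_in, n_out)
    if key not in _resize_cache:
        M = np.zeros((n_out, n_in), dtype=np.float32)
        for i in range(n_out):
            lo = (i * n_in) // n_out
            hi = -(-((i + 1) * n_in) // n_out)  # ceil division
            M[i, lo:hi] = 1.0 / (hi - lo)
        _resize_cache[key] = M
    return _resize_cache[key]


def _separable_linear(x: Tensor, Mh: np.ndarray, Mw: np.ndarray) -> Tensor:
    """Apply row/column linear maps: out[b,c] = Mh @ x[b,c] @ Mw.T."""
    data = np.einsum("ij,bcjk,lk->bcil", Mh, x.data, Mw, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.einsum("ji,bcjk,kl->bcil", Mh, g, Mw, optimize=True))

    return _make(data, (x,), backward)


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear (align-corners) resize of a (B, C, H, W) tensor."""
    B, C, H, W = x.data.shape
    if (H, W) == (out_h, out_w):
        return x
    return _separable_linear(x, _bilinear_matrix(H, out_h), _bilinear_matrix(W, out_w))


def adaptive_avg_pool2d(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Adaptive average pooling of a (B, C, H, W) tensor to (out_h, out_w)."""
    B, C, H, W = x.data.shape
    return _separable_linear(x, _avg_pool_matrix(H, out_h), _avg_pool_matrix(W, out_w))


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (even spatial dims required)."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2d requires even spatial dimensions")
    view = x.data.reshape(B, C, H // 2, 2, W // 2, 2)
    flat = view.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
            dx = (
                dflat.reshape(B, C, H // 2, W // 2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(B, C, H, W)
            )
            x._accumulate(dx)

    return _make(out, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def cross_entropy(logits: Tensor, labels) -> Tensor:
    """Mean per-pixel softmax cross-entropy.

    ``logits``: (B, C, H, W); ``labels``: (B, H, W) integer class indices.
    """
    labels = np.asarray(labels)
    B, C, H, W = logits.data.shape
    if labels.shape != (B, H, W):
        raise ValueError(f"labels shape {labels.shape} != {(B, H, W)}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    softmax = ez / ez.sum(axis=1, keepdims=True)
    n = B * H * W
    onehot_idx = (
        np.arange(B)[:, None, None],
        labels,
        np.arange(H)[None, :, None],
        np.arange(W)[None, None, :],
    )
    picked = softmax[onehot_idx[0], labels, onehot_idx[2], onehot_idx[3]]
    loss = -np.log(np.maximum(picked, 1e-12)).mean()
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite cross-entropy loss")

    def backward(g):
        if logits.requires_grad:
            d = softmax.copy()
            d[onehot_idx[0], labels, onehot_idx[2], onehot_idx[3]] -= 1.0
            logits._accumulate(d * (float(g) / n))

    return _make(np.float32(loss), (logits,), backward)
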