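"""Layer primitives for the numpy network engine.

Each layer object is a pure hyperparameter spec: it knows its trainable
parameter shapes, how shapes propagate, and how to run forward (and,
for the layers the tiny trainable family uses, backward).  Tensors are
``(N, C, H, W)`` float32 with N the batch axis — for an imaging-series
exam, N is the slice axis.  The composite DenseNet-style blocks are
forward-only (inference); backpropagation is implemented exactly for
the primitives the desk-scale models train with.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "GlobalMaxPool",
    "SeriesMax",
    "Flatten",
    "BatchNorm2d",
    "DenseBlock",
    "Transition",
]

_F32 = np.float32


def _pair_out(size: int, k: int, stride: int, pad: int) -> int:
    out = (size + 2 * pad - k) // stride + 1
    if out < 1:
        raise ValueError(f"spatial size {size} too small for k={k}, stride={stride}, pad={pad}")
    return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int, pad_value: float = 0.0):
    """(N,C,H,W) -> patches (N, C*k*k, oh*ow)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=pad_value)
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, :, :]  # (N,C,oh,ow,k,k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols6[:, :, i, j]
    return out[:, :, pad : pad + h, pad : pad + w]


class Conv2d:
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1, padding: int = 0, bias: bool = True):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.stride, self.padding, self.bias = stride, padding, bias

    def param_shapes(self, in_shape):
        shapes = {"weight": (self.out_ch, self.in_ch, self.k, self.k)}
        if self.bias:
            shapes["bias"] = (self.out_ch,)
        return shapes

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.in_ch:
            raise ValueError(f"Conv2d expected {self.in_ch} channels, got {c}")
        return (self.out_ch, _pair_out(h, self.k, self.stride, self.padding),
                _pair_out(w, self.k, self.stride, self.padding))

    def forward(self, x, p):
        cols, oh, ow = _im2col(x, self.k, self.stride, self.padding)
        wmat = p["weight"].reshape(self.out_ch, -1)
        y = np.einsum("of,nfl->nol", wmat, cols, optimize=True)
        if self.bias:
            y = y + p["bias"][None, :, None]
        y = y.reshape(x.shape[0], self.out_ch, oh, ow)
        return y.astype(_F32, copy=False), (x.shape, cols)

    def backward(self, dy, cache, p):
        x_shape, cols = cache
        n = x_shape[0]
        dyf = dy.reshape(n, self.out_ch, -1)
        wmat = p["weight"].reshape(self.out_ch, -1)
        dw = np.einsum("nol,nfl->of", dyf, cols, optimize=True).reshape(p["weight"].shape)
        grads = {"weight": dw.astype(_F32)}
        if self.bias:
            grads["bias"] = dyf.sum(axis=(0, 2)).astype(_F32)
        dcols = np.einsum("of,nol->nfl", wmat, dyf, optimize=True)
        dx = _col2im(dcols, x_shape, self.k, self.stride, self.padding)
        return dx.astype(_F32, copy=False), grads


class Linear:
    def __init__(self, in_f: int, out_f: int, bias: bool = True):
        self.in_f, self.out_f, self.bias = in_f, out_f, bias

    def param_shapes(self, in_shape):
        shapes = {"weight": (self.out_f, self.in_f)}
        if self.bias:
            shapes["bias"] = (self.out_f,)
        return shapes

    def out_shape(self, in_shape):
        if in_shape != (self.in_f,):
            raise ValueError(f"Linear expected ({self.in_f},), got {in_shape}")
        return (self.out_f,)

    def forward(self, x, p):
        y = x @ p["weight"].T
        if self.bias:
            y = y + p["bias"]
        return y.astype(_F32, copy=False), x

    def backward(self, dy, cache, p):
        x = cache
        grads = {"weight": (dy.T @ x).astype(_F32)}
        if self.bias:
            grads["bias"] = dy.sum(axis=0).astype(_F32)
        return (dy @ p["weight"]).astype(_F32, copy=False), grads


class ReLU:
    def param_shapes(self, in_shape):
        return {}

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, p):
        return np.maximum(x, 0), x > 0

    def backward(self, dy, cache, p):
        return dy * cache, {}


class Sigmoid:
    def param_shapes(self, in_shape):
        return {}

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, p):
        y = 1.0 / (1.0 + np.exp(-x))
        return y.astype(_F32, copy=False), y

    def backward(self, dy, cache, p):
        y = cache
        return (dy * y * (1 - y)).astype(_F32, copy=False), {}


class MaxPool2d:
    def __init__(self, k: int, stride: int, padding: int = 0):
        self.k, self.stride, self.padding = k, stride, padding

    def param_shapes(self, in_shape):
        return {}

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, _pair_out(h, self.k, self.stride, self.padding),
                _pair_out(w, self.k, self.stride, self.padding))

    def forward(self, x, p):
        cols, oh, ow = _im2col(x, self.k, self.stride, self.padding, pad_value=-np.inf)
        n, c = x.shape[:2]
        cols = cols.reshape(n, c, self.k * self.k, oh * ow)
        idx = cols.argmax(axis=2)
        y = np.take_along_axis(cols, idx[:, :, None, :], axis=2)[:, :, 0, :]
        return y.reshape(n, c, oh, ow).astype(_F32, copy=False), (x.shape, idx, oh, ow)

    def backward(self, dy, cache, p):
        x_shape, idx, oh, ow = cache
        n, c = x_shape[:2]
        dcols = np.zeros((n, c, self.k * self.k, oh * ow), dtype=_F32)
        np.put_along_axis(dcols, idx[:, :, None, :], dy.reshape(n, c, 1, oh * ow), axis=2)
        dx = _col2im(dcols.reshape(n, c * self.k * self.k, oh * ow), x_shape,
                     self.k, self.stride, self.padding)
        return dx.astype(_F32, copy=False), {}


class AvgPool2d:
    def __init__(self, k: int, stride: int):
        self.k, self.stride = k, stride

    def param_shapes(self, in_shape):
        return {}

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, _pair_out(h, self.k, self.stride, 0), _pair_out(w, self.k, self.stride, 0))

    def forward(self, x, p):
        cols, oh, ow = _im2col(x, self.k, self.stride, 0)
        n, c = x.shape[:2]
        y = cols.reshape(n, c, self.k * self.k, oh * ow).mean(axis=2)
        return y.reshape(n, c, oh, ow).astype(_F32, copy=False), (x.shape, oh, ow)

    def backward(self, dy, cache, p):
        x_shape, oh, ow = cache
        n, c = x_shape[:2]
        share = np.broadcast_to(dy.reshape(n, c, 1, oh * ow) / (self.k * self.k),
                                (n, c, self.k * self.k, oh * ow))
        dx = _col2im(share.reshape(n, c * self.k * self.k, oh * ow).astype(_F32),
                     x_shape, self.k, self.stride, 0)
        return dx, {}


class GlobalAvgPool:
    """Spatial mean: (N,C,H,W) -> (N,C)."""

    def param_shapes(self, in_shape):
        return {}

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c,)

    def forward(self, x, p):
        return x.mean(axis=(2, 3)).astype(_F32, copy=False), x.shape

    def backward(self, dy, cache, p):
        n, c, h, w = cache
        dx = np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w))
        return dx.astype(_F32), {}


class GlobalMaxPool:
    """Spatial max: (N,C,H,W) -> (N,C); gradient routes to the peak location.

    Retains focal (lesion-like) evidence that a spatial average would
    dilute — the right reduction when the label depends on whether a
    localized finding exists anywhere in the image.
    """

    def param_shapes(self, in_shape):
        return {}

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c,)

    def forward(self, x, p):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        idx = flat.argmax(axis=2)
        y = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
        return y.astype(_F32, copy=False), (x.shape, idx)

    def backward(self, dy, cache, p):
        x_shape, idx = cache
        n, c, h, w = x_shape
        dflat = np.zeros((n, c, h * w), dtype=_F32)
        np.put_along_axis(dflat, idx[:, :, None], dy[:, :, None], axis=2)
        return dflat.reshape(x_shape), {}


class SeriesMax:
    """Max over the batch/series axis: (N,C) -> (1,C); gradient routes to argmax."""

    def param_shapes(self, in_shape):
        return {}

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, p):
        idx = x.argmax(axis=0)
        return x[idx, np.arange(x.shape[1])][None, :], (x.shape, idx)

    def backward(self, dy, cache, p):
        x_shape, idx = cache
        dx = np.zeros(x_shape, dtype=_F32)
        dx[idx, np.arange(x_shape[1])] = dy[0]
        return dx, {}


class Flatten:
    def param_shapes(self, in_shape):
        return {}

    def out_shape(self, in_shape):
        n = 1
        for d in in_shape:
            n *= d
        return (n,)

    def forward(self, x, p):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dy, cache, p):
        return dy.reshape(cache), {}


class BatchNorm2d:
    """Inference-mode batch normalization (running stats at their init values).

    The affine scale and shift are trainable parameters and therefore
    counted and serialized; the running mean/variance stay at 0/1 since
    the reference architectures are never trained here.
    """

    EPS = 1e-5

    def __init__(self, ch: int):
        self.ch = ch

    def param_shapes(self, in_shape):
        return {"weight": (self.ch,), "bias": (self.ch,)}

    def out_shape(self, in_shape):
        if in_shape[0] != self.ch:
            raise ValueError(f"BatchNorm2d expected {self.ch} channels, got {in_shape[0]}")
        return in_shape

    def forward(self, x, p):
        scale = (p["weight"] / np.sqrt(1.0 + self.EPS)).astype(_F32)
        return x * scale[None, :, None, None] + p["bias"][None, :, None, None], None

    def backward(self, dy, cache, p):
        raise NotImplementedError("BatchNorm2d is inference-only in this engine")


class DenseBlock:
    """Densely connected block (bottleneck layers), forward-only.

    Each sub-layer maps the concatenation of all previous features
    through BN-ReLU-Conv1x1(bn_size*growth)-BN-ReLU-Conv3x3(growth) and
    appends its output, growing the channel count by ``growth``.
    """

    def __init__(self, in_ch: int, n_layers: int, growth: int = 32, bn_size: int = 4):
        self.in_ch, self.n_layers = in_ch, n_layers
        self.growth, self.bn_size = growth, bn_size

    def _sub(self, j: int):
        return self.in_ch + j * self.growth, self.bn_size * self.growth

    def param_shapes(self, in_shape):
        shapes = {}
        for j in range(self.n_layers):
            cin, mid = self._sub(j)
            shapes[f"l{j:02d}.norm1.weight"] = (cin,)
            shapes[f"l{j:02d}.norm1.bias"] = (cin,)
            shapes[f"l{j:02d}.conv1.weight"] = (mid, cin, 1, 1)
            shapes[f"l{j:02d}.norm2.weight"] = (mid,)
            shapes[f"l{j:02d}.norm2.bias"] = (mid,)
            shapes[f"l{j:02d}.conv2.weight"] = (self.growth, mid, 3, 3)
        return shapes

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.in_ch:
            raise ValueError(f"DenseBlock expected {self.in_ch} channels, got {c}")
        return (c + self.n_layers * self.growth, h, w)

    def forward(self, x, p):
        bn = BatchNorm2d
        feats = x
        for j in range(self.n_layers):
            cin, mid = self._sub(j)
            s1 = (p[f"l{j:02d}.norm1.weight"] / np.sqrt(1 + bn.EPS)).astype(_F32)
            h = feats * s1[None, :, None, None] + p[f"l{j:02d}.norm1.bias"][None, :, None, None]
            h = np.maximum(h, 0)
            h = np.einsum("oc,nchw->nohw", p[f"l{j:02d}.conv1.weight"][:, :, 0, 0], h, optimize=True)
            s2 = (p[f"l{j:02d}.norm2.weight"] / np.sqrt(1 + bn.EPS)).astype(_F32)
            h = h * s2[None, :, None, None] + p[f"l{j:02d}.norm2.bias"][None, :, None, None]
            h = np.maximum(h, 0)
            cols, oh, ow = _im2col(h.astype(_F32), 3, 1, 1)
            wmat = p[f"l{j:02d}.conv2.weight"].reshape(self.growth, -1)
            new = np.einsum("of,nfl->nol", wmat, cols, optimize=True)
            new = new.reshape(h.shape[0], self.growth, oh, ow)
            feats = np.concatenate([feats, new.astype(_F32)], axis=1)
        return feats, None

    def backward(self, dy, cache, p):
        raise NotImplementedError("DenseBlock is inference-only in this engine")


class Transition:
    """BN-ReLU-Conv1x1 channel compression followed by 2x2 average pooling."""

    def __init__(self, in_ch: int, out_ch: int):
        self.in_ch, self.out_ch = in_ch, out_ch

    def param_shapes(self, in_shape):
        return {
            "norm.weight": (self.in_ch,),
            "norm.bias": (self.in_ch,),
            "conv.weight": (self.out_ch, self.in_ch, 1, 1),
        }

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.in_ch:
            raise ValueError(f"Transition expected {self.in_ch} channels, got {c}")
        return (self.out_ch, h // 2, w // 2)

    def forward(self, x, p):
        s = (p["norm.weight"] / np.sqrt(1 + BatchNorm2d.EPS)).astype(_F32)
        h = np.maximum(x * s[None, :, None, None] + p["norm.bias"][None, :, None, None], 0)
        h = np.einsum("oc,nchw->nohw", p["conv.weight"][:, :, 0, 0], h, optimize=True).astype(_F32)
        n, c, hh, ww = h.shape
        h = h[:, :, : hh - hh % 2, : ww - ww % 2]
        y = h.reshape(n, c, hh // 2, 2, ww // 2, 2).mean(axis=(3, 5))
        return y.astype(_F32, copy=False), None

    def backward(self, dy, cache, p):
        raise NotImplementedError("Transition is inference-only in this engine")
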