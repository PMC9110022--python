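"""Minimal reverse-mode autodiff and CNN layers on numpy.

This module provides exactly the operations the fusion network and the
patch classifier need: 2-D convolution and transposed convolution with
Keras-style ``same``/``valid`` padding, average/max pooling, channel
concatenation, dense layers, ReLU/sigmoid, dropout, and the Adam and
Adadelta optimizers.  Arrays are ``float32`` in NCHW layout; gradients are
computed by reverse-mode accumulation over a dynamically built graph.

It is deliberately small: no broadcasting-general ops, no GPU, no graph
optimization.  Everything is deterministic given the numpy Generator used
to initialize weights and drive dropout.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


# ---------------------------------------------------------------------------
# autodiff core
# ---------------------------------------------------------------------------

class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Reverse-mode accumulation from this (scalar) tensor."""
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def _track(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward, track) -> Tensor:
    if track:
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# -- elementwise / reduction ops --------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    track = _track(a, b)

    def bwd(g):
        a._accum(g)
        b._accum(g)
    return _make(a.data + b.data, (a, b), bwd, track)


def sub(a: Tensor, b: Tensor) -> Tensor:
    track = _track(a, b)

    def bwd(g):
        a._accum(g)
        b._accum(-g)
    return _make(a.data - b.data, (a, b), bwd, track)


def mul(a: Tensor, b: Tensor) -> Tensor:
    track = _track(a, b)

    def bwd(g):
        a._accum(g * b.data)
        b._accum(g * a.data)
    return _make(a.data * b.data, (a, b), bwd, track)


def scale(a: Tensor, s: float) -> Tensor:
    def bwd(g):
        a._accum(g * s)
    return _make(a.data * s, (a,), bwd, _track(a))


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size

    def bwd(g):
        a._accum(np.full_like(a.data, g / n))
    return _make(a.data.mean(), (a,), bwd, _track(a))


def channel_mean(a: Tensor) -> Tensor:
    """Mean over the channel axis of an NCHW tensor -> (N, 1, H, W)."""
    c = a.data.shape[1]

    def bwd(g):
        a._accum(np.broadcast_to(g / c, a.data.shape))
    return _make(a.data.mean(axis=1, keepdims=True), (a,), bwd, _track(a))


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bwd(g):
        a._accum(g * mask)
    return _make(a.data * mask, (a,), bwd, _track(a))


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        a._accum(g * out * (1.0 - out))
    return _make(out, (a,), bwd, _track(a))


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    sizes = [t.data.shape[1] for t in tensors]
    offs = np.cumsum([0] + sizes)
    track = _track(*tensors)

    def bwd(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            t._accum(g[:, lo:hi])
    return _make(np.concatenate([t.data for t in tensors], axis=1),
                 tuple(tensors), bwd, track)


def flatten(a: Tensor) -> Tensor:
    shp = a.data.shape

    def bwd(g):
        a._accum(g.reshape(shp))
    return _make(a.data.reshape(shp[0], -1), (a,), bwd, _track(a))


def clip01(a: Tensor, hi: float) -> Tensor:
    """Clamp to [0, hi]; straight-through gradient inside the range."""
    mask = (a.data > 0) & (a.data < hi)

    def bwd(g):
        a._accum(g * mask)
    return _make(np.clip(a.data, 0.0, hi), (a,), bwd, _track(a))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over per-neuron sigmoid outputs (stable)."""
    z = logits.data.astype(np.float64)
    t = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-z))
        logits._accum((g * (p - t) / n).astype(DTYPE))
    return _make(loss.mean(), (logits,), bwd, _track(logits))


# ---------------------------------------------------------------------------
# im2col machinery
# ---------------------------------------------------------------------------

def same_pads(size: int, k: int, s: int) -> tuple[int, int, int]:
    """Keras 'same': output ceil(size/s); returns (out, pad_lo, pad_hi)."""
    out = -(-size // s)
    pad = max((out - 1) * s + k - size, 0)
    return out, pad // 2, pad - pad // 2


def _im2col(x: np.ndarray, kh: int, kw: int, s: int,
            pt: int, pb: int, pl: int, pr: int):
    n, c, h, w = x.shape
    if pt or pb or pl or pr:
        x = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    oh = (x.shape[2] - kh) // s + 1
    ow = (x.shape[3] - kw) // s + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))
    return cols.reshape(n, c * kh * kw, oh * ow), (oh, ow, x.shape[2], x.shape[3])


def _col2im(cols: np.ndarray, n: int, c: int, hp: int, wp: int,
            kh: int, kw: int, s: int, oh: int, ow: int,
            pt: int, pl: int, h: int, w: int) -> np.ndarray:
    out = np.zeros((n, c, hp, wp), dtype=DTYPE)
    c6 = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + s * oh:s, j:j + s * ow:s] += c6[:, :, i, j]
    return out[:, :, pt:pt + h, pl:pl + w]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def glorot_uniform(shape, fan_in, fan_out, rng) -> np.ndarray:
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(DTYPE)


def he_normal(shape, fan_in, fan_out, rng) -> np.ndarray:
    sd = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, sd, size=shape).astype(DTYPE)


class Layer:
    def parameters(self) -> list[Tensor]:
        return []


class Conv2D(Layer):
    """2-D convolution, stride s, Keras 'same' or 'valid' padding."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 padding: str = "same", init=glorot_uniform, rng=None):
        fan_in, fan_out = cin * k * k, cout * k * k
        self.w = Tensor(init((cout, cin, k, k), fan_in, fan_out, rng),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True)
        self.k, self.s, self.padding = k, stride, padding
        self.cin, self.cout = cin, cout

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if self.padding == "same":
            oh = same_pads(h, self.k, self.s)[0]
            ow = same_pads(w, self.k, self.s)[0]
        else:
            oh = (h - self.k) // self.s + 1
            ow = (w - self.k) // self.s + 1
        return (self.cout, oh, ow)

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        k, s = self.k, self.s
        if self.padding == "same":
            _, pt, pb = same_pads(h, k, s)
            _, pl, pr = same_pads(w, k, s)
        else:
            pt = pb = pl = pr = 0
        cols, (oh, ow, hp, wp) = _im2col(x.data, k, k, s, pt, pb, pl, pr)
        wm = self.w.data.reshape(self.cout, -1)
        y = np.matmul(wm, cols).reshape(n, self.cout, oh, ow)
        y += self.b.data[None, :, None, None]
        track = _track(x, self.w)
        weight, bias = self.w, self.b

        def bwd(g):
            gf = g.reshape(n, self.cout, oh * ow)
            weight._accum(np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
                          .reshape(weight.data.shape))
            bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                gcols = np.matmul(wm.T[None], gf)
                x._accum(_col2im(gcols, n, c, hp, wp, k, k, s, oh, ow,
                                 pt, pl, h, w))
        return _make(y, (x, weight, bias), bwd, track)


class ConvTranspose2D(Layer):
    """Transposed convolution with 'same' padding: out = stride * in."""

    def __init__(self, cin: int, cout: int, k: int, stride: int,
                 init=glorot_uniform, rng=None):
        fan_in, fan_out = cin * k * k, cout * k * k
        self.w = Tensor(init((cin, cout, k, k), fan_in, fan_out, rng),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True)
        self.k, self.s = k, stride
        self.cin, self.cout = cin, cout

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (self.cout, h * self.s, w * self.s)

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        k, s = self.k, self.s
        oh, ow = h * s, w * s          # output spatial size
        _, pt, pb = same_pads(oh, k, s)
        _, pl, pr = same_pads(ow, k, s)
        hp, wp = oh + pt + pb, ow + pl + pr
        wm = self.w.data.reshape(self.cin, -1)   # (cin, cout*k*k)
        xf = x.data.reshape(n, c, h * w)
        cols = np.matmul(wm.T[None], xf)         # (n, cout*k*k, h*w)
        y = _col2im(cols, n, self.cout, hp, wp, k, k, s, h, w, pt, pl, oh, ow)
        y += self.b.data[None, :, None, None]
        track = _track(x, self.w)
        weight, bias = self.w, self.b

        def bwd(g):
            gcols, _ = _im2col(g, k, k, s, pt, pb, pl, pr)
            weight._accum(np.matmul(xf, gcols.transpose(0, 2, 1)).sum(axis=0)
                          .reshape(weight.data.shape))
            bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                x._accum(np.matmul(wm[None], gcols).reshape(n, c, h, w))
        return _make(y, (x, weight, bias), bwd, track)


class AvgPool2D(Layer):
    """Average pooling, valid padding; kernel capped at the input size."""

    def __init__(self, k: int, stride: int | None = None):
        self.k = k
        self.s = stride if stride is not None else k

    def out_shape(self, in_shape):
        c, h, w = in_shape
        k = min(self.k, h, w)
        return (c, (h - k) // self.s + 1, (w - k) // self.s + 1)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        k = min(self.k, h, w)
        s = self.s
        oh, ow = (h - k) // s + 1, (w - k) // s + 1
        win = sliding_window_view(x.data, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        y = win.mean(axis=(4, 5))

        def bwd(g):
            # gradient spreads uniformly over each pooling window
            c6 = np.repeat((g / (k * k)).reshape(n, c, 1, oh, ow),
                           k * k, axis=2).reshape(n, c * k * k, oh * ow)
            x._accum(_col2im(c6, n, c, h, w, k, k, s, oh, ow, 0, 0, h, w))
        return _make(y, (x,), bwd, _track(x))


def avg_pool_same(x: Tensor, k: int = 3) -> Tensor:
    """Stride-1 'same' average pooling; padded positions are excluded
    from each window's mean (TF convention)."""
    n, c, h, w = x.data.shape
    k = min(k, h, w)
    _, pt, pb = same_pads(h, k, 1)
    _, pl, pr = same_pads(w, k, 1)
    cols, (oh, ow, hp, wp) = _im2col(
        x.data.reshape(n * c, 1, h, w), k, k, 1, pt, pb, pl, pr)
    ones = np.ones((1, 1, h, w), dtype=DTYPE)
    cnt, _ = _im2col(ones, k, k, 1, pt, pb, pl, pr)
    count = cnt.sum(axis=1)  # (1, oh*ow)
    y = (cols.sum(axis=1) / count).reshape(n, c, oh, ow)

    def bwd(g):
        gc = (g.reshape(n * c, 1, oh * ow) / count[None]).astype(DTYPE)
        gcols = np.broadcast_to(gc, (n * c, k * k, oh * ow))
        gx = _col2im(np.ascontiguousarray(gcols), n * c, 1, hp, wp,
                     k, k, 1, oh, ow, pt, pl, h, w)
        x._accum(gx.reshape(n, c, h, w))
    return _make(y, (x,), bwd, _track(x))


class MaxPool2D(Layer):
    """Max pooling, valid padding; kernel capped at the input size."""

    def __init__(self, k: int, stride: int):
        self.k, self.s = k, stride

    def out_shape(self, in_shape):
        c, h, w = in_shape
        k = min(self.k, h, w)
        return (c, (h - k) // self.s + 1, (w - k) // self.s + 1)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        k = min(self.k, h, w)
        s = self.s
        oh, ow = (h - k) // s + 1, (w - k) // s + 1
        win = sliding_window_view(x.data, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(n, c, oh, ow, k * k)
        idx = flat.argmax(axis=4)
        y = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]

        def bwd(g):
            gwin = np.zeros((n, c, oh, ow, k * k), dtype=DTYPE)
            np.put_along_axis(gwin, idx[..., None], g[..., None], axis=4)
            cols = gwin.reshape(n, c, oh, ow, k, k).transpose(0, 1, 4, 5, 2, 3)
            cols = cols.reshape(n, c * k * k, oh * ow)
            x._accum(_col2im(cols, n, c, h, w, k, k, s, oh, ow, 0, 0, h, w))
        return _make(y, (x,), bwd, _track(x))


class Dense(Layer):
    def __init__(self, fin: int, fout: int, init=glorot_uniform, rng=None):
        self.w = Tensor(init((fin, fout), fin, fout, rng), requires_grad=True)
        self.b = Tensor(np.zeros(fout, dtype=DTYPE), requires_grad=True)

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        y = x.data @ self.w.data + self.b.data
        weight, bias = self.w, self.b

        def bwd(g):
            weight._accum(x.data.T @ g)
            bias._accum(g.sum(axis=0))
            if x.requires_grad or x._parents:
                x._accum(g @ weight.data.T)
        return _make(y, (x, weight, bias), bwd, _track(x, self.w))


class Dropout(Layer):
    """Inverted dropout driven by an explicit Generator; identity in eval."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep).astype(DTYPE) / keep

        def bwd(g):
            x._accum(g * mask)
        return _make(x.data * mask, (x,), bwd, _track(x))


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Adam:
    """Adam with Keras-style defaults (eps 1e-7)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * math.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= lr_t * m / (np.sqrt(v) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adadelta:
    """Adadelta (accumulated gradient / update RMS), Keras-style."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1.0,
                 rho: float = 0.95, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.eg = [np.zeros_like(p.data) for p in self.params]
        self.ed = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, eg, ed in zip(self.params, self.eg, self.ed):
            if p.grad is None:
                continue
            g = p.grad
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            upd = g * np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps)
            ed *= self.rho
            ed += (1 - self.rho) * upd * upd
            p.data -= self.lr * upd

    def zero_grad(self):
        for p in self.params:
            p.grad = None
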