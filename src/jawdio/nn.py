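"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the ingestive-sound classifiers need:
broadcast add/mul, (batched) matmul, relu/tanh/sigmoid, reshape, slicing
and concatenation, valid-mode 1-D/2-D convolution via im2col, axis-wise
max-pooling, dropout, and a fused softmax cross-entropy loss, plus an Adam
optimizer.  Everything is float32 and fully deterministic: identical
parameters, inputs and seeds give bit-identical results on CPU.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
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
            for p in node.parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(DTYPE, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(a.data + b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(a.data * b.data, (a, b), bw)


def scale(a: Tensor, c) -> Tensor:
    c = np.asarray(c, dtype=DTYPE)

    def bw(g):
        _accum(a, _unbroadcast(g * c, a.data.shape))

    return Tensor(a.data * c, (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.data.shape))
        _accum(b, _unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.data.shape))

    return Tensor(np.matmul(a.data, b.data), (a, b), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g):
        _accum(a, g * mask)

    return Tensor(a.data * mask, (a,), bw)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bw(g):
        _accum(a, g * (1.0 - out_data * out_data))

    return Tensor(out_data, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    from scipy.special import expit

    out_data = expit(a.data)

    def bw(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return Tensor(out_data, (a,), bw)


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape

    def bw(g):
        _accum(a, g.reshape(orig))

    return Tensor(a.data.reshape(shape), (a,), bw)


def slice_axis(a: Tensor, axis: int, start: int, end: int) -> Tensor:
    key = [slice(None)] * a.data.ndim
    key[axis] = slice(start, end)
    key = tuple(key)

    def bw(g):
        if not a.requires_grad:
            return
        if a.grad is None:
            a.grad = np.zeros_like(a.data)
        a.grad[key] += g

    return Tensor(a.data[key], (a,), bw)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            key = [slice(None)] * g.ndim
            key[axis] = slice(lo, hi)
            _accum(t, g[tuple(key)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def dropout(a: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= p).astype(DTYPE) / DTYPE(1.0 - p)
    return scale(a, mask)


def maxpool_axis(a: Tensor, axis: int, pool: int) -> Tensor:
    """Non-overlapping max pooling along one axis (tail truncated)."""
    n = a.data.shape[axis]
    keep = (n // pool) * pool
    trimmed = slice_axis(a, axis, 0, keep) if keep != n else a
    shape = list(trimmed.data.shape)
    new_shape = shape[:axis] + [keep // pool, pool] + shape[axis + 1 :]
    windows = trimmed.data.reshape(new_shape)
    arg = windows.argmax(axis=axis + 1, keepdims=True)
    out_data = np.take_along_axis(windows, arg, axis=axis + 1).squeeze(axis=axis + 1)

    def bw(g):
        gw = np.zeros(new_shape, dtype=DTYPE)
        np.put_along_axis(gw, arg, np.expand_dims(g, axis + 1), axis=axis + 1)
        _accum(trimmed, gw.reshape(trimmed.data.shape))

    return Tensor(out_data, (trimmed,), bw)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1-D convolution: x (B, L, Cin), w (K, Cin, Cout) -> (B, L-K+1, Cout)."""
    bsz, length, cin = x.data.shape
    k, _, cout = w.data.shape
    lout = length - k + 1
    cols = np.stack([x.data[:, i : i + lout, :] for i in range(k)], axis=2)
    cols = cols.reshape(bsz, lout, k * cin)
    wmat = w.data.reshape(k * cin, cout)
    out_data = cols @ wmat + b.data

    def bw(g):
        _accum(b, g.sum(axis=(0, 1)))
        gw = np.tensordot(cols, g, axes=([0, 1], [0, 1]))
        _accum(w, gw.reshape(w.data.shape))
        gcols = (g @ wmat.T).reshape(bsz, lout, k, cin)
        gx = np.zeros_like(x.data)
        for i in range(k):
            gx[:, i : i + lout, :] += gcols[:, :, i, :]
        _accum(x, gx)

    return Tensor(out_data, (x, w, b), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 2-D convolution: x (B,H,W,Cin), w (kh,kw,Cin,Cout)."""
    bsz, h, wdt, cin = x.data.shape
    kh, kw, _, cout = w.data.shape
    ho, wo = h - kh + 1, wdt - kw + 1
    cols = np.stack(
        [x.data[:, i : i + ho, j : j + wo, :] for i in range(kh) for j in range(kw)],
        axis=3,
    ).reshape(bsz, ho, wo, kh * kw * cin)
    wmat = w.data.reshape(kh * kw * cin, cout)
    out_data = cols @ wmat + b.data

    def bw(g):
        _accum(b, g.sum(axis=(0, 1, 2)))
        gw = np.tensordot(cols, g, axes=([0, 1, 2], [0, 1, 2]))
        _accum(w, gw.reshape(w.data.shape))
        gcols = (g @ wmat.T).reshape(bsz, ho, wo, kh * kw, cin)
        gx = np.zeros_like(x.data)
        idx = 0
        for i in range(kh):
            for j in range(kw):
                gx[:, i : i + ho, j : j + wo, :] += gcols[:, :, :, idx, :]
                idx += 1
        _accum(x, gx)

    return Tensor(out_data, (x, w, b), bw)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels; fused softmax backward."""
    probs = softmax(logits.data.astype(np.float64))
    n = logits.data.shape[0]
    nll = -np.log(np.maximum(probs[np.arange(n), labels], 1e-12)).mean()

    def bw(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        _accum(logits, (g * grad / n).astype(DTYPE))

    return Tensor(nll, (logits,), bw)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Adam:
    """Adam optimizer with bias correction (deterministic)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
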