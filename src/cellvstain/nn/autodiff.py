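"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the virtual-staining model zoo needs:
stride-1 (optionally dilated) 3x3/1x1 convolutions, 2x average pooling,
nearest-neighbour 2x upsampling, channel concatenation, dense layers and
the usual pointwise nonlinearities.  Everything is float64 and fully
deterministic, which keeps the training pipelines bit-reproducible under
a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


class Var:
    """A node in the computation graph: a value plus an optional gradient."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Var", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the graph."""
        topo: list[Var] = []
        seen: set[int] = set()
        stack: list[tuple[Var, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- convenience arithmetic ------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(np.asarray(x, dtype=np.float64))


def add(a: Var, b) -> Var:
    a, b = as_var(a), as_var(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return Var(data, (a, b), backward)


def mul(a: Var, b) -> Var:
    a, b = as_var(a), as_var(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Var(data, (a, b), backward)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Var, b: Var) -> Var:
    a, b = as_var(a), as_var(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return Var(data, (a, b), backward)


def relu(x: Var) -> Var:
    x = as_var(x)
    mask = x.data > 0
    data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    return Var(data, (x,), backward)


def leaky_relu(x: Var, slope: float = 0.2) -> Var:
    x = as_var(x)
    mask = x.data > 0
    data = np.where(mask, x.data, slope * x.data)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * np.where(mask, 1.0, slope))

    return Var(data, (x,), backward)


def sigmoid(x: Var) -> Var:
    x = as_var(x)
    data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * data * (1.0 - data))

    return Var(data, (x,), backward)


def conv2d(x: Var, w: Var, b: Var | None = None, dilation: int = 1) -> Var:
    """Same-padding stride-1 2-D convolution.

    ``x`` is (N, C, H, W); ``w`` is (F, C, kh, kw); output is (N, F, H, W).
    """
    N, C, H, W = x.data.shape
    F, Cw, kh, kw = w.data.shape
    assert C == Cw, (C, Cw)
    d = dilation
    ph, pw = d * (kh // 2), d * (kw // 2)
    if kh == 1 and kw == 1:
        # fast path: 1x1 convolution is a channel-mixing matmul
        xm = x.data.transpose(0, 2, 3, 1).reshape(-1, C)
        out = xm @ w.data.reshape(F, C).T
        if b is not None:
            out = out + b.data
        data = out.reshape(N, H, W, F).transpose(0, 3, 1, 2)

        def backward_1x1(g):
            gm = g.transpose(0, 2, 3, 1).reshape(-1, F)
            if w.requires_grad:
                w.accumulate((gm.T @ xm).reshape(F, C, 1, 1))
            if b is not None and b.requires_grad:
                b.accumulate(gm.sum(axis=0))
            if x.requires_grad:
                gx = (gm @ w.data.reshape(F, C)).reshape(N, H, W, C)
                x.accumulate(gx.transpose(0, 3, 1, 2))

        parents = (x, w) if b is None else (x, w, b)
        return Var(data, parents, backward_1x1)

    # conv as a sum of kh*kw shifted channel-mixing products: contiguous
    # GEMMs beat an im2col gather at these tiny channel counts
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    shifts = [(xp[:, :, i * d:i * d + H, j * d:j * d + W], i, j)
              for i in range(kh) for j in range(kw)]
    data = np.zeros((N, F, H, W))
    for xs, i, j in shifts:
        # (F, C) x (N, C, H, W) -> (F, N, H, W)
        data += np.tensordot(w.data[:, :, i, j], xs, axes=([1], [1])).transpose(1, 0, 2, 3)
    if b is not None:
        data += b.data[None, :, None, None]

    def backward(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for xs, i, j in shifts:
                gw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
            w.accumulate(gw)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for _, i, j in shifts:
                gxp[:, :, i * d:i * d + H, j * d:j * d + W] += np.tensordot(
                    w.data[:, :, i, j], g, axes=([0], [1])).transpose(1, 0, 2, 3)
            x.accumulate(gxp[:, :, ph:ph + H, pw:pw + W] if ph or pw else gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Var(data, parents, backward)


def avg_pool2(x: Var) -> Var:
    """2x2 average pooling with stride 2; spatial dims must be even."""
    N, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0, (H, W)
    data = x.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            x.accumulate(gx)

    return Var(data, (x,), backward)


def max_pool2(x: Var) -> Var:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    N, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0, (H, W)
    blocks = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    data = blocks.max(axis=(3, 5))
    # winner mask for gradient routing (ties split evenly)
    expand = np.repeat(np.repeat(data, 2, axis=2), 2, axis=3)
    winners = (x.data == expand).astype(np.float64)
    counts = winners.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))
    norm = np.repeat(np.repeat(counts, 2, axis=2), 2, axis=3)
    winners /= norm

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * winners)

    return Var(data, (x,), backward)


def upsample2(x: Var) -> Var:
    """Nearest-neighbour 2x upsampling."""
    data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        if x.requires_grad:
            N, C, H2, W2 = g.shape
            gx = g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            x.accumulate(gx)

    return Var(data, (x,), backward)


def concat_channels(parts: Sequence[Var]) -> Var:
    parts = [as_var(p) for p in parts]
    data = np.concatenate([p.data for p in parts], axis=1)
    sizes = [p.data.shape[1] for p in parts]

    def backward(g):
        off = 0
        for p, n in zip(parts, sizes):
            if p.requires_grad:
                p.accumulate(g[:, off:off + n])
            off += n

    return Var(data, tuple(parts), backward)


def spatial_mean(x: Var) -> Var:
    """Mean over the spatial axes: (N, C, H, W) -> (N, C)."""
    N, C, H, W = x.data.shape
    data = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.broadcast_to(g[:, :, None, None], x.data.shape) / (H * W))

    return Var(data, (x,), backward)


def mean(x: Var) -> Var:
    x = as_var(x)
    data = np.asarray(x.data.mean())

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.broadcast_to(g, x.data.shape) / x.data.size)

    return Var(data, (x,), backward)


def absolute(x: Var) -> Var:
    x = as_var(x)
    sign = np.sign(x.data)
    data = np.abs(x.data)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * sign)

    return Var(data, (x,), backward)


def square(x: Var) -> Var:
    x = as_var(x)
    data = x.data ** 2

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * 2.0 * x.data)

    return Var(data, (x,), backward)


def softmax_cross_entropy(logits: Var, labels: np.ndarray) -> Var:
    """Mean cross-entropy of integer ``labels`` under softmax(logits)."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    data = np.asarray(-np.mean(np.log(probs[np.arange(n), labels] + 1e-300)))

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits.accumulate(g * grad / n)

    return Var(data, (logits,), backward)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def mae_loss(pred: Var, target: np.ndarray) -> Var:
    return mean(absolute(add(pred, -np.asarray(target))))


def mse_loss(pred: Var, target) -> Var:
    target = target.data if isinstance(target, Var) else np.asarray(target)
    return mean(square(add(pred, -target)))
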