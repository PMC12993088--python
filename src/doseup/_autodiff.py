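"""Minimal reverse-mode automatic differentiation for small convolutional nets.

Arrays are float32 in NHWC layout (batch, height, width, channels).  Only the
handful of operations the upsampling network needs are provided: 3x3 "same"
convolution, 3x3/stride-3 transposed convolution (kernel == stride, so output
blocks are disjoint), 1x1 convolution, ReLU, channel concatenation, the D4
square symmetries, mean-squared error, and scalar combination of losses.

Gradients are accumulated on :class:`Var` nodes by a single reverse topological
sweep; parameter updates are left to the optimizer in :mod:`doseup.network`.
The backward pass of every op is exercised against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

from .symmetry import D4, d4_apply, d4_inverse

__all__ = [
    "Var",
    "backward",
    "conv3x3",
    "conv_transpose3",
    "conv1x1",
    "relu",
    "concat",
    "d4t",
    "mse",
    "add",
    "scale",
]


class Var:
    """A node of the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad", "name")

    def __init__(self, data, parents=(), backward=None, requires_grad=False, name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad
        self.name = name

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        """Add a gradient contribution.

        ``own=True`` donates ``g`` (a freshly allocated array the caller will
        not reuse), avoiding a copy on the first accumulation.
        """
        if self.grad is None:
            if own and isinstance(g, np.ndarray) and g.dtype == np.float32:
                self.grad = g
            else:
                self.grad = np.array(g, dtype=np.float32, copy=True)
        else:
            self.grad += g


def backward(root: Var) -> None:
    """Reverse-accumulate gradients of a scalar ``root`` through the graph."""
    if root.data.size != 1:
        raise ValueError("backward expects a scalar loss")
    topo: list[Var] = []
    seen: set[int] = set()
    stack: list[tuple[Var, bool]] = [(root, False)]
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
    root.grad = np.ones_like(root.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
        if not node.requires_grad and node is not root:
            node.grad = None  # free intermediate buffers early


def _as32(a) -> np.ndarray:
    return np.ascontiguousarray(a, dtype=np.float32)


def conv3x3(x: Var, w: Var, b: Var) -> Var:
    """Zero-padded "same" 3x3 convolution: (N,H,W,C) x (3,3,C,O) -> (N,H,W,O).

    Implemented as one GEMM on the (contiguous) padded input producing all
    nine tap contributions at once, followed by shifted-slice accumulation;
    this keeps the large memory traffic inside BLAS.
    """
    n, h, wd, c = x.data.shape
    o = w.data.shape[3]
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    # w_all[c, (di,dj,o)]: all taps as one weight matrix
    w_all = np.ascontiguousarray(w.data.transpose(2, 0, 1, 3)).reshape(c, 9 * o)
    z = (xp.reshape(-1, c) @ w_all).reshape(n, h + 2, wd + 2, 3, 3, o)
    y = np.broadcast_to(b.data, (n, h, wd, o)).copy()
    for di in range(3):
        for dj in range(3):
            y += z[:, di : di + h, dj : dj + wd, di, dj, :]

    def bw(g: np.ndarray) -> None:
        if b.requires_grad or b._parents:
            b._accumulate(g.reshape(-1, o).sum(axis=0))
        dz = np.zeros((n, h + 2, wd + 2, 3, 3, o), dtype=np.float32)
        for di in range(3):
            for dj in range(3):
                dz[:, di : di + h, dj : dj + wd, di, dj, :] = g
        dz2 = dz.reshape(-1, 9 * o)
        dx = np.ascontiguousarray(
            (dz2 @ w_all.T).reshape(n, h + 2, wd + 2, c)[:, 1 : h + 1, 1 : wd + 1, :]
        )
        x._accumulate(dx, own=True)
        dw_all = xp.reshape(-1, c).T @ dz2
        w._accumulate(dw_all.reshape(c, 3, 3, o).transpose(1, 2, 0, 3))
        del dz

    return Var(y, parents=(x, w, b), backward=bw)


def conv_transpose3(x: Var, w: Var, b: Var) -> Var:
    """Transposed convolution, 3x3 kernel with stride 3 (disjoint blocks).

    (N,H,W,C) x (3,3,C,O) -> (N,3H,3W,O): every input pixel paints one 3x3
    output block, so the output resolution triples exactly.
    """
    n, h, wd, c = x.data.shape
    o = w.data.shape[3]
    w2 = w.data.transpose(2, 0, 1, 3).reshape(c, 9 * o)  # (C, 3*3*O)
    y = (x.data.reshape(-1, c) @ w2).reshape(n, h, wd, 3, 3, o)
    y = _as32(y.transpose(0, 1, 3, 2, 4, 5).reshape(n, 3 * h, 3 * wd, o))
    y += b.data

    def bw(g: np.ndarray) -> None:
        if b.requires_grad or b._parents:
            b._accumulate(g.reshape(-1, o).sum(axis=0))
        g6 = _as32(
            g.reshape(n, h, 3, wd, 3, o).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(-1, 9 * o)
        x._accumulate((g6 @ w2.T).reshape(n, h, wd, c), own=True)
        dw2 = x.data.reshape(-1, c).T @ g6
        w._accumulate(dw2.reshape(c, 3, 3, o).transpose(1, 2, 0, 3))

    return Var(y, parents=(x, w, b), backward=bw)


def conv1x1(x: Var, w: Var, b: Var) -> Var:
    """Pointwise convolution: (N,H,W,C) x (C,O) -> (N,H,W,O)."""
    n, h, wd, c = x.data.shape
    o = w.data.shape[1]
    y = (x.data.reshape(-1, c) @ w.data).reshape(n, h, wd, o) + b.data

    def bw(g: np.ndarray) -> None:
        g2 = g.reshape(-1, o)
        if b.requires_grad or b._parents:
            b._accumulate(g2.sum(axis=0))
        w._accumulate(x.data.reshape(-1, c).T @ g2, own=False)
        x._accumulate((g2 @ w.data.T).reshape(n, h, wd, c), own=True)

    return Var(y, parents=(x, w, b), backward=bw)


def relu(x: Var) -> Var:
    y = np.maximum(x.data, 0.0)

    def bw(g: np.ndarray) -> None:
        x._accumulate(g * (x.data > 0), own=True)

    return Var(y, parents=(x,), backward=bw)


def concat(a: Var, b: Var) -> Var:
    """Concatenate along the channel (last) axis."""
    ca = a.data.shape[-1]
    y = np.concatenate([a.data, b.data], axis=-1)

    def bw(g: np.ndarray) -> None:
        a._accumulate(g[..., :ca])
        b._accumulate(g[..., ca:])

    return Var(y, parents=(a, b), backward=bw)


def d4t(x: Var, g_idx: int) -> Var:
    """Apply square symmetry ``g_idx`` to the spatial axes (1, 2)."""
    if g_idx not in D4:
        raise ValueError(f"not a square symmetry index: {g_idx}")
    y = _as32(d4_apply(x.data, g_idx, axes=(1, 2)))
    inv = d4_inverse(g_idx)

    def bw(g: np.ndarray) -> None:
        x._accumulate(_as32(d4_apply(g, inv, axes=(1, 2))), own=True)

    return Var(y, parents=(x,), backward=bw)


def mse(a: Var, b: Var) -> Var:
    """Mean squared error between two equally shaped tensors (scalar Var)."""
    diff = a.data.astype(np.float64) - b.data.astype(np.float64)
    val = np.float32((diff * diff).mean())
    scale_ = np.float32(2.0 / diff.size)

    def bw(g: np.ndarray) -> None:
        gd = (g * scale_ * diff).astype(np.float32)
        a._accumulate(gd, own=True)
        b._accumulate(-gd, own=True)

    return Var(val, parents=(a, b), backward=bw)


def add(a: Var, b: Var) -> Var:
    """Sum of two scalar losses."""
    y = a.data + b.data

    def bw(g: np.ndarray) -> None:
        a._accumulate(g)
        b._accumulate(g)

    return Var(y, parents=(a, b), backward=bw)


def scale(a: Var, k: float) -> Var:
    y = a.data * np.float32(k)

    def bw(g: np.ndarray) -> None:
        a._accumulate(g * np.float32(k), own=True)

    return Var(y, parents=(a,), backward=bw)
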