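"""A small reverse-mode autodiff engine over numpy arrays.

The engine implements exactly the primitives the two segmentation networks
need: 3D convolution (stride 1, "same" padding, odd kernels), 2x stride-2
transposed convolution, 2x max-pooling, shape-preserving 3x3x3 max-pooling,
batch normalization, ReLU/sigmoid, channel concatenation and slicing,
log-softmax, and the elementwise arithmetic required by the losses.

Tensors carry a ``(N, C, D, H, W)`` layout for feature maps.  Convolutions
are evaluated as chunked im2col + BLAS matmul so the largest network inputs
(96x96x128 at 64 channels) stay within a few hundred MB of working memory.
Gradients are accumulated into ``.grad`` by :meth:`Tensor.backward` over a
topologically sorted tape.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# working-memory bound for a single im2col chunk (bytes)
CONV_CHUNK_BYTES = 2 ** 28

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable tape recording (forward-only inference)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, p):
        return power(self, p)

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the original operand shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ------------------------------------------------------------- elementwise --
def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(grad):
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(grad, a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(grad, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(grad):
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(grad * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(grad * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** p

    def backward(grad):
        a._accum(grad * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(grad):
        a._accum(grad * out_data)

    return _make(out_data, (a,), backward)


def log(a, eps: float = 0.0) -> Tensor:
    a = _as_tensor(a)
    out_data = np.log(a.data + eps)

    def backward(grad):
        a._accum(grad / (a.data + eps))

    return _make(out_data, (a,), backward)


def tsum(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.asarray(a.data.sum())

    def backward(grad):
        a._accum(np.broadcast_to(grad, a.data.shape).astype(a.data.dtype))

    return _make(out_data, (a,), backward)


def tmean(a) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size
    out_data = np.asarray(a.data.mean())

    def backward(grad):
        a._accum(np.broadcast_to(grad / n, a.data.shape).astype(a.data.dtype))

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0)

    def backward(grad):
        a._accum(grad * mask)

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    # numerically stable logistic
    out_data = np.empty_like(a.data)
    pos = a.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def backward(grad):
        a._accum(grad * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


# ------------------------------------------------------- shape manipulation --
def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        for t, g in zip(tensors, np.split(grad, splits, axis=axis)):
            if t.requires_grad or t._parents:
                t._accum(g)

    return _make(out_data, tuple(tensors), backward)


def channel_slice(a: Tensor, lo: int, hi: int) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data[:, lo:hi]

    def backward(grad):
        full = np.zeros_like(a.data)
        full[:, lo:hi] = grad
        a._accum(full)

    return _make(out_data, (a,), backward)


# ------------------------------------------------------------- convolution --
def _conv_chunks(D: int, H: int, W: int, C: int, k: int, itemsize: int):
    per_slice = H * W * C * k ** 3 * itemsize
    chunk = max(1, CONV_CHUNK_BYTES // max(per_slice, 1))
    return [(d0, min(D, d0 + chunk)) for d0 in range(0, D, chunk)]


def _im2col(xp: np.ndarray, d0: int, d1: int, k: int, H: int, W: int) -> np.ndarray:
    """Columns (C*k^3, voxels) for output depth slab [d0, d1) of one item.

    Built by k^3 block copies (one per kernel offset) rather than a strided
    transpose of a sliding-window view — the copies run along contiguous
    rows, which is substantially faster.
    """
    C = xp.shape[0]
    d = d1 - d0
    cols = np.empty((C, k ** 3, d, H, W), dtype=xp.dtype)
    o = 0
    for a in range(k):
        for b in range(k):
            for c in range(k):
                cols[:, o] = xp[:, d0 + a:d0 + a + d, b:b + H, c:c + W]
                o += 1
    return cols.reshape(C * k ** 3, d * H * W)


def _conv3d_raw(xd: np.ndarray, wd: np.ndarray, bd: np.ndarray | None) -> np.ndarray:
    """Stride-1 'same' 3D correlation via chunked im2col + GEMM."""
    N, C, D, H, W = xd.shape
    Co, Ci, k, _, _ = wd.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, kernel expects {Ci}")
    p = k // 2
    wmat = wd.reshape(Co, -1)  # (Co, C*k^3), matches the cols layout
    out = np.empty((N, Co, D, H, W), dtype=xd.dtype)
    for n in range(N):
        xp = np.pad(xd[n], ((0, 0), (p, p), (p, p), (p, p))) if p else xd[n]
        for d0, d1 in _conv_chunks(D, H, W, C, k, xd.dtype.itemsize):
            y = wmat @ _im2col(xp, d0, d1, k, H, W)
            out[n, :, d0:d1] = y.reshape(Co, d1 - d0, H, W)
    if bd is not None:
        out += bd.reshape(1, Co, 1, 1, 1)
    return out


def _conv3d_wgrad(xd: np.ndarray, gd: np.ndarray, k: int) -> np.ndarray:
    """Weight gradient of the stride-1 'same' conv, chunked like forward."""
    N, C, D, H, W = xd.shape
    Co = gd.shape[1]
    p = k // 2
    dwmat = np.zeros((Co, C * k ** 3), dtype=xd.dtype)
    for n in range(N):
        xp = np.pad(xd[n], ((0, 0), (p, p), (p, p), (p, p))) if p else xd[n]
        for d0, d1 in _conv_chunks(D, H, W, C, k, xd.dtype.itemsize):
            cols = _im2col(xp, d0, d1, k, H, W)
            gmat = gd[n, :, d0:d1].reshape(Co, -1)
            dwmat += gmat @ cols.T
    return dwmat.reshape(Co, C, k, k, k)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3D convolution, stride 1, zero 'same' padding, odd cubic kernel.

    ``x``: (N, C, D, H, W); ``w``: (Cout, Cin, k, k, k); ``b``: (Cout,).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    out_data = _conv3d_raw(x.data, w.data, None if b is None else b.data)
    k = w.data.shape[2]
    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        if b is not None and (b.requires_grad or b._parents):
            b._accum(grad.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad or w._parents:
            w._accum(_conv3d_wgrad(x.data, grad, k))
        if x.requires_grad or x._parents:
            wflip = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            x._accum(_conv3d_raw(grad, np.ascontiguousarray(wflip), None))

    return _make(out_data, parents, backward)


def conv_transpose3d_2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed conv with 2x2x2 kernel, stride 2: learned 2x upsampling.

    Each input voxel maps linearly onto a disjoint 2x2x2 output block, so the
    operation is an einsum followed by an interleaving reshape.
    ``w``: (Cin, Cout, 2, 2, 2).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    N, C, D, H, W = x.data.shape
    Ci, Co = w.data.shape[:2]
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, kernel expects {Ci}")
    t = np.einsum("ncdhw,coijk->nodihjwk", x.data, w.data, optimize=True)
    out_data = np.ascontiguousarray(t).reshape(N, Co, 2 * D, 2 * H, 2 * W)
    if b is not None:
        out_data += b.data.reshape(1, Co, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        g = grad.reshape(N, Co, D, 2, H, 2, W, 2)
        if b is not None and (b.requires_grad or b._parents):
            b._accum(grad.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad or w._parents:
            w._accum(np.einsum("ncdhw,nodihjwk->coijk", x.data, g, optimize=True))
        if x.requires_grad or x._parents:
            x._accum(np.einsum("nodihjwk,coijk->ncdhw", g, w.data, optimize=True))

    return _make(out_data, parents, backward)


# ----------------------------------------------------------------- pooling --
def maxpool3d_2x(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2 (all spatial dims must be even)."""
    x = _as_tensor(x)
    N, C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool3d_2x needs even spatial dims, got {(D, H, W)}")
    xr = (
        x.data.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(N, C, D // 2, H // 2, W // 2, 8)
    )
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(grad):
        g = np.zeros_like(xr)
        np.put_along_axis(g, idx[..., None], grad[..., None], axis=-1)
        g = (
            g.reshape(N, C, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(N, C, D, H, W)
        )
        x._accum(g)

    return _make(out_data, (x,), backward)


def maxpool3d_same(x: Tensor, k: int = 3) -> Tensor:
    """kxkxk max pooling with stride 1 and 'same' padding (odd k)."""
    x = _as_tensor(x)
    N, C, D, H, W = x.data.shape
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    winf = win.reshape(N, C, D, H, W, k ** 3)
    idx = winf.argmax(axis=-1)
    out_data = np.take_along_axis(winf, idx[..., None], axis=-1)[..., 0]

    def backward(grad):
        gp = np.zeros_like(xp)
        di, hi, wi = np.unravel_index(idx, (k, k, k))
        nn, cc, dd, hh, ww = np.indices((N, C, D, H, W), sparse=True)
        np.add.at(gp, (nn, cc, dd + di, hh + hi, ww + wi), grad)
        x._accum(gp[:, :, p:p + D, p:p + H, p:p + W] if p else gp)

    return _make(out_data, (x,), backward)


# --------------------------------------------------------------- batchnorm --
def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
              running_var: np.ndarray, training: bool, momentum: float = 0.1,
              eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, D, H, W).

    In training mode batch statistics are used and the running estimates are
    updated in place; in eval mode the running estimates are used.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = (0, 2, 3, 4)
    cshape = (1, -1, 1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(cshape)) * inv_std.reshape(cshape)
    out_data = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)

    def backward(grad):
        if gamma.requires_grad or gamma._parents:
            gamma._accum((grad * xhat).sum(axis=axes))
        if beta.requires_grad or beta._parents:
            beta._accum(grad.sum(axis=axes))
        if x.requires_grad or x._parents:
            dxhat = grad * gamma.data.reshape(cshape)
            if training:
                m = x.data.size // x.data.shape[1]
                term = (
                    dxhat
                    - dxhat.mean(axis=axes, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
                )
                x._accum(term * inv_std.reshape(cshape))
            else:
                x._accum(dxhat * inv_std.reshape(cshape))

    return _make(out_data, (x, gamma, beta), backward)


# ------------------------------------------------------------------ losses --
def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    x = _as_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse

    def backward(grad):
        sm = np.exp(out_data)
        x._accum(grad - sm * grad.sum(axis=axis, keepdims=True))

    return _make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    return exp(log_softmax(x, axis=axis))


def nll_loss(logp: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; ``labels``: (N, D, H, W) ints."""
    logp = _as_tensor(logp)
    lab = labels[:, None]  # (N, 1, D, H, W)
    picked = np.take_along_axis(logp.data, lab, axis=1)
    m = picked.size
    out_data = np.asarray(-picked.mean())

    def backward(grad):
        g = np.zeros_like(logp.data)
        np.put_along_axis(g, lab, -grad / m, axis=1)
        logp._accum(g)

    return _make(out_data, (logp,), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    pred = _as_tensor(pred)
    diff = pred.data - target
    m = diff.size
    out_data = np.asarray((diff ** 2).mean())

    def backward(grad):
        pred._accum(grad * 2.0 * diff / m)

    return _make(out_data, (pred,), backward)
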