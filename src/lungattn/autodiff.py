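"""Reverse-mode automatic differentiation over numpy arrays.

A small define-by-run engine: each operation returns a :class:`Tensor`
holding the forward value and a closure that distributes the upstream
gradient to its parents. Only the operations the segmentation network
needs are provided (elementwise arithmetic, dense and convolutional
linear maps, batch normalization, pooling/upsampling, concatenation and
the usual activations). Convolutions are evaluated by im2col + BLAS
matmul; every backward pass is checked against central finite
differences in the test suite.

Arrays are laid out batch-first: dense features as ``(N, C)`` and
spatial features as ``(N, C, H, W)``.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "batch_norm",
    "linear",
    "relu",
    "sigmoid",
    "global_avg_pool",
    "upsample2x",
    "mean_all",
    "mse",
]


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    # numerically stable logistic
    s = np.empty_like(x.data)
    pos = x.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    s[~pos] = e / (1.0 + e)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Dense map ``x @ w.T + b`` for ``x`` of shape (N, C_in), ``w`` (C_out, C_in)."""
    x, w = _as_tensor(x), _as_tensor(w)
    out_data = x.data @ w.data.T
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g @ w.data)
        if w.requires_grad:
            w.accumulate(g.T @ x.data)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=0))

    return Tensor(out_data, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, ho: int, wo: int):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += d[
                :, :, ki, kj
            ]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution; ``w`` has shape (C_out, C_in, k, k)."""
    x, w = _as_tensor(x), _as_tensor(w)
    co, ci, k, k2 = w.data.shape
    if k != k2:
        raise ValueError("only square kernels are supported")
    if x.data.ndim != 4 or x.data.shape[1] != ci:
        raise ValueError(
            f"conv2d input has shape {x.data.shape}, expected (N, {ci}, H, W)"
        )
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    wm = w.data.reshape(co, ci * k * k)
    out = cols @ wm.T  # (N, Ho*Wo, Co)
    if b is not None:
        b = _as_tensor(b)
        out = out + b.data
    n = x.data.shape[0]
    out_data = out.transpose(0, 2, 1).reshape(n, co, ho, wo)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.reshape(n, co, ho * wo).transpose(0, 2, 1)  # (N, Ho*Wo, Co)
        if w.requires_grad:
            dw = np.tensordot(gm, cols, axes=([0, 1], [0, 1]))  # (Co, C*k*k)
            w.accumulate(dw.reshape(co, ci, k, k))
        if b is not None and b.requires_grad:
            b.accumulate(gm.sum(axis=(0, 1)))
        if x.requires_grad:
            dcols = gm @ wm  # (N, Ho*Wo, C*k*k)
            x.accumulate(_col2im(dcols, x.data.shape, k, stride, pad, ho, wo))

    return Tensor(out_data, parents=parents, backward=backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact x2 upsampling).

    ``w`` has shape (C_in, C_out, 2, 2); output spatial size is doubled.
    With stride equal to the kernel size the output windows do not
    overlap, so the map is a channel-mixing block expansion.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    ci, co, k, _ = w.data.shape
    n, cx, h, wd = x.data.shape
    if cx != ci:
        raise ValueError(f"conv_transpose2d input channels {cx} != kernel C_in {ci}")
    out_data = np.zeros((n, co, 2 * h, 2 * wd))
    for ki in range(2):
        for kj in range(2):
            # (N,H,W,Co) <- (N,Ci,H,W) x (Ci,Co)
            t = np.tensordot(x.data, w.data[:, :, ki, kj], axes=([1], [0]))
            out_data[:, :, ki::2, kj::2] = np.moveaxis(t, 3, 1)
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data.reshape(1, co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        for ki in range(2):
            for kj in range(2):
                gs = g[:, :, ki::2, kj::2]  # (N, Co, H, W)
                if x.requires_grad:
                    t = np.tensordot(gs, w.data[:, :, ki, kj], axes=([1], [1]))
                    x.accumulate(np.moveaxis(t, 3, 1))
                if w.requires_grad:
                    dw = np.tensordot(x.data, gs, axes=([0, 2, 3], [0, 2, 3]))
                    w.grad = np.zeros_like(w.data) if w.grad is None else w.grad
                    w.grad[:, :, ki, kj] += dw

    return Tensor(out_data, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# normalization / pooling / resampling


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over the non-channel axes.

    Accepts (N, C) or (N, C, H, W) inputs. In training mode with more
    than one element per channel the batch statistics are used and the
    running statistics updated in place; otherwise the running
    statistics are used (they then enter the graph as constants).
    """
    x = _as_tensor(x)
    if x.data.ndim == 2:
        axes, view = (0,), (1, -1)
    elif x.data.ndim == 4:
        axes, view = (0, 2, 3), (1, -1, 1, 1)
    else:
        raise ValueError("batch_norm expects (N,C) or (N,C,H,W)")
    m = int(np.prod([x.data.shape[a] for a in axes]))
    use_batch_stats = training and m > 1
    if use_batch_stats:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(view)) * inv_std.reshape(view)
    out_data = gamma.data.reshape(view) * xhat + beta.data.reshape(view)

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gs = g * gamma.data.reshape(view)
            if use_batch_stats:
                dxhat_sum = gs.sum(axis=axes).reshape(view)
                dxhat_dot = (gs * xhat).sum(axis=axes).reshape(view)
                dx = (gs - dxhat_sum / m - xhat * dxhat_dot / m) * inv_std.reshape(view)
            else:
                dx = gs * inv_std.reshape(view)
            x.accumulate(dx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial axes: (N, C, H, W) -> (N, C)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


_INTERP_CACHE: dict[tuple[int, str], np.ndarray] = {}


def _interp_matrix(n_in: int, mode: str) -> np.ndarray:
    """(2n, n) matrix realizing x2 upsampling along one axis."""
    key = (n_in, mode)
    if key in _INTERP_CACHE:
        return _INTERP_CACHE[key]
    n_out = 2 * n_in
    m = np.zeros((n_out, n_in))
    if mode == "nearest":
        for o in range(n_out):
            m[o, o // 2] = 1.0
    elif mode == "bilinear":
        # half-pixel-centre convention: src = (o + 0.5)/2 - 0.5
        for o in range(n_out):
            src = (o + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            t = src - i0
            i0c = min(max(i0, 0), n_in - 1)
            i1c = min(max(i0 + 1, 0), n_in - 1)
            m[o, i0c] += 1.0 - t
            m[o, i1c] += t
    else:
        raise ValueError(f"unknown upsampling mode {mode!r}")
    _INTERP_CACHE[key] = m
    return m


def upsample2x(x: Tensor, mode: str = "bilinear") -> Tensor:
    """Double the spatial size of an (N, C, H, W) tensor.

    Implemented as a fixed separable linear map, so the adjoint used in
    the backward pass is exact.
    """
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    mh = _interp_matrix(h, mode)
    mw = _interp_matrix(w, mode)
    out_data = np.matmul(np.matmul(mh, x.data), mw.T)

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.matmul(np.matmul(mh.T, g), mw))

    return Tensor(out_data, parents=(x,), backward=backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g.reshape(x.data.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.concatenate([a.data, b.data], axis=axis)
    split = a.data.shape[axis]

    def backward(g):
        ga, gb = np.split(g, [split], axis=axis)
        if a.requires_grad:
            a.accumulate(ga)
        if b.requires_grad:
            b.accumulate(gb)

    return Tensor(out_data, parents=(a, b), backward=backward)


def mean_all(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = np.array(x.data.mean())

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.broadcast_to(g / x.data.size, x.data.shape).copy())

    return Tensor(out_data, parents=(x,), backward=backward)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    diff = pred.data - target
    out_data = np.array((diff * diff).mean())

    def backward(g):
        if pred.requires_grad:
            pred.accumulate(g * 2.0 * diff / diff.size)

    return Tensor(out_data, parents=(pred,), backward=backward)
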