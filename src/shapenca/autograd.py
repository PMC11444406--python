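"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the NCA pipeline needs: broadcasting
elementwise arithmetic, same-padded 2D convolution, batch normalization,
nearest-neighbour upsampling, spatial cropping, superpixel mean-smoothing
and numerically stable binary cross-entropy on logits.  Tensors wrap
float32 arrays; gradients are accumulated by a tape built as operations
execute and replayed in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "backward",
    "conv2d",
    "batch_norm2d",
    "upsample_nearest",
    "crop2d",
    "superpixel_smooth",
    "bce_with_logits",
    "relu",
    "sigmoid",
    "Adam",
]


class Tensor:
    """A float32 array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(np.float32(-1.0)))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def sum(self):
        return tsum(self)

    def mean(self):
        return tmean(self)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum-reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def backward(loss: Tensor) -> None:
    """Backpropagate from a scalar loss through the recorded tape."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
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
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None:
            node._backward(node.grad)


# -- elementwise -------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward_fn(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward_fn)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward_fn(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward_fn)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward_fn(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(out_data, (a, b), backward_fn)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def backward_fn(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), backward_fn)


def sigmoid(a: Tensor) -> Tensor:
    out_data = _sigmoid_np(a.data)

    def backward_fn(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward_fn)


def _sigmoid_np(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def tsum(a: Tensor) -> Tensor:
    out_data = a.data.sum(dtype=np.float32)

    def backward_fn(g):
        _accum(a, np.broadcast_to(g, a.data.shape))

    return _make(out_data, (a,), backward_fn)


def tmean(a: Tensor) -> Tensor:
    n = a.data.size
    out_data = a.data.mean(dtype=np.float32)

    def backward_fn(g):
        _accum(a, np.broadcast_to(g / n, a.data.shape).astype(np.float32))

    return _make(out_data, (a,), backward_fn)


# -- spatial operators -------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 2D convolution, NCHW layout, square odd kernel.

    Computed as a sum of shifted 1x1 matmuls over the k*k kernel taps,
    which avoids materializing the full im2col matrix; the backward pass
    reuses the same shifted-slice structure for both the input and the
    weight gradients.
    """
    n, c, h, wd = x.data.shape
    co, ci, k, k2 = w.data.shape
    if k != k2 or k % 2 != 1:
        raise ValueError("kernel must be square with odd size")
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {ci}")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    xf = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # N, H+2p, W+2p, C
    of = np.broadcast_to(b.data, (n, h, wd, co)).copy()
    wt = w.data.transpose(2, 3, 1, 0)  # k, k, C, Co
    for i in range(k):
        for j in range(k):
            of += xf[:, i : i + h, j : j + wd, :] @ wt[i, j]
    out_data = of.transpose(0, 3, 1, 2)

    def backward_fn(g):
        gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # N, H, W, Co
        if b.requires_grad:
            _accum(b, gf.sum(axis=(0, 1, 2)))
        dw = np.zeros_like(w.data) if w.requires_grad else None
        dxf = np.zeros_like(xf) if x.requires_grad else None
        gmat = gf.reshape(-1, co)
        for i in range(k):
            for j in range(k):
                if dw is not None:
                    xs = np.ascontiguousarray(xf[:, i : i + h, j : j + wd, :]).reshape(
                        -1, c
                    )
                    dw[:, :, i, j] = gmat.T @ xs
                if dxf is not None:
                    dxf[:, i : i + h, j : j + wd, :] += gf @ w.data[:, :, i, j]
        if dw is not None:
            _accum(w, dw)
        if dxf is not None:
            _accum(x, dxf.transpose(0, 3, 1, 2)[:, :, p : p + h, p : p + wd])

    return _make(out_data, (x, w, b), backward_fn)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running: dict,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    ``running`` holds keys ``mean``/``var`` (float32, shape (C,)); in
    training mode batch statistics are used and the running estimates
    updated in place, in eval mode the running estimates are used.
    """
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running["mean"] = ((1 - momentum) * running["mean"] + momentum * mu).astype(
            np.float32
        )
        running["var"] = ((1 - momentum) * running["var"] + momentum * var).astype(
            np.float32
        )
    else:
        mu = running["mean"]
        var = running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    mu4 = mu[None, :, None, None]
    inv4 = inv[None, :, None, None]
    xhat = (x.data - mu4) * inv4
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward_fn(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                term1 = dxhat
                term2 = dxhat.mean(axis=axes, keepdims=True)
                term3 = xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
                _accum(x, inv4 * (term1 - term2 - term3))
            else:
                _accum(x, dxhat * inv4)

    return _make(out_data, (x, gamma, beta), backward_fn)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    if factor < 1:
        raise ValueError("upsampling factor must be >= 1")
    if factor == 1:
        return x
    n, c, h, w = x.data.shape
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def backward_fn(g):
        _accum(x, g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward_fn)


def crop2d(x: Tensor, oy: int, ox: int, h: int, w: int) -> Tensor:
    out_data = x.data[:, :, oy : oy + h, ox : ox + w].copy()

    def backward_fn(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, :, oy : oy + h, ox : ox + w] = g
            _accum(x, gx)

    return _make(out_data, (x,), backward_fn)


def _smooth_np(arr: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Replace each pixel by the mean of its superpixel; arr (C,H,W)."""
    c, h, w = arr.shape
    flat_lab = labels.ravel()
    k = int(flat_lab.max()) + 1
    counts = np.bincount(flat_lab, minlength=k).astype(arr.dtype)
    sums = np.zeros((k, c), dtype=arr.dtype)
    np.add.at(sums, flat_lab, arr.reshape(c, -1).T)
    pooled = sums / counts[:, None]
    return pooled[flat_lab].T.reshape(c, h, w)


def superpixel_smooth(x: Tensor, labels: np.ndarray) -> Tensor:
    """Per-image superpixel mean smoothing; x (N,C,H,W), labels (N,H,W).

    The smoothing operator is an orthogonal projection and symmetric, so
    the backward pass re-applies the same smoothing to the gradient.
    """
    labels = np.asarray(labels)
    out_data = np.stack([_smooth_np(x.data[i], labels[i]) for i in range(x.data.shape[0])])

    def backward_fn(g):
        if x.requires_grad:
            _accum(x, np.stack([_smooth_np(g[i], labels[i]) for i in range(g.shape[0])]))

    return _make(out_data, (x,), backward_fn)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits."""
    z = logits.data
    y = np.asarray(target, dtype=np.float32)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out_data = loss.mean(dtype=np.float32)
    n = z.size

    def backward_fn(g):
        _accum(logits, g * (_sigmoid_np(z) - y) / n)

    return _make(out_data, (logits,), backward_fn)


# -- optimizer ---------------------------------------------------------

class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
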