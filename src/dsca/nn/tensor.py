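"""Reverse-mode automatic differentiation on numpy arrays.

This is a deliberately small tape-based autodiff core: a :class:`Tensor`
wraps a float32 numpy array, every operation records a backward closure,
and :meth:`Tensor.backward` walks the tape in reverse topological order.
It implements exactly the operations the segmentation network needs
(convolution via im2col, batch normalisation, pooling, bilinear resize,
sigmoid gating, softmax cross-entropy) — nothing more.

Multiply-accumulate counting for the profiler is wired directly into the
dense operations (`conv2d`, `linear`, `matmul`); see :func:`count_macs`.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

_GRAD_ENABLED = True

# MAC counter state used by dsca.profiling
_MAC_COUNTER: dict[str, int | bool] = {"active": False, "macs": 0}


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (evaluation / prediction forwards)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def count_macs():
    """Context manager that tallies multiply-accumulates of dense ops.

    Yields a dict whose ``"macs"`` entry holds the running total.
    """
    _MAC_COUNTER["active"] = True
    _MAC_COUNTER["macs"] = 0
    try:
        yield _MAC_COUNTER
    finally:
        _MAC_COUNTER["active"] = False


def _add_macs(n: int) -> None:
    if _MAC_COUNTER["active"]:
        _MAC_COUNTER["macs"] += int(n)


class Tensor:
    """A numpy array with an optional gradient and autodiff tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff ------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs are deep for a 34-layer net)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def sum(self):
        return tensor_sum(self)

    def mean(self):
        return tensor_mean(self)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def tensor_sum(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return _make(np.asarray(a.data.sum(), dtype=np.float32), (a,), backward)


def tensor_mean(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        a._accumulate(np.broadcast_to(g / n, a.data.shape).astype(np.float32))

    return _make(np.asarray(a.data.mean(), dtype=np.float32), (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = expit(a.data).astype(np.float32)

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def amax_spatial(a: Tensor) -> Tensor:
    """Global max pooling over the two trailing spatial axes (N,C,H,W)->(N,C)."""
    n, c, h, w = a.data.shape
    flat = a.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=2)
    out = np.take_along_axis(flat, idx[..., None], axis=2)[..., 0]

    def backward(g):
        gx = np.zeros_like(flat)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=2)
        a._accumulate(gx.reshape(a.data.shape))

    return _make(out, (a,), backward)


def mean_spatial(a: Tensor) -> Tensor:
    """Global average pooling over the spatial axes (N,C,H,W)->(N,C)."""
    n, c, h, w = a.data.shape
    out = a.data.mean(axis=(2, 3))

    def backward(g):
        a._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), a.data.shape).astype(np.float32))

    return _make(out, (a,), backward)


# ---------------------------------------------------------------------------
# dense ops
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data
    _add_macs(data.size * a.data.shape[-1])

    def backward(g):
        a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return _make(data, (a, b), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map ``x @ w.T + b`` with ``x`` of shape (..., in), ``w`` (out, in)."""
    data = x.data @ w.data.T
    _add_macs(data.size // w.data.shape[0] * w.data.shape[0] * w.data.shape[1])
    if b is not None:
        data = data + b.data

    def backward(g):
        x._accumulate(g @ w.data)
        gw = np.tensordot(g.reshape(-1, g.shape[-1]).T, x.data.reshape(-1, x.data.shape[-1]), axes=1)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _conv_out_size(size: int, k: int, stride: int, pad: int, dil: int) -> int:
    eff = dil * (k - 1) + 1
    return (size + 2 * pad - eff) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, dil: int,
            pad_value: float = 0.0):
    n, c, h, w = x.shape
    ho = _conv_out_size(h, kh, stride, pad, dil)
    wo = _conv_out_size(w, kw, stride, pad, dil)
    if ho < 1 or wo < 1:
        raise ValueError(f"convolution output would be empty for input {h}x{w}")
    if pad:
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                    constant_values=pad_value)
    else:
        xp = x
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i * dil:i * dil + (ho - 1) * stride + 1:stride,
                                  j * dil:j * dil + (wo - 1) * stride + 1:stride]
    return cols, ho, wo


def _col2im(gcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int,
            dil: int) -> np.ndarray:
    n, c, h, w = x_shape
    ho, wo = gcols.shape[-2:]
    gxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i * dil:i * dil + (ho - 1) * stride + 1:stride,
                j * dil:j * dil + (wo - 1) * stride + 1:stride] += gcols[:, :, i, j]
    if pad:
        return gxp[:, :, pad:-pad, pad:-pad]
    return gxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (Cout, Cin, kh, kw)."""
    cout, cin, kh, kw = w.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.data.shape[1]} channels, weight expects {cin}")
    n = x.data.shape[0]
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding, dilation)
    k = cin * kh * kw
    cols2 = cols.reshape(n, k, ho * wo)
    wm = w.data.reshape(cout, k)
    out = np.matmul(wm, cols2)  # (n, cout, ho*wo)
    _add_macs(n * cout * ho * wo * k)
    out = out.reshape(n, cout, ho, wo)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        gflat = g.reshape(n, cout, ho * wo)
        gw = np.einsum("ncl,nkl->ck", gflat, cols2, optimize=True).reshape(w.data.shape)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        gcols = np.matmul(wm.T, gflat).reshape(n, cin, kh, kw, ho, wo)
        x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, padding, dilation))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.data.shape
    cols, ho, wo = _im2col(x.data, kernel, kernel, stride, padding, 1,
                           pad_value=-np.inf)
    cols2 = cols.reshape(n, c, kernel * kernel, ho * wo)
    idx = cols2.argmax(axis=2)
    out = np.take_along_axis(cols2, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        gcols = np.zeros_like(cols2)
        np.put_along_axis(gcols, idx[:, :, None, :], g.reshape(n, c, 1, ho * wo), axis=2)
        gcols = gcols.reshape(n, c, kernel, kernel, ho, wo)
        x._accumulate(_col2im(gcols, x.data.shape, kernel, kernel, stride, padding, 1))

    return _make(out.reshape(n, c, ho, wo), (x,), backward)


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Adaptive average pooling with torch-style uneven bin edges."""
    n, c, h, w = x.data.shape
    oh, ow = out_hw
    rows = [(i * h // oh, -(-(i + 1) * h // oh)) for i in range(oh)]
    cols = [(j * w // ow, -(-(j + 1) * w // ow)) for j in range(ow)]
    out = np.empty((n, c, oh, ow), dtype=x.data.dtype)
    for i, (r0, r1) in enumerate(rows):
        for j, (c0, c1) in enumerate(cols):
            out[:, :, i, j] = x.data[:, :, r0:r1, c0:c1].mean(axis=(2, 3))

    def backward(g):
        gx = np.zeros_like(x.data)
        for i, (r0, r1) in enumerate(rows):
            for j, (c0, c1) in enumerate(cols):
                area = (r1 - r0) * (c1 - c0)
                gx[:, :, r0:r1, c0:c1] += g[:, :, i, j][:, :, None, None] / area
        x._accumulate(gx)

    return _make(out, (x,), backward)


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear interpolation to ``out_hw`` (half-pixel centers, no corner alignment)."""
    n, c, h, w = x.data.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        def backward_id(g):
            x._accumulate(g)
        return _make(x.data.copy(), (x,), backward_id)

    def axis_weights(src: int, dst: int):
        pos = (np.arange(dst, dtype=np.float64) + 0.5) * (src / dst) - 0.5
        pos = np.clip(pos, 0.0, src - 1.0)
        i0 = np.floor(pos).astype(np.intp)
        i1 = np.minimum(i0 + 1, src - 1)
        t = (pos - i0).astype(np.float32)
        return i0, i1, t

    r0, r1, ty = axis_weights(h, oh)
    c0, c1, tx = axis_weights(w, ow)
    ty2 = ty[:, None]
    tx2 = tx[None, :]
    top = x.data[:, :, r0[:, None], c0[None, :]] * (1 - tx2) + \
        x.data[:, :, r0[:, None], c1[None, :]] * tx2
    bot = x.data[:, :, r1[:, None], c0[None, :]] * (1 - tx2) + \
        x.data[:, :, r1[:, None], c1[None, :]] * tx2
    out = top * (1 - ty2) + bot * ty2

    def backward(g):
        gx = np.zeros_like(x.data)
        for ri, wy in ((r0, 1 - ty2), (r1, ty2)):
            for ci, wx in ((c0, 1 - tx2), (c1, tx2)):
                contrib = (g * (wy * wx)).astype(np.float32)
                np.add.at(gx, (slice(None), slice(None), ri[:, None], ci[None, :]), contrib)
        x._accumulate(gx)

    return _make(out.astype(np.float32), (x,), backward)


# ---------------------------------------------------------------------------
# normalisation and loss
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation on NCHW; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = x.data.size // x.data.shape[1]
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        # unbiased running variance, biased batch variance in the forward pass
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    if training:
        def backward(g):
            m = x.data.size // x.data.shape[1]
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            dbeta = g.sum(axis=(0, 2, 3))
            gamma._accumulate(dgamma)
            beta._accumulate(dbeta)
            gi = (gamma.data * inv)[None, :, None, None]
            gx = gi * (g - dbeta[None, :, None, None] / m
                       - xhat * dgamma[None, :, None, None] / m)
            x._accumulate(gx.astype(np.float32))
    else:
        def backward(g):
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            x._accumulate((g * (gamma.data * inv)[None, :, None, None]).astype(np.float32))

    return _make(out.astype(np.float32), (x, gamma, beta), backward)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``logits`` (N,K,...) and integer ``target`` (N,...)."""
    z = logits.data
    target = np.asarray(target)
    if target.shape != z.shape[:1] + z.shape[2:]:
        raise ValueError(f"target shape {target.shape} does not match logits {z.shape}")
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sez = ez.sum(axis=1, keepdims=True)
    logp = (z - zmax) - np.log(sez)
    npix = target.size
    picked = np.take_along_axis(logp, target[:, None].astype(np.intp), axis=1)
    loss = -picked.sum() / npix

    def backward(g):
        p = ez / sez
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, target[:, None].astype(np.intp), 1.0, axis=1)
        logits._accumulate((g * (p - onehot) / npix).astype(np.float32))

    return _make(np.asarray(loss, dtype=np.float32), (logits,), backward)
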