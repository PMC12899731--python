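"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The detector stack in this package (convolutions, batch normalization,
attention, the training loop) runs on this compact tape-based autograd.
Only the primitives the architecture actually needs are implemented; each
op records a backward closure and :meth:`Tensor.backward` replays the tape
in reverse topological order.

Conventions
-----------
* Activations are ``float32`` by default; numerically sensitive tests may
  build models in ``float64`` (every op preserves the input dtype).
* ``Tensor`` wraps ``numpy.ndarray``; ``requires_grad`` propagates through
  ops, and constants can be plain arrays/scalars (auto-wrapped, no grad).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add", "sub", "mul", "div", "neg", "pow_const", "matmul",
    "exp", "log", "sqrt", "sigmoid", "silu", "relu", "tanh",
    "softmax", "clip",
    "sum_", "mean_", "reshape", "transpose", "concat", "narrow", "index_select",
    "conv2d", "maxpool2d", "upsample_nearest2x", "pad2d",
    "mac_counter",
]


class _MacCounter:
    """Global multiply–accumulate counter used by the FLOP profiler.

    Only ops representing learnable conv/linear layers contribute (the
    ``count`` flag on :func:`conv2d` / :func:`matmul`), matching the usual
    convention where normalization, activations and pooling are excluded.
    """

    def __init__(self) -> None:
        self.active = False
        self.macs = 0

    def reset(self) -> None:
        self.macs = 0

    def add(self, n: int) -> None:
        if self.active:
            self.macs += int(n)


mac_counter = _MacCounter()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the tape as we go
            node._backward = None
            node._parents = ()

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g.flags.writeable is False else g
        else:
            self.grad = self.grad + g

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis, keepdims)


def tensor(data, requires_grad=False) -> Tensor:
    if isinstance(data, Tensor):
        return data
    return Tensor(np.asarray(data), requires_grad=requires_grad)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(p for p in parents if p.requires_grad),
                  backward=backward if req else None)


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def div(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(out_data, (a, b), backward)


def neg(a):
    a = _wrap(a)

    def backward(g):
        a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def pow_const(a, p: float):
    a = _wrap(a)
    out_data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1))

    return _make(out_data, (a,), backward)


def exp(a):
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    a = _wrap(a)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def sqrt(a):
    a = _wrap(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accumulate(g * 0.5 / out_data)

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = _wrap(a)
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(x.dtype)

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def tanh(a):
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), backward)


def relu(a):
    a = _wrap(a)
    out_data = np.maximum(a.data, 0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _make(out_data, (a,), backward)


def silu(a):
    """x * sigmoid(x) — the activation used throughout the detector."""
    a = _wrap(a)
    x = a.data
    s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                 np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(x.dtype)
    out_data = x * s

    def backward(g):
        a._accumulate(g * (s * (1.0 + x * (1.0 - s))))

    return _make(out_data, (a,), backward)


def clip(a, lo: float, hi: float):
    """Clamp with zero gradient outside [lo, hi]."""
    a = _wrap(a)
    out_data = np.clip(a.data, lo, hi)

    def backward(g):
        mask = (a.data >= lo) & (a.data <= hi)
        a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


def softmax(a, axis=-1):
    a = _wrap(a)
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shaping
# ---------------------------------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(a.data.dtype))
            return
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

    return _make(out_data, (a,), backward)


def mean_(a, axis=None, keepdims=False):
    a = _wrap(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g / n, a.data.shape).astype(a.data.dtype))
            return
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g / n, a.data.shape).astype(a.data.dtype))

    return _make(out_data, (a,), backward)


def reshape(a, shape):
    a = _wrap(a)
    if isinstance(shape, (list, tuple)) and len(shape) == 1 and isinstance(shape[0], (list, tuple)):
        shape = shape[0]

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes):
    a = _wrap(a)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis=1):
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tuple(tensors), backward)


def narrow(a, axis, start, length):
    """Contiguous slice along one axis (gradient is zero-padded back)."""
    a = _wrap(a)
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        a._accumulate(full)

    return _make(a.data[idx], (a,), backward)


def index_select(a, idx, axis=0):
    """Gather along one axis with integer indices (backward scatter-adds)."""
    a = _wrap(a)
    idx = np.asarray(idx, dtype=np.int64)
    out_data = np.take(a.data, idx, axis=axis)

    def backward(g):
        full = np.zeros_like(a.data)
        sl = [slice(None)] * a.data.ndim
        sl[axis] = idx
        np.add.at(full, tuple(sl), g)
        a._accumulate(full)

    return _make(out_data, (a,), backward)


def matmul(a, b, count=False):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data
    if count:
        # MACs = output elements * inner dimension
        mac_counter.add(out_data.size * a.data.shape[-1])

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# spatial ops (N, C, H, W)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = x.strides
    win = np.lib.stride_tricks.as_strided(
        x, (n, c, ho, wo, kh, kw), (s0, s1, s2 * stride, s3 * stride, s2, s3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho * wo, c * kh * kw)
    return cols, ho, wo


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad, ho, wo):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad:pad + h, pad:pad + w]
    return dxp


def conv2d(x, weight, bias=None, stride=1, padding=0, groups=1, count=True):
    """2-D cross-correlation. weight: (Cout, Cin//groups, kh, kw)."""
    x, weight = _wrap(x), _wrap(weight)
    if bias is not None:
        bias = _wrap(bias)
    n, c, h, w = x.data.shape
    cout, cing, kh, kw = weight.data.shape
    if c != cing * groups:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {cing * groups}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    if count:
        mac_counter.add(n * cout * ho * wo * cing * kh * kw)
    wmat = weight.data.reshape(cout, cing * kh * kw)
    if groups == 1:
        out = cols @ wmat.T                      # (n, L, cout)
    else:
        cpg = c // groups
        opg = cout // groups
        cols_g = cols.reshape(n, ho * wo, groups, cpg * kh * kw)
        w_g = wmat.reshape(groups, opg, cpg * kh * kw)
        out = np.einsum("nlgk,gok->nlgo", cols_g, w_g).reshape(n, ho * wo, cout)
    out_data = out.transpose(0, 2, 1).reshape(n, cout, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.reshape(n, cout, ho * wo).transpose(0, 2, 1)   # (n, L, cout)
        if weight.requires_grad:
            if groups == 1:
                dw = np.einsum("nlo,nlk->ok", gmat, cols)
            else:
                cpg = c // groups
                opg = cout // groups
                cols_g = cols.reshape(n, ho * wo, groups, cpg * kh * kw)
                g_g = gmat.reshape(n, ho * wo, groups, opg)
                dw = np.einsum("nlgo,nlgk->gok", g_g, cols_g).reshape(cout, cpg * kh * kw)
            weight._accumulate(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if groups == 1:
                dcols = gmat @ wmat
            else:
                cpg = c // groups
                opg = cout // groups
                w_g = wmat.reshape(groups, opg, cpg * kh * kw)
                g_g = gmat.reshape(n, ho * wo, groups, opg)
                dcols = np.einsum("nlgo,gok->nlgk", g_g, w_g).reshape(n, ho * wo, c * kh * kw)
            x._accumulate(_col2im(dcols, (n, c, h, w), kh, kw, stride, padding, ho, wo))

    return _make(out_data, parents, backward)


def maxpool2d(x, kernel: int, stride: int = 1, padding: int = 0):
    x = _wrap(x)
    n, c, h, w = x.data.shape
    neg = np.finfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg) if padding else x.data
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, ho, wo, kernel, kernel), (s0, s1, s2 * stride, s3 * stride, s2, s3))
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=g.dtype)
        ki, kj = np.divmod(arg, kernel)
        ii = (np.arange(ho) * stride)[None, None, :, None] + ki
        jj = (np.arange(wo) * stride)[None, None, None, :] + kj
        nn_idx = np.arange(n)[:, None, None, None]
        cc_idx = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn_idx, cc_idx, ii, jj), g)
        if padding:
            dxp = dxp[:, :, padding:padding + h, padding:padding + w]
        x._accumulate(dxp)

    return _make(np.ascontiguousarray(out_data), (x,), backward)


def upsample_nearest2x(x):
    x = _wrap(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        x._accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward)


def pad2d(x, pad: int, mode: str = "zero"):
    """Spatial padding; mode 'zero' or 'replicate'."""
    x = _wrap(x)
    np_mode = "constant" if mode == "zero" else "edge"
    out_data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode=np_mode)
    n, c, h, w = x.data.shape

    def backward(g):
        core = g[:, :, pad:pad + h, pad:pad + w].copy()
        if mode == "replicate":
            core[:, :, 0, :] += g[:, :, :pad, pad:pad + w].sum(axis=2)
            core[:, :, -1, :] += g[:, :, pad + h:, pad:pad + w].sum(axis=2)
            core[:, :, :, 0] += g[:, :, pad:pad + h, :pad].sum(axis=3)
            core[:, :, :, -1] += g[:, :, pad:pad + h, pad + w:].sum(axis=3)
            core[:, :, 0, 0] += g[:, :, :pad, :pad].sum(axis=(2, 3))
            core[:, :, 0, -1] += g[:, :, :pad, pad + w:].sum(axis=(2, 3))
            core[:, :, -1, 0] += g[:, :, pad + h:, :pad].sum(axis=(2, 3))
            core[:, :, -1, -1] += g[:, :, pad + h:, pad + w:].sum(axis=(2, 3))
        x._accumulate(core)

    return _make(out_data, (x,), backward)
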