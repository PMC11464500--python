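"""Minimal reverse-mode autodiff engine and neural-network layers on numpy.

The detector in this package needs only a small, fixed set of primitives:
2-D convolution (im2col + GEMM), batch normalization, SiLU/sigmoid, stride-1
max/avg pooling, nearest/bilinear resizing, modulated deformable sampling,
and two optimizers.  They are implemented here on float32 numpy arrays with
a tape-based backward pass.  Gradient correctness of every primitive is
checked against central finite differences in the test-suite.

Conventions
-----------
* Feature maps are ``(N, C, H, W)`` float32 arrays.
* ``Parameter`` is a ``Tensor`` with ``requires_grad=True``.
* A module's trainable state is discovered by reflection over attributes,
  so plain attribute assignment registers sub-modules and parameters.
* Op accounting for FLOP reports: conv/linear multiply-accumulates and
  normalization output elements are tallied separately (see
  ``model_core.count_flops`` for the convention); pooling, activations
  and resizing are free.
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterable, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# global state: grad mode, init rng, MAC counter
# ---------------------------------------------------------------------------

_GRAD_ENABLED = True
_INIT_RNG = np.random.default_rng(0)
_MAC_COUNTER: list | None = None  # single-element list accumulating MACs


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def init_rng(rng: np.random.Generator):
    """Route parameter initialization through ``rng`` (deterministic builds)."""
    global _INIT_RNG
    prev = _INIT_RNG
    _INIT_RNG = rng
    try:
        yield
    finally:
        _INIT_RNG = prev


@contextlib.contextmanager
def count_macs():
    """Context accumulating op counts of the forward pass.

    Yields a dict with ``macs`` (conv/linear multiply-accumulates) and
    ``norm`` (normalization output elements); both feed the FLOP report.
    """
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    _MAC_COUNTER = {"macs": 0, "norm": 0}
    try:
        yield _MAC_COUNTER
    finally:
        _MAC_COUNTER = prev


def _add_macs(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER["macs"] += int(n)


def _add_norm_elems(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER["norm"] += int(n)


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32) if x.dtype != np.float32 else x
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go
                node._backward = None
                node._parents = ()

    # -- arithmetic --------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._coerce(other)
        a, b = self, o

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        a, b = self, o

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        a, b = self, o

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bw(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._make(out_data, (a,), bw)

    # -- elementwise functions --------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bw)

    def arctan(self):
        a = self

        def bw(g):
            a._accum(g / (1.0 + a.data * a.data))

        return Tensor._make(np.arctan(a.data), (a,), bw)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bw)

    def silu(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        out_data = a.data * s

        def bw(g):
            a._accum(g * (s * (1.0 + a.data * (1.0 - s))))

        return Tensor._make(out_data, (a,), bw)

    def clip(self, lo: float | None, hi: float | None):
        a = self
        out_data = np.clip(a.data, lo, hi)
        pass_mask = np.ones_like(a.data)
        if lo is not None:
            pass_mask *= (a.data >= lo)
        if hi is not None:
            pass_mask *= (a.data <= hi)

        def bw(g):
            a._accum(g * pass_mask)

        return Tensor._make(out_data, (a,), bw)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(i % a.data.ndim for i in ax)
                gg = np.expand_dims(gg, ax)
            a._accum(np.broadcast_to(gg, a.data.shape).astype(np.float32))

        return Tensor._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bw(g):
            a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(np.ascontiguousarray(a.data.transpose(axes)), (a,), bw)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def bw(g):
            full = np.zeros_like(a.data)
            has_array = any(isinstance(i, np.ndarray) for i in (idx if isinstance(idx, tuple) else (idx,)))
            if has_array:
                np.add.at(full, idx, g)  # may contain repeated indices
            else:
                full[idx] += g
            a._accum(full)

        return Tensor._make(np.ascontiguousarray(out_data), (a,), bw)

    def __matmul__(self, other):
        o = self._coerce(other)
        a, b = self, o
        out_data = a.data @ b.data
        _add_macs(a.data.size * b.data.shape[-1] // 1)

        def bw(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(out_data, (a, b), bw)


def maximum(a, b):
    """Elementwise max; ties send gradient to the first argument."""
    at = a if isinstance(a, Tensor) else Tensor(a)
    bt = b if isinstance(b, Tensor) else Tensor(b)
    take_a = at.data >= bt.data
    out_data = np.where(take_a, at.data, bt.data)

    def bw(g):
        if at.requires_grad:
            at._accum(_unbroadcast(g * take_a, at.data.shape))
        if bt.requires_grad:
            bt._accum(_unbroadcast(g * (~take_a), bt.data.shape))

    return Tensor._make(out_data, (at, bt), bw)


def minimum(a, b):
    at = a if isinstance(a, Tensor) else Tensor(a)
    bt = b if isinstance(b, Tensor) else Tensor(b)
    take_a = at.data <= bt.data
    out_data = np.where(take_a, at.data, bt.data)

    def bw(g):
        if at.requires_grad:
            at._accum(_unbroadcast(g * take_a, at.data.shape))
        if bt.requires_grad:
            bt._accum(_unbroadcast(g * (~take_a), bt.data.shape))

    return Tensor._make(out_data, (at, bt), bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    ts = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(np.ascontiguousarray(g[tuple(sl)]))

    return Tensor._make(out_data, ts, bw)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, s: int, ph: int, pw: int):
    n, c, h, w = x.shape
    ho = (h + 2 * ph - kh) // s + 1
    wo = (w + 2 * pw - kw) // s + 1
    if ph > 0 or pw > 0:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    sn, sc, sh, sw = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, ho, wo), (sn, sc, sh, sw, sh * s, sw * s)
    )
    # (N, L, C*kh*kw)
    col = np.ascontiguousarray(view.transpose(0, 4, 5, 1, 2, 3)).reshape(n, ho * wo, c * kh * kw)
    return col, ho, wo


def _col2im(dcol: np.ndarray, xshape, kh: int, kw: int, s: int, ph: int, pw: int, ho: int, wo: int):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=np.float32)
    d = dcol.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)  # N,C,kh,kw,Ho,Wo
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += d[:, :, i, j]
    if ph > 0 or pw > 0:
        return dxp[:, :, ph : ph + h, pw : pw + w]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding=0) -> Tensor:
    """2-D convolution, NCHW, dilation 1, groups 1; rectangular kernels OK."""
    co, ci, kh, kw = weight.data.shape
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    col, ho, wo = _im2col(x.data, kh, kw, stride, ph, pw)
    n = x.data.shape[0]
    wm = weight.data.reshape(co, ci * kh * kw)
    out = col.reshape(n * ho * wo, -1) @ wm.T
    if bias is not None:
        out += bias.data
    out = out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    _add_macs(n * ho * wo * ci * kh * kw * co)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, co)
        if weight.requires_grad:
            dw = g2.T @ col.reshape(n * ho * wo, -1)
            weight._accum(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g2.sum(axis=0))
        if x.requires_grad:
            dcol = g2 @ wm
            x._accum(_col2im(dcol.reshape(n, ho * wo, -1), x.data.shape, kh, kw, stride, ph, pw, ho, wo))

    return Tensor._make(np.ascontiguousarray(out), parents, bw)


# ---------------------------------------------------------------------------
# pooling and resizing
# ---------------------------------------------------------------------------


def maxpool2d_same(x: Tensor, k: int) -> Tensor:
    """Max pooling with odd kernel ``k``, stride 1, same padding (-inf fill)."""
    assert k % 2 == 1
    p = k // 2
    n, c, h, w = x.data.shape
    xp = np.full((n, c, h + 2 * p, w + 2 * p), -np.inf, dtype=np.float32)
    xp[:, :, p : p + h, p : p + w] = x.data
    best = np.full((n, c, h, w), -np.inf, dtype=np.float32)
    arg = np.zeros((n, c, h, w), dtype=np.int64)
    wp = w + 2 * p
    for i in range(k):
        for j in range(k):
            win = xp[:, :, i : i + h, j : j + w]
            m = win > best
            best = np.where(m, win, best)
            # flat index into padded map
            rows = np.arange(i, i + h)[:, None]
            cols = np.arange(j, j + w)[None, :]
            flat = (rows * wp + cols).astype(np.int64)
            arg = np.where(m, flat, arg)

    def bw(g):
        dxp = np.zeros((n, c, (h + 2 * p) * wp), dtype=np.float32)
        flat_arg = arg.reshape(n, c, -1)
        np.add.at(dxp, (np.arange(n)[:, None, None], np.arange(c)[None, :, None], flat_arg), g.reshape(n, c, -1))
        dxp = dxp.reshape(n, c, h + 2 * p, wp)
        x._accum(dxp[:, :, p : p + h, p : p + w])

    return Tensor._make(best, (x,), bw)


def _window_sum(a: np.ndarray, k: int) -> np.ndarray:
    """Sum over a k x k window, stride 1, zero 'same' padding."""
    p = k // 2
    n, c, h, w = a.shape
    ap = np.pad(a, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros_like(a)
    for i in range(k):
        for j in range(k):
            out += ap[:, :, i : i + h, j : j + w]
    return out


def _border_counts(h: int, w: int, k: int) -> np.ndarray:
    ones = np.ones((1, 1, h, w), dtype=np.float32)
    return _window_sum(ones, k)


def avgpool2d_same(x: Tensor, k: int) -> Tensor:
    """Average pooling, odd kernel, stride 1, same padding, borders averaged
    over the in-bounds elements only (count_include_pad = False)."""
    if k % 2 == 0:
        raise ValueError(f"pool kernel must be odd, got {k}")
    n, c, h, w = x.data.shape
    cnt = _border_counts(h, w, k)
    out = _window_sum(x.data, k) / cnt

    def bw(g):
        x._accum(_window_sum(g / cnt, k))

    return Tensor._make(out, (x,), bw)


def global_avgpool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3))


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bw(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bw)


_BILINEAR_CACHE: dict = {}


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    if key not in _BILINEAR_CACHE:
        a = np.zeros((n_out, n_in), dtype=np.float32)
        if n_in == 1:
            a[:, 0] = 1.0
        else:
            src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
            src = np.clip(src, 0, n_in - 1)
            lo = np.floor(src).astype(int)
            hi = np.minimum(lo + 1, n_in - 1)
            t = (src - lo).astype(np.float32)
            a[np.arange(n_out), lo] += 1.0 - t
            a[np.arange(n_out), hi] += t
        _BILINEAR_CACHE[key] = a
    return _BILINEAR_CACHE[key]


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize (align_corners=False), differentiable."""
    n, c, h, w = x.data.shape
    ho, wo = out_hw
    if (ho, wo) == (h, w):
        return x
    ah = _interp_matrix(ho, h)
    aw = _interp_matrix(wo, w)
    tmp = np.tensordot(x.data, ah, axes=([2], [1]))          # N,C,W,Ho
    out = np.tensordot(tmp, aw, axes=([2], [1]))             # N,C,Ho,Wo
    out = np.ascontiguousarray(out)

    def bw(g):
        t = np.tensordot(g, aw, axes=([3], [0]))             # N,C,Ho,W
        dx = np.tensordot(t, ah, axes=([2], [0]))            # N,C,W,H -> wait
        # g: N,C,Ho,Wo ; contract Wo with aw rows -> N,C,Ho,W ; contract Ho -> N,C,W,H
        x._accum(np.ascontiguousarray(dx.transpose(0, 1, 3, 2)))

    return Tensor._make(out, (x,), bw)


# ---------------------------------------------------------------------------
# modulated deformable 3x3 sampling
# ---------------------------------------------------------------------------


def deform_sample3x3(x: Tensor, offset: Tensor) -> Tensor:
    """Bilinearly sample the K=9 locations of a 3x3 grid plus learned offsets.

    x: (N, C, H, W); offset: (N, 18, H, W) ordered (dy_k, dx_k) per point.
    Returns (N, C, 9, H, W).  Out-of-bounds samples read as zero.
    """
    n, c, h, w = x.data.shape
    off = offset.data.reshape(n, 9, 2, h, w)
    gy, gx = np.meshgrid(np.arange(h, dtype=np.float32), np.arange(w, dtype=np.float32), indexing="ij")
    out = np.zeros((n, c, 9, h, w), dtype=np.float32)
    cache = []
    xd = x.data
    for kk in range(9):
        ky, kx = kk // 3 - 1, kk % 3 - 1
        py = gy[None] + ky + off[:, kk, 0]
        px = gx[None] + kx + off[:, kk, 1]
        y0 = np.floor(py)
        x0 = np.floor(px)
        ty = (py - y0).astype(np.float32)
        tx = (px - x0).astype(np.float32)
        corners = []
        for dy, wy in ((0, 1.0 - ty), (1, ty)):
            for dx, wx in ((0, 1.0 - tx), (1, tx)):
                yy = (y0 + dy).astype(np.int64)
                xx = (x0 + dx).astype(np.int64)
                valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
                yc = np.clip(yy, 0, h - 1)
                xc = np.clip(xx, 0, w - 1)
                wgt = (wy * wx * valid).astype(np.float32)  # (N,H,W)
                vals = xd[np.arange(n)[:, None, None], :, yc, xc]  # (N,H,W,C)
                out[:, :, kk] += vals.transpose(0, 3, 1, 2) * wgt[:, None]
                corners.append((yc, xc, valid, wgt, dy, dx))
        cache.append((corners, ty, tx))

    def bw(g):
        # g: (N, C, 9, H, W)
        need_x = x.requires_grad
        need_o = offset.requires_grad
        dx_full = np.zeros_like(xd) if need_x else None
        doff = np.zeros((n, 9, 2, h, w), dtype=np.float32) if need_o else None
        nidx = np.arange(n)[:, None, None]
        for kk in range(9):
            corners, ty, tx = cache[kk]
            gk = g[:, :, kk]  # (N,C,H,W)
            for (yc, xc, valid, wgt, dy, dx) in corners:
                if need_x:
                    contrib = (gk * wgt[:, None]).transpose(0, 2, 3, 1)  # N,H,W,C
                    np.add.at(dx_full.transpose(0, 2, 3, 1), (nidx, yc, xc), contrib)
                if need_o:
                    vals = xd[nidx, :, yc, xc].transpose(0, 3, 1, 2)  # N,C,H,W
                    s = (gk * vals).sum(axis=1) * valid  # N,H,W
                    wy = (1.0 - ty) if dy == 0 else ty
                    wx = (1.0 - tx) if dx == 0 else tx
                    doff[:, kk, 0] += s * (wx * (1.0 if dy == 1 else -1.0))
                    doff[:, kk, 1] += s * (wy * (1.0 if dx == 1 else -1.0))
        if need_x:
            x._accum(dx_full)
        if need_o:
            offset._accum(doff.reshape(n, 18, h, w))

    return Tensor._make(out, (x, offset), bw)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    _buffer_names: tuple = ()

    def __init__(self):
        self.training = True

    # -- reflection --------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for bname in self._buffer_names:
            yield prefix + bname, getattr(self, bname)
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- modes -------------------------------------------------------------
    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict:
        d = {k: v.data.copy() for k, v in self.named_parameters()}
        d.update({k: np.asarray(v).copy() for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, state: dict, strict: bool = True):
        """Load a flat name -> array mapping.

        Accepts partial mappings (e.g. backbone-only pre-trained weights);
        returns ``(missing, unexpected)`` key lists.
        """
        own_params = dict(self.named_parameters())
        own_bufs = dict(self._iter_buffer_slots())
        missing, loaded = [], set()
        for name, p in own_params.items():
            if name in state:
                arr = np.asarray(state[name], dtype=np.float32)
                if arr.shape != p.data.shape:
                    raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
                p.data[...] = arr
                loaded.add(name)
            else:
                missing.append(name)
        for name, (mod, attr) in own_bufs.items():
            if name in state:
                setattr(mod, attr, np.asarray(state[name], dtype=np.float32).copy())
                loaded.add(name)
            else:
                missing.append(name)
        unexpected = [k for k in state if k not in loaded]
        if strict and (missing or unexpected):
            raise KeyError(f"state mismatch: missing={missing[:5]}..., unexpected={unexpected[:5]}...")
        return missing, unexpected

    def _iter_buffer_slots(self, prefix: str = ""):
        for bname in self._buffer_names:
            yield prefix + bname, (self, bname)
        for cname, child in self._children():
            yield from child._iter_buffer_slots(prefix + cname + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = ModuleList(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k, stride: int = 1,
                 padding=None, bias: bool = True):
        super().__init__()
        kh, kw = (k, k) if isinstance(k, int) else k
        if padding is None:
            padding = ((kh - 1) // 2, (kw - 1) // 2)
        self.in_ch, self.out_ch, self.k, self.stride, self.padding = in_ch, out_ch, (kh, kw), stride, padding
        fan_in = in_ch * kh * kw
        bound = math.sqrt(1.0 / fan_in)
        self.weight = Parameter(_INIT_RNG.uniform(-bound, bound, (out_ch, in_ch, kh, kw)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True):
        super().__init__()
        bound = math.sqrt(1.0 / in_f)
        self.weight = Parameter(_INIT_RNG.uniform(-bound, bound, (out_f, in_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        wt = self.weight.transpose(1, 0)
        out = x @ wt
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        _add_norm_elems(x.data.size)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            with np.errstate(all="ignore"):
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu.data.reshape(-1))
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * unbiased)
            inv = (var + self.eps) ** -0.5
            xn = xc * inv
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, -1, 1, 1) + self.eps)
            xn = (x - mu) * inv
        w = self.weight.reshape(1, self.ch, 1, 1)
        b = self.bias.reshape(1, self.ch, 1, 1)
        return xn * w + b


class LayerNormChannel(Module):
    """Layer normalization over the channel axis of an NCHW map (token norm)."""

    def __init__(self, ch: int, eps: float = 1e-5):
        super().__init__()
        self.ch, self.eps = ch, eps
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))

    def forward(self, x: Tensor) -> Tensor:
        _add_norm_elems(x.data.size)
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.weight.reshape(1, self.ch, 1, 1) + self.bias.reshape(1, self.ch, 1, 1)


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class SGD:
    """SGD with momentum and (optionally) decoupled weight decay."""

    def __init__(self, params: Iterable[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, nesterov: bool = True):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay, self.nesterov = lr, momentum, weight_decay, nesterov
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            upd = g + self.momentum * v if self.nesterov else v
            p.data -= self.lr * upd

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
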