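"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the segmentation network needs are implemented:
elementwise arithmetic with broadcasting, reductions, reshape/concat/slice,
sigmoid/relu/exp/log/sqrt, 3D convolution (stride 1, symmetric zero
padding), 2x max-pooling, 2x trilinear up-sampling, softmax/log-softmax and
a fused cross-entropy. Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "evonorm_s0_op"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = parents if self.requires_grad or parents else ()
        self._backward = backward

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"], backward):
        needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if not needs:
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=tuple(parents),
                      backward=backward)

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        out_data = a.data + b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        out_data = a.data * b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)
        out_data = a.data / b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return self._make(out_data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    # -- unary -------------------------------------------------------------

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * 0.5 / out_data)

        return self._make(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def sigmoid(self):
        a = self
        out_data = expit(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), backward)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not a.requires_grad:
                return
            gg = g
            if not keepdims and axis is not None:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(ax % a.ndim for ax in axes)
                gg = np.expand_dims(g, axes)
            a._accumulate(np.broadcast_to(gg, a.shape).astype(np.float32))

        return self._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old_shape = a.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old_shape))

        return self._make(a.data.reshape(shape), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros(a.shape, dtype=np.float32)
                full[idx] = g
                a._accumulate(full)

        return self._make(a.data[idx], (a,), backward)

    # -- structured ops ----------------------------------------------------

    @staticmethod
    def concat(tensors: Iterable["Tensor"], axis: int = 1) -> "Tensor":
        ts = [Tensor._lift(t) for t in tensors]
        out_data = np.concatenate([t.data for t in ts], axis=axis)
        sizes = [t.shape[axis] for t in ts]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, start, stop in zip(ts, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(start, stop)
                    t._accumulate(g[tuple(sl)])

        return ts[0]._make(out_data, ts, backward)

    def softmax(self, axis: int = 1) -> "Tensor":
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if a.requires_grad:
                dot = (g * p).sum(axis=axis, keepdims=True)
                a._accumulate(p * (g - dot))

        return self._make(p, (a,), backward)

    def log_softmax(self, axis: int = 1) -> "Tensor":
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        p = np.exp(out_data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g - p * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (a,), backward)

    # -- convolution -------------------------------------------------------

    def conv3d(self, weight: "Tensor", bias: "Tensor | None" = None,
               pad: int = 0) -> "Tensor":
        """3D cross-correlation, stride 1, symmetric zero padding.

        x: (B, Ci, D, H, W); weight: (Co, Ci, k, k, k); bias: (Co,).
        Implemented as one batched GEMM over an im2col block, which is kept
        for the weight gradient; the input gradient scatters tap-wise GEMMs
        back into a padded buffer.
        """
        x, w = self, weight
        b, ci = x.shape[:2]
        co, ci_w, k = w.shape[0], w.shape[1], w.shape[2]
        if ci != ci_w:
            raise ValueError(f"conv3d channel mismatch: input {ci}, weight {ci_w}")
        if k == 1:
            return self._conv1x1(weight, bias)
        kt = k ** 3
        cols, out_spatial = _im2col(x.data, k, pad)  # (B, kt*Ci, S)
        wflat = np.ascontiguousarray(
            w.data.reshape(co, ci, kt).transpose(0, 2, 1).reshape(co, kt * ci))
        y = np.matmul(wflat, cols)  # (B, Co, S)
        out_data = y.reshape(b, co, *out_spatial)
        if bias is not None:
            out_data += bias.data.reshape(1, -1, 1, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)

        def backward(g):
            s = g.shape[2] * g.shape[3] * g.shape[4]
            g3 = g.reshape(b, co, s)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
            if w.requires_grad:
                gw = np.matmul(g3, cols.transpose(0, 2, 1)).sum(axis=0)
                w._accumulate(np.ascontiguousarray(
                    gw.reshape(co, kt, ci).transpose(0, 2, 1)).reshape(w.shape))
            if x.requires_grad:
                x._accumulate(_conv3d_grad_x(w.data, g3, x.shape, pad))

        return self._make(out_data, parents, backward)

    def _conv1x1(self, weight: "Tensor", bias: "Tensor | None") -> "Tensor":
        x, w = self, weight
        b, ci = x.shape[:2]
        co = w.shape[0]
        spatial = x.shape[2:]
        s = int(np.prod(spatial))
        wm = w.data[:, :, 0, 0, 0]
        out_data = np.matmul(wm, x.data.reshape(b, ci, s)).reshape(b, co, *spatial)
        if bias is not None:
            out_data += bias.data.reshape(1, -1, 1, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)

        def backward(g):
            g3 = g.reshape(b, co, s)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
            if w.requires_grad:
                gw = np.matmul(g3, x.data.reshape(b, ci, s).transpose(0, 2, 1))
                w._accumulate(gw.sum(axis=0).reshape(w.shape))
            if x.requires_grad:
                x._accumulate(np.matmul(wm.T, g3).reshape(x.shape))

        return self._make(out_data, parents, backward)

    def maxpool2(self) -> "Tensor":
        """2x2x2 max pooling, stride 2; spatial dims must be even."""
        a = self
        b, c, d, h, w = a.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"maxpool2 needs even spatial dims, got {(d, h, w)}")
        xr = a.data.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xt = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d // 2, h // 2, w // 2, 8)
        idx = xt.argmax(axis=-1)
        out_data = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            if not a.requires_grad:
                return
            gz = np.zeros((b, c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
            np.put_along_axis(gz, idx[..., None], g[..., None], axis=-1)
            gz = gz.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
            gz = gz.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d, h, w)
            a._accumulate(gz)

        return self._make(out_data, (a,), backward)

    def upsample2(self) -> "Tensor":
        """2x trilinear up-sampling (half-voxel aligned, edge clamped)."""
        a = self
        mats = [_upsample_matrix(n) for n in a.shape[2:]]
        out_data = a.data
        for axis, m in enumerate(mats):
            out_data = np.moveaxis(
                np.tensordot(m, np.moveaxis(out_data, axis + 2, 0), axes=(1, 0)),
                0, axis + 2)

        def backward(g):
            if not a.requires_grad:
                return
            gg = g
            for axis, m in enumerate(mats):
                gg = np.moveaxis(
                    np.tensordot(m.T, np.moveaxis(gg, axis + 2, 0), axes=(1, 0)),
                    0, axis + 2)
            a._accumulate(gg.astype(np.float32))

        return self._make(np.ascontiguousarray(out_data), (a,), backward)

    # -- loss --------------------------------------------------------------

    def cross_entropy(self, target: np.ndarray) -> "Tensor":
        """Mean -log softmax(logits)[target]; logits (B, N, *S), target (B, *S)."""
        a = self
        target = np.asarray(target)
        if target.min() < 0 or target.max() >= a.shape[1]:
            raise ValueError(
                f"target ids must be in [0, {a.shape[1] - 1}], got "
                f"[{target.min()}, {target.max()}]")
        shifted = a.data - a.data.max(axis=1, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        logp = shifted - lse
        picked = np.take_along_axis(logp, target[:, None], axis=1)[:, 0]
        count = picked.size
        out_data = -picked.sum() / count

        def backward(g):
            if not a.requires_grad:
                return
            p = np.exp(logp)
            onehot_grad = p.copy()
            np.put_along_axis(
                onehot_grad, target[:, None],
                np.take_along_axis(onehot_grad, target[:, None], axis=1) - 1.0,
                axis=1)
            a._accumulate(onehot_grad * (float(g) / count))

        return self._make(out_data, (a,), backward)


def evonorm_s0_op(x: Tensor, gamma: Tensor, beta: Tensor, v: Tensor,
                  groups: int, eps: float = 1e-5) -> Tensor:
    """Fused EvoNorm-S0: y = gamma * x * sigmoid(v*x) / sqrt(Var_g(x)+eps) + beta.

    The variance is the biased estimator per sample over each channel
    group's channels and all spatial positions. gamma/beta/v broadcast as
    (1, C, 1, 1, 1). Fused forward/backward keeps the graph small.
    """
    b, c = x.shape[0], x.shape[1]
    if c % groups:
        raise ValueError(f"channels {c} not divisible by {groups} norm groups")
    spatial = x.shape[2:]
    m = (c // groups) * int(np.prod(spatial))  # elements per group
    xd = x.data
    xg = xd.reshape(b, groups, -1)
    mu = xg.mean(axis=2)
    var = xg.var(axis=2)
    sigma = np.sqrt(var + eps)  # (b, groups)
    sig_full = np.repeat(sigma, c // groups, axis=1).reshape(
        b, c, *(1,) * len(spatial))
    s = expit(v.data * xd)
    num = xd * s
    inv = 1.0 / sig_full
    out_data = gamma.data * num * inv + beta.data

    def backward(g):
        gnum = gamma.data * g * inv
        if x.requires_grad:
            gx = gnum * (s + v.data * xd * s * (1.0 - s))
            # through sigma: dL/dsigma = -sum_group(gamma*g*num)/sigma^2
            gsig = -(gnum * num * inv).reshape(b, groups, -1).sum(axis=2)
            mu_full = np.repeat(mu, c // groups, axis=1).reshape(
                b, c, *(1,) * len(spatial))
            scale = (gsig / (m * sigma)).reshape(b, groups)
            scale_full = np.repeat(scale, c // groups, axis=1).reshape(
                b, c, *(1,) * len(spatial))
            gx = gx + scale_full * (xd - mu_full)
            x._accumulate(gx.astype(np.float32))
        reduce_axes = (0,) + tuple(range(2, xd.ndim))
        if gamma.requires_grad:
            gamma._accumulate((g * num * inv).sum(axis=reduce_axes,
                                                  keepdims=True).astype(np.float32))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=reduce_axes, keepdims=True).astype(np.float32))
        if v.requires_grad:
            gv = (gnum * xd * xd * s * (1.0 - s)).sum(axis=reduce_axes, keepdims=True)
            v._accumulate(gv.astype(np.float32))

    return x._make(out_data.astype(np.float32), (x, gamma, beta, v), backward)


# ---------------------------------------------------------------------------
# convolution internals (sum of shifted pointwise GEMMs)


def _im2col(x: np.ndarray, k: int, pad: int
            ) -> tuple[np.ndarray, tuple[int, int, int]]:
    """(B, k^3 * Ci, S) column block and the output spatial shape."""
    b, ci = x.shape[:2]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    do, ho, wo = x.shape[2] - k + 1, x.shape[3] - k + 1, x.shape[4] - k + 1
    kt = k ** 3
    cols = np.empty((b, kt, ci, do, ho, wo), dtype=np.float32)
    t = 0
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                cols[:, t] = x[:, :, dz:dz + do, dy:dy + ho, dx:dx + wo]
                t += 1
    return cols.reshape(b, kt * ci, do * ho * wo), (do, ho, wo)


def _conv3d_grad_x(w: np.ndarray, g3: np.ndarray, x_shape, pad: int
                   ) -> np.ndarray:
    """Scatter tap-wise GEMMs of the output gradient back onto the input."""
    b, ci, d, h, wd = x_shape
    co, _, k = w.shape[0], w.shape[1], w.shape[2]
    do, ho, wo = d + 2 * pad - k + 1, h + 2 * pad - k + 1, wd + 2 * pad - k + 1
    gx_pad = np.zeros((b, ci, d + 2 * pad, h + 2 * pad, wd + 2 * pad),
                      dtype=np.float32)
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                contrib = np.matmul(w[:, :, dz, dy, dx].T, g3)
                gx_pad[:, :, dz:dz + do, dy:dy + ho, dx:dx + wo] += \
                    contrib.reshape(b, ci, do, ho, wo)
    if pad:
        return gx_pad[:, :, pad:-pad, pad:-pad, pad:-pad]
    return gx_pad


_UPSAMPLE_CACHE: dict[int, np.ndarray] = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """(2n, n) interpolation matrix for 2x trilinear upsampling along one axis.

    Output sample i maps to input coordinate (i + 0.5)/2 - 0.5, clamped.
    """
    if n not in _UPSAMPLE_CACHE:
        m = np.zeros((2 * n, n), dtype=np.float32)
        for i in range(2 * n):
            x = (i + 0.5) / 2.0 - 0.5
            lo = int(np.floor(x))
            frac = x - lo
            lo_c = min(max(lo, 0), n - 1)
            hi_c = min(max(lo + 1, 0), n - 1)
            m[i, lo_c] += 1.0 - frac
            m[i, hi_c] += frac
        _UPSAMPLE_CACHE[n] = m
    return _UPSAMPLE_CACHE[n]
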