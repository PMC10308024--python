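"""Minimal reverse-mode automatic differentiation on numpy arrays.

This backend exists to support the 3D segmentation network: it provides
exactly the operator set the attention-gated residual U-Net and the soft
focal-Tversky loss need — elementwise arithmetic with broadcasting,
reductions, sigmoid/relu/softmax, stride-1 "same" 3x3x3 convolution,
non-overlapping stride-2 down/up convolutions (kernel 2), 1x1x1 convolution
and a factor-2 trilinear upsampler.  Convolutions are realised as matrix
multiplications (im2col / block-reshape), which is the only way to get
usable throughput out of numpy on CPU.

Tensors are channel-first: (C, D, H, W).  There is no batch axis; the
training recipe uses batch size 1 throughout, so the batch dimension is
implicit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "conv3x3",
    "conv1x1",
    "down2",
    "up2",
    "upsample2_linear",
    "softmax",
    "relu",
    "sigmoid",
    "switch_norm",
]


class Tensor:
    """A node in the computation graph: value, gradient and a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- graph mechanics ---------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        return self

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- convenience -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        return _elementwise_binary(self, _wrap(other), np.add,
                                   lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _elementwise_binary(self, _wrap(other), np.subtract,
                                   lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return _wrap(other).__sub__(self)

    def __mul__(self, other):
        return _elementwise_binary(self, _wrap(other), np.multiply,
                                   lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _elementwise_binary(self, _wrap(other), np.divide,
                                   lambda g, a, b: g / b,
                                   lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return _wrap(other).__truediv__(self)

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g / (2.0 * out_data))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def constant(x):
    return _wrap(x)


def parameter(x):
    return Tensor(np.asarray(x), requires_grad=True)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _elementwise_binary(a, b, fwd, dfda, dfdb):
    out_data = fwd(a.data, b.data)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(dfda(g, a.data, b.data), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(dfdb(g, a.data, b.data), b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


# -- nonlinearities --------------------------------------------------------

def relu(x):
    mask = x.data > 0

    def bwd(g):
        x._accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bwd)


def sigmoid(x):
    # clip to keep exp() in range; sigmoid saturates to 0/1 beyond +-60
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))

    def bwd(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=bwd)


def softmax(x, axis=0):
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accumulate(out_data * (g - dot))

    return Tensor(out_data, parents=(x,), backward=bwd)


def _softmax3(logits):
    e = np.exp(logits - logits.max())
    return e / e.sum()


def switch_norm(x, gain, bias, mean_logits, var_logits, eps=1e-5):
    """Switchable normalization with an implicit batch of one.

    Normalizes a (C, D, H, W) tensor by a learnable softmax mixture of
    instance, layer and batch statistics; with batch size 1 the batch
    statistics coincide with the instance statistics, but all three mixture
    weights are kept so the parametrization matches the general form.
    Fused forward/backward (a single composite node) — the normalization
    sits on every block of the network, so per-op overhead matters.
    """
    c = x.data.shape[0]
    xd = x.data.reshape(c, -1)
    s = xd.shape[1]

    mu_in = xd.mean(axis=1, keepdims=True)              # (C, 1)
    var_in = xd.var(axis=1, keepdims=True)
    mu_ly = xd.mean()
    var_ly = xd.var()

    wm = _softmax3(mean_logits.data)
    wv = _softmax3(var_logits.data)
    am, bm = wm[0] + wm[2], wm[1]     # instance(+batch) vs layer weight
    av, bv = wv[0] + wv[2], wv[1]

    mu = am * mu_in + bm * mu_ly                        # (C, 1)
    var = av * var_in + bv * var_ly
    r = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * r
    g_flat = gain.data.reshape(c, 1)
    out_data = (g_flat * xhat + bias.data.reshape(c, 1)).reshape(x.data.shape)

    def bwd(grad):
        gd = grad.reshape(c, -1)
        if gain.requires_grad:
            gain._accumulate((gd * xhat).sum(axis=1).reshape(gain.data.shape))
        if bias.requires_grad:
            bias._accumulate(gd.sum(axis=1).reshape(bias.data.shape))
        gx = gd * g_flat                                 # dL/dxhat
        dmu = -(gx * r).sum(axis=1, keepdims=True)       # dL/dmu(c)
        dvar = (-0.5) * (r ** 3) * (gx * (xd - mu)).sum(axis=1, keepdims=True)
        if x.requires_grad:
            dx = gx * r
            dx += (am * dmu + 2.0 * av * dvar * (xd - mu_in)) / s
            dx += (bm * dmu.sum() + 2.0 * bv * dvar.sum() * (xd - mu_ly)) / (c * s)
            x._accumulate(dx.reshape(x.data.shape))
        if mean_logits.requires_grad:
            # per-statistic sensitivities, then softmax backward
            dw = np.array([float((dmu * mu_in).sum()),
                           float(dmu.sum() * mu_ly),
                           float((dmu * mu_in).sum())])
            mean_logits._accumulate(wm * (dw - float(wm @ dw)))
        if var_logits.requires_grad:
            dv = np.array([float((dvar * var_in).sum()),
                           float(dvar.sum() * var_ly),
                           float((dvar * var_in).sum())])
            var_logits._accumulate(wv * (dv - float(wv @ dv)))

    return Tensor(out_data, parents=(x, gain, bias, mean_logits, var_logits),
                  backward=bwd)


# -- convolutions ----------------------------------------------------------

def _pad_flat(a):
    """Zero-pad one voxel on every spatial side; return (padded array,
    flat contiguous view, padded spatial shape)."""
    ap = np.pad(a, ((0, 0), (1, 1), (1, 1), (1, 1)))
    return ap, ap.reshape(a.shape[0], -1), ap.shape[1:]


def _shift_offsets(pshape):
    """Flat-index offsets of the 27 neighbours on the padded grid."""
    _, hp, wp = pshape
    return [(a - 1) * hp * wp + (b - 1) * wp + (c - 1)
            for a in range(3) for b in range(3) for c in range(3)]


def conv3x3(x, w):
    """'Same' 3x3x3 convolution, stride 1.  w: (Cout, Cin, 3, 3, 3).

    Computed as 27 shifted matrix products on a zero-padded, flattened
    grid: for interior voxels every shifted read stays in bounds and maps
    to the correct 3D neighbour, and the padded border of the output is
    simply discarded.  This avoids the large gather copies of an explicit
    im2col and keeps every operand contiguous for BLAS.
    """
    cout, cin = w.data.shape[:2]
    if x.data.shape[0] != cin:
        raise ValueError(f"conv3x3: input has {x.data.shape[0]} channels, "
                         f"kernel expects {cin}")
    spatial = x.data.shape[1:]
    _, xpf, pshape = _pad_flat(x.data)
    offs = _shift_offsets(pshape)
    npad = xpf.shape[1]
    wk = w.data.reshape(cout, cin, 27)

    out = np.zeros((cout, npad), dtype=x.data.dtype)
    for k, d in enumerate(offs):
        lo, hi = max(0, -d), min(npad, npad - d)
        out[:, lo:hi] += wk[:, :, k] @ xpf[:, lo + d:hi + d]
    interior = (slice(None), slice(1, -1), slice(1, -1), slice(1, -1))
    out_data = np.ascontiguousarray(out.reshape(cout, *pshape)[interior])

    def bwd(g):
        _, gpf, _ = _pad_flat(g)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            dwk = dw.reshape(cout, cin, 27)
            for k, d in enumerate(offs):
                lo, hi = max(0, -d), min(npad, npad - d)
                dwk[:, :, k] = gpf[:, lo:hi] @ xpf[:, lo + d:hi + d].T
            w._accumulate(dw)
        if x.requires_grad:
            dxp = np.zeros((cin, npad), dtype=g.dtype)
            wt = wk.transpose(1, 0, 2)   # (Cin, Cout, 27)
            for k, d in enumerate(offs):
                lo, hi = max(0, d), min(npad, npad + d)
                dxp[:, lo:hi] += wt[:, :, k] @ gpf[:, lo - d:hi - d]
            x._accumulate(
                np.ascontiguousarray(dxp.reshape(cin, *pshape)[interior]))

    return Tensor(out_data, parents=(x, w), backward=bwd)


def conv1x1(x, w):
    """Pointwise convolution.  w: (Cout, Cin)."""
    cin = x.data.shape[0]
    spatial = x.data.shape[1:]
    xf = x.data.reshape(cin, -1)
    out_data = (w.data @ xf).reshape(w.data.shape[0], *spatial)

    def bwd(g):
        gm = g.reshape(w.data.shape[0], -1)
        if w.requires_grad:
            w._accumulate(gm @ xf.T)
        if x.requires_grad:
            x._accumulate((w.data.T @ gm).reshape(x.data.shape))

    return Tensor(out_data, parents=(x, w), backward=bwd)


def _to_blocks(a):
    """(C, D, H, W) -> (C*8, D/2*H/2*W/2) gathering 2x2x2 blocks."""
    c, d, h, w = a.shape
    b = a.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    b = np.ascontiguousarray(b.transpose(0, 2, 4, 6, 1, 3, 5))
    return b.reshape(c * 8, -1)


def _from_blocks(b, c, spatial):
    d, h, w = spatial
    a = b.reshape(c, 2, 2, 2, d // 2, h // 2, w // 2)
    a = a.transpose(0, 4, 1, 5, 2, 6, 3)
    return np.ascontiguousarray(a).reshape(c, d, h, w)


def down2(x, w):
    """Stride-2, kernel-2 convolution (halves each spatial dim).

    w: (Cout, Cin, 2, 2, 2); non-overlapping windows, so it is a plain
    matrix product on 2x2x2 blocks.
    """
    cout, cin = w.data.shape[:2]
    if x.data.shape[0] != cin:
        raise ValueError(f"down2: input has {x.data.shape[0]} channels, "
                         f"kernel expects {cin}")
    spatial = x.data.shape[1:]
    xb = _to_blocks(x.data)
    wm = w.data.reshape(cout, cin * 8)
    out_spatial = tuple(s // 2 for s in spatial)
    out_data = (wm @ xb).reshape(cout, *out_spatial)

    def bwd(g):
        gm = g.reshape(cout, -1)
        if w.requires_grad:
            w._accumulate((gm @ xb.T).reshape(w.data.shape))
        if x.requires_grad:
            x._accumulate(_from_blocks(wm.T @ gm, cin, spatial))

    return Tensor(out_data, parents=(x, w), backward=bwd)


def up2(x, w):
    """Transposed convolution, kernel 2 stride 2 (doubles each spatial dim).

    w: (Cin, Cout, 2, 2, 2).
    """
    cin, cout = w.data.shape[:2]
    if x.data.shape[0] != cin:
        raise ValueError(f"up2: input has {x.data.shape[0]} channels, "
                         f"kernel expects {cin}")
    spatial = x.data.shape[1:]
    out_spatial = tuple(2 * s for s in spatial)
    xf = x.data.reshape(cin, -1)
    wm = w.data.reshape(cin, cout * 8)
    out_data = _from_blocks(wm.T @ xf, cout, out_spatial)

    def bwd(g):
        gb = _to_blocks(g)          # (Cout*8, V)
        if w.requires_grad:
            w._accumulate((xf @ gb.T).reshape(w.data.shape))
        if x.requires_grad:
            x._accumulate((wm @ gb).reshape(x.data.shape))

    return Tensor(out_data, parents=(x, w), backward=bwd)


# -- trilinear upsampling --------------------------------------------------

def _lin_up_axis(a, axis):
    """Factor-2 linear interpolation along one axis (edge-replicated)."""
    a = np.moveaxis(a, axis, -1)
    n = a.shape[-1]
    out = np.empty(a.shape[:-1] + (2 * n,), dtype=a.dtype)
    out[..., 0::2] = a
    out[..., 1:-1:2] = 0.5 * (a[..., :-1] + a[..., 1:])
    out[..., -1] = a[..., -1]
    return np.moveaxis(out, -1, axis)


def _lin_up_axis_adjoint(g, axis):
    g = np.moveaxis(g, axis, -1)
    n = g.shape[-1] // 2
    out = np.zeros(g.shape[:-1] + (n,), dtype=g.dtype)
    out += g[..., 0::2]
    mid = 0.5 * g[..., 1:-1:2]
    out[..., :-1] += mid
    out[..., 1:] += mid
    out[..., -1] += g[..., -1]  # trailing odd sample replicates a[-1]
    return np.moveaxis(out, -1, axis)


def upsample2_linear(x):
    """Trilinear factor-2 upsampling of a (C, D, H, W) tensor."""

    def fwd(a):
        for ax in (1, 2, 3):
            a = _lin_up_axis(a, ax)
        return a

    def adj(g):
        for ax in (3, 2, 1):
            g = _lin_up_axis_adjoint(g, ax)
        return g

    out_data = fwd(x.data)

    def bwd(g):
        x._accumulate(adj(g))

    return Tensor(out_data, parents=(x,), backward=bwd)
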