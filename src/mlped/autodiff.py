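"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerical engine behind :mod:`mlped.network`: a small tape-based
autograd with exactly the operations an encoder-decoder reconstruction CNN
needs (2-D convolution, instance normalisation, leaky ReLU, dropout, max/avg
pooling, bilinear resampling, pixel shuffle, concatenation and an L1
objective).  Every operation is vectorised; convolutions decompose into one
BLAS contraction per kernel tap, which keeps both directions exact and fast
for the image sizes this package works at.

Gradients are accumulated by summation, so a tensor feeding several consumers
(residual connections, concatenations) receives the correct total derivative.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "add",
    "mul",
    "sub",
    "scalar_affine",
    "leaky_relu",
    "conv2d",
    "instance_norm",
    "dropout",
    "max_pool2d",
    "avg_pool2d",
    "upsample_bilinear",
    "pixel_shuffle",
    "concat",
    "mean_abs_error",
]


class Tensor:
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- convenience -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor (leaf node with requires_grad=True)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _node(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, (gdim, sdim) in enumerate(zip(g.shape, shape)):
        if sdim == 1 and gdim != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / affine
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(g, b.shape))

    return _node(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g: np.ndarray) -> None:
        _accumulate(a, _unbroadcast(g * b.data, a.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g: np.ndarray) -> None:
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(-g, b.shape))

    return _node(out_data, (a, b), backward)


def scalar_affine(x: Tensor, scale: float, shift: float) -> Tensor:
    """``x * scale + shift`` for python-scalar scale/shift (no grad to them)."""
    out_data = x.data * scale + shift

    def backward(g: np.ndarray) -> None:
        _accumulate(x, g * scale)

    return _node(out_data, (x,), backward)


def leaky_relu(x: Tensor, negative_slope: float = 0.2) -> Tensor:
    factor = np.where(x.data >= 0, 1.0, negative_slope).astype(x.data.dtype)
    out_data = x.data * factor

    def backward(g: np.ndarray) -> None:
        _accumulate(x, g * factor)

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation of NCHW input with OIHW weights.

    Decomposed into kh*kw rank-updates: each kernel tap contributes a
    (C -> O) channel contraction over a strided spatial slice.  The adjoint
    scatters gradients back through the identical slices, so forward and
    backward agree to machine precision for any stride/padding.
    """
    n, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError("conv2d: kernel larger than padded input")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out_data = np.zeros((n, o, ho, wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            sub_ = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            out_data += np.tensordot(
                sub_, weight.data[:, :, i, j], axes=([1], [1])
            ).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data += bias.data.reshape(1, o, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g: np.ndarray) -> None:
        if bias is not None and bias.requires_grad:
            _accumulate(bias, g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        need_w = weight.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(weight.data) if need_w else None
        for i in range(kh):
            for j in range(kw):
                sub_ = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
                if need_w:
                    # (O,C) contraction over batch and space
                    gw[:, :, i, j] = np.tensordot(g, sub_, axes=([0, 2, 3], [0, 2, 3]))
                if need_x:
                    gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += (
                        np.tensordot(g, weight.data[:, :, i, j], axes=([1], [0]))
                        .transpose(0, 3, 1, 2)
                    )
        if need_w:
            _accumulate(weight, gw)
        if need_x:
            gx = gxp
            if padding:
                gx = gxp[:, :, padding:padding + h, padding:padding + w]
            _accumulate(x, gx)

    return _node(out_data, parents, backward)


# ---------------------------------------------------------------------------
# normalisation & regularisation
# ---------------------------------------------------------------------------

def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel standardisation over the spatial axes."""
    n, c, h, w = x.shape
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (x.data - mu) / std
    gview = gamma.data.reshape(1, c, 1, 1)
    out_data = gview * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accumulate(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            ghat = g * gview
            m1 = ghat.mean(axis=(2, 3), keepdims=True)
            m2 = (ghat * xhat).mean(axis=(2, 3), keepdims=True)
            _accumulate(x, (ghat - m1 - xhat * m2) / std)

    return _node(out_data, (x, gamma, beta), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    """Inverted dropout; identity when rate=0 or in eval mode."""
    if not training or rate == 0.0:
        return x
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    keep = (rng.random(x.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    out_data = x.data * keep

    def backward(g: np.ndarray) -> None:
        _accumulate(x, g * keep)

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int) -> Tensor:
    """Max pooling with window == stride == ``kernel`` (floor division).

    Trailing rows/columns that do not fill a window are dropped, as in the
    CE-Net residual multi-kernel pooling convention.
    """
    n, c, h, w = x.shape
    if h < kernel or w < kernel:
        raise ValueError(f"max_pool2d: spatial dims {h}x{w} smaller than kernel {kernel}")
    ho, wo = h // kernel, w // kernel
    hc, wc = ho * kernel, wo * kernel
    windows = (
        x.data[:, :, :hc, :wc]
        .reshape(n, c, ho, kernel, wo, kernel)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, ho, wo, kernel * kernel)
    )
    idx = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g: np.ndarray) -> None:
        gw = np.zeros_like(windows)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, :hc, :wc] = (
            gw.reshape(n, c, ho, wo, kernel, kernel)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, hc, wc)
        )
        _accumulate(x, gx)

    return _node(out_data, (x,), backward)


def avg_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    """Average pooling with window == stride; spatial dims must divide."""
    n, c, h, w = x.shape
    if h % kernel or w % kernel:
        raise ValueError(f"avg_pool2d: {h}x{w} not divisible by {kernel}")
    ho, wo = h // kernel, w // kernel
    out_data = (
        x.data.reshape(n, c, ho, kernel, wo, kernel).mean(axis=(3, 5))
    )

    def backward(g: np.ndarray) -> None:
        gx = np.repeat(np.repeat(g, kernel, axis=2), kernel, axis=3)
        _accumulate(x, gx / (kernel * kernel))

    return _node(out_data, (x,), backward)


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense 1-D bilinear resampling operator (half-pixel centres)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        frac = src - i0
        m[o, i0] += 1.0 - frac
        m[o, i1] += frac
    return m


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resampling to an arbitrary spatial size (align_corners=False)."""
    n, c, h, w = x.shape
    mh = _interp_matrix(h, out_h, x.data.dtype)
    mw = _interp_matrix(w, out_w, x.data.dtype)
    # y[n,c,oh,ow] = sum_{h,w} Mh[oh,h] * x[n,c,h,w] * Mw[ow,w]
    tmp = np.tensordot(x.data, mh, axes=([2], [1]))       # (N,C,W,OH)
    out_data = np.tensordot(tmp, mw, axes=([2], [1]))      # (N,C,OH,OW)

    def backward(g: np.ndarray) -> None:
        t = np.tensordot(g, mw, axes=([3], [0]))           # (N,C,OH,W)
        gx = np.tensordot(t, mh, axes=([2], [0]))          # (N,C,W,H)
        _accumulate(x, gx.transpose(0, 1, 3, 2))

    return _node(out_data, (x,), backward)


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Sub-pixel rearrangement (C*r^2, H, W) -> (C, H*r, W*r).

    Output pixel (c, h*r+dy, w*r+dx) takes input channel c*r^2 + dy*r + dx at
    (h, w); the map is a bijection on values.
    """
    if r < 1:
        raise ValueError("pixel_shuffle factor must be >= 1")
    n, c, h, w = x.shape
    if c % (r * r):
        raise ValueError(f"pixel_shuffle: {c} channels not divisible by r^2={r * r}")
    co = c // (r * r)
    out_data = (
        x.data.reshape(n, co, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, co, h * r, w * r)
    )

    def backward(g: np.ndarray) -> None:
        gx = (
            g.reshape(n, co, h, r, w, r)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, c, h, w)
        )
        _accumulate(x, gx)

    return _node(out_data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    if not ts:
        raise ValueError("concat of an empty sequence")
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])

    return _node(out_data, ts, backward)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def mean_abs_error(pred: Tensor, target: Tensor) -> Tensor:
    """Mean absolute (L1) error; subgradient 0 at exact ties."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred.data - target.data
    out_data = np.asarray(np.abs(diff).mean())
    sign = np.sign(diff) / diff.size

    def backward(g: np.ndarray) -> None:
        _accumulate(pred, g * sign)
        _accumulate(target, -g * sign)

    return _node(out_data, (pred, target), backward)
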