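"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the trainable parts of the package need:
elementwise arithmetic with broadcasting, matrix products, ReLU, reductions,
concatenation, strided 2D/3D convolution, bilinear/trilinear map sampling and
scatter-mean voxelization. Sampling coordinates and voxel indices are treated
as constants (no gradient flows through geometry), which matches how the
models are trained: gradients reach the feature maps and network weights only.

Everything is float64; the networks here are small enough that numerical
robustness is worth more than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "relu",
    "tsum",
    "tmean",
    "concat",
    "reshape",
    "conv2d",
    "conv3d",
    "bilinear2d",
    "trilinear3d",
    "voxelize_mean",
]


class Tensor:
    """A numpy array plus a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_parents", "_bw", "requires_grad")

    # make numpy defer binary ops to the reflected Tensor methods
    __array_ufunc__ = None

    def __init__(self, data, parents=(), bw=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._bw = bw
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph traversal ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return _add(self, astensor(other))

    def __radd__(self, other):
        return _add(astensor(other), self)

    def __sub__(self, other):
        return _add(self, _neg(astensor(other)))

    def __rsub__(self, other):
        return _add(astensor(other), _neg(self))

    def __neg__(self):
        return _neg(self)

    def __mul__(self, other):
        return _mul(self, astensor(other))

    def __rmul__(self, other):
        return _mul(astensor(other), self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return _mul(self, other ** -1.0)
        return _mul(self, astensor(1.0 / np.asarray(other, dtype=np.float64)))

    def __pow__(self, p):
        return _pow(self, float(p))

    def __matmul__(self, other):
        return _matmul(self, astensor(other))

    def __rmatmul__(self, other):
        return _matmul(astensor(other), self)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), bw)


def _neg(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, -g)

    return Tensor(-a.data, (a,), bw)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, (a, b), bw)


def _pow(a: Tensor, p: float) -> Tensor:
    out_data = a.data**p

    def bw(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return Tensor(out_data, (a,), bw)


def _matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bw(g):
        _accum(a, g @ b.data.swapaxes(-1, -2))
        _accum(b, a.data.swapaxes(-1, -2) @ g)

    return Tensor(out_data, (a, b), bw)


def relu(a: Tensor) -> Tensor:
    a = astensor(a)
    mask = a.data > 0

    def bw(g):
        _accum(a, g * mask)

    return Tensor(a.data * mask, (a,), bw)


def tsum(a: Tensor) -> Tensor:
    a = astensor(a)

    def bw(g):
        _accum(a, np.full_like(a.data, float(g)))

    return Tensor(a.data.sum(), (a,), bw)


def tmean(a: Tensor) -> Tensor:
    a = astensor(a)
    n = a.data.size

    def bw(g):
        _accum(a, np.full_like(a.data, float(g) / n))

    return Tensor(a.data.mean(), (a,), bw)


def concat(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return Tensor(out_data, tuple(tensors), bw)


def reshape(a: Tensor, shape) -> Tensor:
    a = astensor(a)
    old = a.data.shape

    def bw(g):
        _accum(a, g.reshape(old))

    return Tensor(a.data.reshape(shape), (a,), bw)


# -- convolutions -----------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2D convolution, single image. x: (C,H,W), w: (O,C,kh,kw), b: (O,)."""
    x, w = astensor(x), astensor(w)
    O, C, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad))) if pad else x.data
    _, Hp, Wp = xp.shape
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (C, Ho, Wo, kh, kw)
    cols = win.transpose(0, 3, 4, 1, 2).reshape(C * kh * kw, Ho * Wo)
    w2 = w.data.reshape(O, C * kh * kw)
    out = (w2 @ cols).reshape(O, Ho, Wo)
    parents = [x, w]
    if b is not None:
        b = astensor(b)
        out = out + b.data[:, None, None]
        parents.append(b)

    def bw(g):
        g2 = g.reshape(O, Ho * Wo)
        _accum(w, (g2 @ cols.T).reshape(w.data.shape))
        if b is not None:
            _accum(b, g.sum(axis=(1, 2)))
        if x.requires_grad:
            gcols = (w2.T @ g2).reshape(C, kh, kw, Ho, Wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i:i + stride * Ho:stride,
                        j:j + stride * Wo:stride] += gcols[:, i, j]
            _accum(x, gxp[:, pad:Hp - pad, pad:Wp - pad] if pad else gxp)

    return Tensor(out, tuple(parents), bw)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """3D convolution. x: (C,D,H,W), w: (O,C,kd,kh,kw), b: (O,)."""
    x, w = astensor(x), astensor(w)
    O, C, kd, kh, kw = w.data.shape
    xp = (np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
          if pad else x.data)
    _, Dp, Hp, Wp = xp.shape
    Do = (Dp - kd) // stride + 1
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kd, kh, kw),
                                                   axis=(1, 2, 3))
    win = win[:, ::stride, ::stride, ::stride]  # (C,Do,Ho,Wo,kd,kh,kw)
    cols = win.transpose(0, 4, 5, 6, 1, 2, 3).reshape(C * kd * kh * kw,
                                                      Do * Ho * Wo)
    w2 = w.data.reshape(O, -1)
    out = (w2 @ cols).reshape(O, Do, Ho, Wo)
    parents = [x, w]
    if b is not None:
        b = astensor(b)
        out = out + b.data[:, None, None, None]
        parents.append(b)

    def bw(g):
        g2 = g.reshape(O, Do * Ho * Wo)
        _accum(w, (g2 @ cols.T).reshape(w.data.shape))
        if b is not None:
            _accum(b, g.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            gcols = (w2.T @ g2).reshape(C, kd, kh, kw, Do, Ho, Wo)
            gxp = np.zeros_like(xp)
            for i in range(kd):
                for j in range(kh):
                    for k in range(kw):
                        gxp[:, i:i + stride * Do:stride,
                            j:j + stride * Ho:stride,
                            k:k + stride * Wo:stride] += gcols[:, i, j, k]
            _accum(x, gxp[:, pad:Dp - pad, pad:Hp - pad, pad:Wp - pad]
                   if pad else gxp)

    return Tensor(out, tuple(parents), bw)


# -- map sampling -----------------------------------------------------------


def bilinear2d(fmap: Tensor, uv: np.ndarray) -> Tensor:
    """Sample a (C,H,W) map at continuous (u,v)=(col,row) pixel coordinates.

    Coordinates are clipped to the map; returns (N,C). Gradient flows into
    the map only (uv is constant).
    """
    fmap = astensor(fmap)
    C, H, W = fmap.data.shape
    u = np.clip(uv[:, 0], 0.0, W - 1.0)
    v = np.clip(uv[:, 1], 0.0, H - 1.0)
    u0 = np.clip(np.floor(u).astype(int), 0, max(W - 2, 0))
    v0 = np.clip(np.floor(v).astype(int), 0, max(H - 2, 0))
    u1 = np.minimum(u0 + 1, W - 1)
    v1 = np.minimum(v0 + 1, H - 1)
    fu, fv = u - u0, v - v0
    w00 = (1 - fu) * (1 - fv)
    w01 = fu * (1 - fv)
    w10 = (1 - fu) * fv
    w11 = fu * fv
    f = fmap.data
    out = (f[:, v0, u0] * w00 + f[:, v0, u1] * w01
           + f[:, v1, u0] * w10 + f[:, v1, u1] * w11).T  # (N,C)

    def bw(g):
        gm = np.zeros_like(fmap.data)
        gt = g.T  # (C,N)
        np.add.at(gm, (slice(None), v0, u0), gt * w00)
        np.add.at(gm, (slice(None), v0, u1), gt * w01)
        np.add.at(gm, (slice(None), v1, u0), gt * w10)
        np.add.at(gm, (slice(None), v1, u1), gt * w11)
        _accum(fmap, gm)

    return Tensor(out, (fmap,), bw)


def trilinear3d(grid: Tensor, pts: np.ndarray) -> Tensor:
    """Sample a (C,D,H,W) grid at continuous (i,j,k) coordinates -> (N,C)."""
    grid = astensor(grid)
    C, D, H, W = grid.data.shape
    p = np.stack([np.clip(pts[:, 0], 0, D - 1),
                  np.clip(pts[:, 1], 0, H - 1),
                  np.clip(pts[:, 2], 0, W - 1)], axis=1)
    i0 = np.clip(np.floor(p).astype(int), 0,
                 np.array([max(D - 2, 0), max(H - 2, 0), max(W - 2, 0)]))
    i1 = np.minimum(i0 + 1, np.array([D - 1, H - 1, W - 1]))
    f = p - i0
    corners = []
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                idx = (np.where(di, i1[:, 0], i0[:, 0]),
                       np.where(dj, i1[:, 1], i0[:, 1]),
                       np.where(dk, i1[:, 2], i0[:, 2]))
                wgt = ((f[:, 0] if di else 1 - f[:, 0])
                       * (f[:, 1] if dj else 1 - f[:, 1])
                       * (f[:, 2] if dk else 1 - f[:, 2]))
                corners.append((idx, wgt))
    g = grid.data
    out = sum(g[:, idx[0], idx[1], idx[2]] * w for idx, w in corners).T

    def bw(gr):
        gg = np.zeros_like(grid.data)
        gt = gr.T
        for idx, w in corners:
            np.add.at(gg, (slice(None), idx[0], idx[1], idx[2]), gt * w)
        _accum(grid, gg)

    return Tensor(out, (grid,), bw)


def voxelize_mean(feats: Tensor, flat_idx: np.ndarray,
                  grid_shape: tuple[int, int, int]) -> Tensor:
    """Average per-point features into voxels. feats: (N,C) -> (C,D,H,W).

    flat_idx holds each point's flattened voxel index (constant). Empty
    voxels are zero.
    """
    feats = astensor(feats)
    D, H, W = grid_shape
    V = D * H * W
    counts = np.bincount(flat_idx, minlength=V).astype(np.float64)
    denom = np.maximum(counts, 1.0)
    C = feats.data.shape[1]
    sums = np.zeros((V, C))
    np.add.at(sums, flat_idx, feats.data)
    out = (sums / denom[:, None]).T.reshape(C, D, H, W)

    def bw(g):
        gv = g.reshape(C, V).T / denom[:, None]  # (V,C)
        _accum(feats, gv[flat_idx])

    return Tensor(out, (feats,), bw)
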