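"""Minimal reverse-mode autodiff on NumPy arrays.

This is the package's lightweight training engine: a tape-based ``Tensor``
plus the handful of array primitives the segmentation networks need
(convolution, batch norm, pooling, bilinear resampling, deformable
convolution, softmax losses). Everything runs in float32 on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add",
    "relu",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "batch_norm2d",
    "max_pool2d",
    "adaptive_avg_pool2d",
    "upsample_bilinear",
    "deform_conv2d",
    "focal_softmax_loss",
]


class Tensor:
    """A NumPy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape.

        The tape is released afterwards (closures capture their output
        tensor, a reference cycle the gc is slow to notice under large
        array allocations)."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        for t in topo:
            if t._prev:
                t._backward = None
                t._prev = ()
                t.grad = None

    def zero_grad(self):
        self.grad = None


class no_grad:
    """Context manager disabling tape construction (inference paths)."""

    def __enter__(self):
        global _grad_enabled
        self._saved = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._saved
        return False


_grad_enabled = True


def _make(data, parents, backward_fn):
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward_fn(out)
    return out


def _accum(t: Tensor, g: np.ndarray):
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


# ---------------------------------------------------------------------------
# elementwise


def add(a: Tensor, b: Tensor) -> Tensor:
    def bwd(out):
        def fn():
            _accum(a, out.grad)
            _accum(b, out.grad)

        return fn

    return _make(a.data + b.data, (a, b), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(out):
        def fn():
            _accum(x, out.grad * mask)

        return fn

    return _make(x.data * mask, (x,), bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(out):
        def fn():
            splits = np.split(out.grad, np.cumsum(sizes)[:-1], axis=axis)
            for t, g in zip(tensors, splits):
                _accum(t, g)

        return fn

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# convolution via im2col


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, dilation: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (eh, ew), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]  # n,c,oh,ow,kh,kw
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))  # n,c,kh,kw,oh,ow


def _col2im(cols, xshape, kh, kw, stride, pad, dilation):
    n, c, h, w = xshape
    oh, ow = cols.shape[4], cols.shape[5]
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[
                :,
                :,
                i * dilation : i * dilation + stride * oh : stride,
                j * dilation : j * dilation + stride * ow : stride,
            ] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0,
           dilation: int = 1) -> Tensor:
    """2-D cross-correlation with zero padding; w is (Cout, Cin, kh, kw)."""
    co, ci, kh, kw = w.data.shape
    cols = _im2col(x.data, kh, kw, stride, pad, dilation)
    n, _, _, _, oh, ow = cols.shape
    flat = cols.reshape(n, ci * kh * kw, oh * ow)
    y = (w.data.reshape(co, -1) @ flat).reshape(n, co, oh, ow)
    if b is not None:
        y = y + b.data.reshape(1, co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(out):
        def fn():
            gy = out.grad.reshape(n, co, oh * ow)
            if w.requires_grad:
                gw = np.einsum("nol,nkl->ok", gy, flat, optimize=True)
                _accum(w, gw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                _accum(b, out.grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gflat = np.einsum("ok,nol->nkl", w.data.reshape(co, -1), gy, optimize=True)
                gcols = gflat.reshape(n, ci, kh, kw, oh, ow)
                _accum(x, _col2im(gcols, x.data.shape, kh, kw, stride, pad, dilation))

        return fn

    return _make(y, parents, bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel size == stride (block upsampling).

    w is (Cin, Cout, k, k); each input pixel expands into a k x k block.
    """
    ci, co, k, _ = w.data.shape
    assert stride == k, "kernel size must equal stride for this operator"
    n, _, h, wd = x.data.shape
    blocks = np.einsum("nchw,cokl->nohkwl", x.data, w.data, optimize=True)
    y = blocks.reshape(n, co, h * k, wd * k)
    if b is not None:
        y = y + b.data.reshape(1, co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(out):
        def fn():
            gb = out.grad.reshape(n, co, h, k, wd, k)
            if x.requires_grad:
                _accum(x, np.einsum("nohkwl,cokl->nchw", gb, w.data, optimize=True))
            if w.requires_grad:
                _accum(w, np.einsum("nohkwl,nchw->cokl", gb, x.data, optimize=True))
            if b is not None and b.requires_grad:
                _accum(b, out.grad.sum(axis=(0, 2, 3)))

        return fn

    return _make(y, parents, bwd)


# ---------------------------------------------------------------------------
# normalization and pooling


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    y = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def bwd(out):
        def fn():
            g = out.grad
            if gamma.requires_grad:
                _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                _accum(beta, g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gi = g * gamma.data.reshape(1, -1, 1, 1)
                if training:
                    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                    s1 = gi.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    gx = (gi - s1 / m - xhat * s2 / m) * inv.reshape(1, -1, 1, 1)
                else:
                    gx = gi * inv.reshape(1, -1, 1, 1)
                _accum(x, gx.astype(np.float32))

        return fn

    return _make(y, (x, gamma, beta), bwd)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k max pooling with stride k; odd trailing rows/cols padded with -inf."""
    n, c, h, w = x.data.shape
    ph, pw = (-h) % k, (-w) % k
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
    oh, ow = xp.shape[2] // k, xp.shape[3] // k
    win = xp.reshape(n, c, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, k * k)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bwd(out):
        def fn():
            gwin = np.zeros_like(win)
            np.put_along_axis(gwin, idx[..., None], out.grad[..., None], axis=-1)
            gxp = gwin.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
            gxp = gxp.reshape(n, c, oh * k, ow * k)[:, :, :h, :w]
            _accum(x, gxp)

        return fn

    return _make(y, (x,), bwd)


def _pool_bounds(size: int, bins: int):
    starts = (np.arange(bins) * size) // bins
    ends = -((-(np.arange(bins) + 1) * size) // bins)
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, out_hw) -> Tensor:
    n, c, h, w = x.data.shape
    oh, ow = out_hw
    ys, ye = _pool_bounds(h, oh)
    xs, xe = _pool_bounds(w, ow)
    y = np.empty((n, c, oh, ow), dtype=np.float32)
    for i in range(oh):
        for j in range(ow):
            y[:, :, i, j] = x.data[:, :, ys[i] : ye[i], xs[j] : xe[j]].mean(axis=(2, 3))

    def bwd(out):
        def fn():
            gx = np.zeros_like(x.data)
            for i in range(oh):
                for j in range(ow):
                    area = (ye[i] - ys[i]) * (xe[j] - xs[j])
                    gx[:, :, ys[i] : ye[i], xs[j] : xe[j]] += (
                        out.grad[:, :, i, j][:, :, None, None] / area
                    )
            _accum(x, gx)

        return fn

    return _make(y, (x,), bwd)


def _bilinear_axis(in_size: int, out_size: int):
    """Source indices and weights for non-corner-aligned bilinear resampling."""
    pos = (np.arange(out_size) + 0.5) * in_size / out_size - 0.5
    pos = np.clip(pos, 0, in_size - 1)
    i0 = np.floor(pos).astype(np.int64)
    i1 = np.minimum(i0 + 1, in_size - 1)
    w1 = (pos - i0).astype(np.float32)
    return i0, i1, 1.0 - w1, w1


def upsample_bilinear(x: Tensor, out_hw) -> Tensor:
    n, c, h, w = x.data.shape
    oh, ow = out_hw
    r0, r1, wr0, wr1 = _bilinear_axis(h, oh)
    c0, c1, wc0, wc1 = _bilinear_axis(w, ow)
    rows = x.data[:, :, r0, :] * wr0[None, None, :, None] + x.data[:, :, r1, :] * wr1[None, None, :, None]
    y = rows[:, :, :, c0] * wc0 + rows[:, :, :, c1] * wc1

    def bwd(out):
        def fn():
            grows = np.zeros((n, c, oh, w), dtype=np.float32)
            np.add.at(grows, (slice(None), slice(None), slice(None), c0), out.grad * wc0)
            np.add.at(grows, (slice(None), slice(None), slice(None), c1), out.grad * wc1)
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), slice(None), r0, slice(None)),
                      grows * wr0[None, None, :, None])
            np.add.at(gx, (slice(None), slice(None), r1, slice(None)),
                      grows * wr1[None, None, :, None])
            _accum(x, gx)

        return fn

    return _make(y.astype(np.float32), (x,), bwd)


# ---------------------------------------------------------------------------
# deformable convolution (stride 1, same padding)


def deform_conv2d(x: Tensor, offsets: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Deformable 2-D convolution: kernel sampling points displaced per position.

    ``offsets`` has 2*N channels ordered (dy, dx) per kernel element n; the
    displaced positions are sampled from ``x`` by bilinear interpolation with
    zero padding outside the array. Offsets are shared across input channels.
    """
    n, ci, h, wd = x.data.shape
    co, ci2, kh, kw = w.data.shape
    if ci2 != ci:
        raise ValueError(f"channel mismatch: input has {ci}, kernel expects {ci2}")
    nk = kh * kw
    if offsets.data.shape != (n, 2 * nk, h, wd):
        raise ValueError(
            f"offset field shape {offsets.data.shape} != {(n, 2 * nk, h, wd)}"
        )
    off = offsets.data.reshape(n, nk, 2, h, wd)
    ky, kx = np.meshgrid(np.arange(kh) - (kh - 1) // 2, np.arange(kw) - (kw - 1) // 2,
                         indexing="ij")
    base_y = np.arange(h)[None, :, None] + ky.ravel()[:, None, None]  # nk,h,w
    base_x = np.arange(wd)[None, None, :] + kx.ravel()[:, None, None]
    py = base_y[None] + off[:, :, 0]  # n,nk,h,w
    px = base_x[None] + off[:, :, 1]

    y0 = np.floor(py).astype(np.int64)
    x0 = np.floor(px).astype(np.int64)
    wy1 = (py - y0).astype(np.float32)
    wx1 = (px - x0).astype(np.float32)
    corners = []
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        cy, cx = y0 + dy, x0 + dx
        inb = ((cy >= 0) & (cy < h) & (cx >= 0) & (cx < wd)).astype(np.float32)
        cyc, cxc = np.clip(cy, 0, h - 1), np.clip(cx, 0, wd - 1)
        wgt = (wy1 if dy else 1 - wy1) * (wx1 if dx else 1 - wx1) * inb
        corners.append((cyc, cxc, wgt, inb, dy, dx))

    ni = np.arange(n)[:, None, None, None]
    sampled = np.zeros((n, ci, nk, h, wd), dtype=np.float32)
    gathered = []
    for cyc, cxc, wgt, inb, dy, dx in corners:
        vals = x.data[ni, :, cyc, cxc].transpose(0, 4, 1, 2, 3) * inb[:, None]
        gathered.append(vals)
        sampled += vals * wgt[:, None]
    wr = w.data.reshape(co, ci, nk)
    y = np.einsum("nckhw,ock->nohw", sampled, wr, optimize=True)
    if b is not None:
        y = y + b.data.reshape(1, co, 1, 1)
    parents = [x, offsets, w] + ([b] if b is not None else [])

    def bwd(out):
        def fn():
            gs = np.einsum("nohw,ock->nckhw", out.grad, wr, optimize=True)
            if w.requires_grad:
                gw = np.einsum("nohw,nckhw->ock", out.grad, sampled, optimize=True)
                _accum(w, gw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                _accum(b, out.grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gx = np.zeros_like(x.data)
                for cyc, cxc, wgt, inb, dy, dx in corners:
                    contrib = (gs * wgt[:, None]).transpose(0, 2, 3, 4, 1)  # n,nk,h,w,c
                    np.add.at(gx, (ni, slice(None), cyc, cxc),
                              contrib.transpose(0, 1, 2, 3, 4))
                _accum(x, gx)
            if offsets.requires_grad:
                gpy = np.zeros((n, nk, h, wd), dtype=np.float32)
                gpx = np.zeros((n, nk, h, wd), dtype=np.float32)
                for vals, (cyc, cxc, wgt, inb, dy, dx) in zip(gathered, corners):
                    per = (gs * vals).sum(axis=1)  # n,nk,h,w
                    sy = 1.0 if dy else -1.0
                    sx = 1.0 if dx else -1.0
                    gpy += per * sy * (wx1 if dx else 1 - wx1)
                    gpx += per * sx * (wy1 if dy else 1 - wy1)
                goff = np.stack([gpy, gpx], axis=2).reshape(n, 2 * nk, h, wd)
                _accum(offsets, goff)

        return fn

    return _make(y, parents, bwd)


# ---------------------------------------------------------------------------
# loss


def focal_softmax_loss(logits: Tensor, target: np.ndarray, gamma: float = 2.0,
                       valid: np.ndarray | None = None, eps: float = 1e-8) -> Tensor:
    """Mean focal loss -(1-p_t)^gamma * log(p_t) over valid pixels.

    gamma=0 recovers plain softmax cross-entropy. ``target`` holds integer
    class ids (N,H,W); ``valid`` optionally masks pixels out of the mean
    (letterbox padding).
    """
    n, c, h, w = logits.data.shape
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    onehot = np.eye(c, dtype=np.float32)[target].transpose(0, 3, 1, 2)
    pt = np.maximum((p * onehot).sum(axis=1), eps)  # n,h,w
    if valid is None:
        valid = np.ones((n, h, w), dtype=np.float32)
    else:
        valid = valid.astype(np.float32)
    m = max(valid.sum(), 1.0)
    per_pixel = -((1 - pt) ** gamma) * np.log(pt)
    loss = float((per_pixel * valid).sum() / m)

    def bwd(out):
        def fn():
            if gamma == 0:
                dpt = -1.0 / pt
            else:
                dpt = gamma * (1 - pt) ** (gamma - 1) * np.log(pt) - (1 - pt) ** gamma / pt
            coef = dpt * pt * valid / m  # n,h,w
            gz = coef[:, None] * (onehot - p)
            _accum(logits, (gz * out.grad).astype(np.float32))

        return fn

    return _make(np.float32(loss), (logits,), bwd)
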