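"""Reference 2-D deformable convolution.

A deformable convolution displaces each kernel sampling point by a learned
fractional offset and reads the input there by bilinear interpolation:

    y(p0) = sum_n w(p_n) * x(p0 + p_n + dp_n)

with the bilinear kernel  g(a, b) = max(0, 1 - |a - b|)  applied per axis, so
only the four integer neighbours of a sampling point contribute. Positions
outside the array contribute zero (zero padding).

This module is the plain-NumPy single-channel reference used throughout the
tests; :class:`frogeye.nn.DeformConv2d` is the multi-channel trainable layer
built on the same math. Coordinates are (row, col) with y down, x right.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["sampling_grid", "bilinear_sample", "standard_conv2d", "deform_conv2d",
           "OffsetPredictor"]


def sampling_grid(k: int) -> np.ndarray:
    """Regular k x k sampling grid R: integer displacements, row-major.

    For k=3 this is {(-1,-1), (-1,0), ..., (1,1)}; N = k**2 elements.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("kernel size must be a positive odd integer")
    c = (k - 1) // 2
    return np.array([(i - c, j - c) for i in range(k) for j in range(k)],
                    dtype=np.int64)


def _g(a: float, b: float) -> float:
    return max(0.0, 1.0 - abs(a - b))


def bilinear_sample(x: np.ndarray, p) -> float:
    """Bilinearly interpolate ``x`` at fractional position p = (row, col).

    The interpolation weight of integer position q is
    g(q_y, p_y) * g(q_x, p_x); positions outside the array contribute zero.
    """
    x = np.asarray(x)
    py, px = float(p[0]), float(p[1])
    if not (math.isfinite(py) and math.isfinite(px)):
        raise ValueError(f"non-finite sampling position {p!r}")
    h, w = x.shape
    y0, x0 = math.floor(py), math.floor(px)
    val = 0.0
    for qy in (y0, y0 + 1):
        for qx in (x0, x0 + 1):
            wgt = _g(qy, py) * _g(qx, px)
            if wgt > 0 and 0 <= qy < h and 0 <= qx < w:
                val += wgt * float(x[qy, qx])
    return val


def standard_conv2d(x: np.ndarray, w: np.ndarray, grid: np.ndarray | None = None
                    ) -> np.ndarray:
    """Same-size zero-padded convolution y(p0) = sum_n w(p_n) x(p0 + p_n)."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    k = int(round(math.sqrt(w.size)))
    if k * k != w.size:
        raise ValueError(f"weight size {w.size} is not a square kernel")
    if grid is None:
        grid = sampling_grid(k)
    if grid.shape[0] != w.size:
        raise ValueError(f"grid has {grid.shape[0]} elements, weights {w.size}")
    wf = w.ravel()
    h, wd = x.shape
    xp = np.pad(x, k // 2)
    y = np.zeros_like(x)
    for n, (dy, dx) in enumerate(grid):
        y += wf[n] * xp[k // 2 + dy : k // 2 + dy + h, k // 2 + dx : k // 2 + dx + wd]
    return y


def deform_conv2d(x: np.ndarray, w: np.ndarray, grid: np.ndarray,
                  offsets: np.ndarray) -> np.ndarray:
    """Deformable convolution with per-position fractional offsets.

    ``offsets`` has shape (H, W, N, 2) holding (dy, dx) for every output
    position and kernel element; sampling uses :func:`bilinear_sample`
    semantics, vectorized.
    """
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64).ravel()
    h, wd = x.shape
    n = grid.shape[0]
    offsets = np.asarray(offsets, dtype=np.float64)
    if offsets.shape != (h, wd, n, 2):
        raise ValueError(f"offset field shape {offsets.shape} != {(h, wd, n, 2)}")
    if not np.isfinite(offsets).all():
        raise ValueError("offset field contains non-finite values")
    oy = np.arange(h)[:, None, None] + grid[None, None, :, 0] + offsets[..., 0]
    ox = np.arange(wd)[None, :, None] + grid[None, None, :, 1] + offsets[..., 1]
    y0 = np.floor(oy).astype(np.int64)
    x0 = np.floor(ox).astype(np.int64)
    wy1, wx1 = oy - y0, ox - x0
    s = np.zeros((h, wd, n))
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        qy, qx = y0 + dy, x0 + dx
        inb = (qy >= 0) & (qy < h) & (qx >= 0) & (qx < wd)
        wgt = (wy1 if dy else 1 - wy1) * (wx1 if dx else 1 - wx1)
        s += np.where(inb, wgt * x[np.clip(qy, 0, h - 1), np.clip(qx, 0, wd - 1)], 0.0)
    # accumulate kernel elements in the same order as standard_conv2d so that
    # a zero offset field reproduces it bit-for-bit
    y = np.zeros((h, wd))
    for i in range(n):
        y += w[i] * s[:, :, i]
    return y


class OffsetPredictor:
    """Offset field from an auxiliary standard convolution with 2N channels.

    Weights and bias start at zero, so a freshly initialized predictor emits
    an all-zero offset field and the deformable convolution it feeds reduces
    exactly to a standard convolution.
    """

    def __init__(self, k: int = 3):
        self.k = k
        self.n = k * k
        self.weight = np.zeros((2 * self.n, k, k))  # (channel, ky, kx)
        self.bias = np.zeros(2 * self.n)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        h, w = x.shape
        out = np.empty((h, w, self.n, 2))
        grid = sampling_grid(self.k)
        for ch in range(2 * self.n):
            ychan = standard_conv2d(x, self.weight[ch], grid) + self.bias[ch]
            out[:, :, ch // 2, ch % 2] = ychan
        return out
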