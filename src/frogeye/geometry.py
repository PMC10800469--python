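"""Letterbox resizing between image space and model input space.

Letterboxing preserves aspect ratio: the image is scaled by the single
factor that fits it inside the model input and the remainder is zero-padded
(padding split evenly, extra pixel to the bottom/right). Masks travel
through the same geometry with nearest-neighbour resampling so they stay
binary; padded pixels are flagged so losses and metrics can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LetterboxMeta", "resize_nearest", "resize_bilinear", "letterbox_image",
           "letterbox_mask", "unletterbox_mask", "valid_region"]


@dataclass(frozen=True)
class LetterboxMeta:
    orig_size: tuple      # (H, W) of the source image
    scaled_size: tuple    # size after aspect-preserving resize
    pad: tuple            # (top, left)
    out_size: tuple       # model input (H, W)


def resize_nearest(arr: np.ndarray, size) -> np.ndarray:
    """Deterministic nearest-neighbour resize (floor index map)."""
    ridx = np.minimum((np.arange(size[0]) * arr.shape[0]) // size[0], arr.shape[0] - 1)
    cidx = np.minimum((np.arange(size[1]) * arr.shape[1]) // size[1], arr.shape[1] - 1)
    return arr[ridx][:, cidx]


def resize_bilinear(arr: np.ndarray, size) -> np.ndarray:
    """Bilinear resize of an HxW or HxWxC array (non-corner-aligned)."""
    from .nn.autograd import _bilinear_axis

    h, w = arr.shape[:2]
    r0, r1, wr0, wr1 = _bilinear_axis(h, size[0])
    c0, c1, wc0, wc1 = _bilinear_axis(w, size[1])
    a = arr.astype(np.float64)
    if a.ndim == 2:
        rows = a[r0] * wr0[:, None] + a[r1] * wr1[:, None]
        return rows[:, c0] * wc0 + rows[:, c1] * wc1
    rows = a[r0] * wr0[:, None, None] + a[r1] * wr1[:, None, None]
    return rows[:, c0] * wc0[:, None] + rows[:, c1] * wc1[:, None]


def _plan(orig_size, out_size) -> LetterboxMeta:
    h, w = orig_size
    oh, ow = out_size
    scale = min(oh / h, ow / w)
    sh, sw = max(1, round(h * scale)), max(1, round(w * scale))
    top, left = (oh - sh) // 2, (ow - sw) // 2
    return LetterboxMeta((h, w), (sh, sw), (top, left), (oh, ow))


def letterbox_image(image: np.ndarray, out_size) -> tuple[np.ndarray, LetterboxMeta]:
    """Aspect-preserving resize + zero pad to ``out_size``; bilinear resampling."""
    meta = _plan(image.shape[:2], out_size)
    resized = resize_bilinear(image, meta.scaled_size)
    out = np.zeros(meta.out_size + image.shape[2:], dtype=image.dtype)
    t, l = meta.pad
    out[t:t + meta.scaled_size[0], l:l + meta.scaled_size[1]] = np.clip(
        resized, 0, 255).astype(image.dtype)
    return out, meta


def letterbox_mask(mask: np.ndarray, out_size) -> tuple[np.ndarray, LetterboxMeta]:
    """Same geometry as :func:`letterbox_image` with nearest resampling."""
    meta = _plan(mask.shape[:2], out_size)
    resized = resize_nearest(mask, meta.scaled_size)
    out = np.zeros(meta.out_size, dtype=mask.dtype)
    t, l = meta.pad
    out[t:t + meta.scaled_size[0], l:l + meta.scaled_size[1]] = resized
    return out, meta


def unletterbox_mask(mask: np.ndarray, meta: LetterboxMeta) -> np.ndarray:
    """Crop the padding and nearest-resize a model-space mask back to the
    original resolution (masks stay binary)."""
    t, l = meta.pad
    sh, sw = meta.scaled_size
    return resize_nearest(mask[t:t + sh, l:l + sw], meta.orig_size)


def valid_region(meta: LetterboxMeta) -> np.ndarray:
    """Boolean model-space map of un-padded pixels (True = real content)."""
    out = np.zeros(meta.out_size, dtype=bool)
    t, l = meta.pad
    out[t:t + meta.scaled_size[0], l:l + meta.scaled_size[1]] = True
    return out
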