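"""Rendering helpers: error overlays, confusion heatmaps, sampling scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["error_overlay", "save_overlay", "confusion_heatmap",
           "sampling_points", "plot_sampling_points", "plot_loss_curve"]

FP_COLOR = (60, 90, 220)    # predicted but not true: blue
FN_COLOR = (235, 205, 40)   # true but not predicted: yellow


def error_overlay(image: np.ndarray, true_mask: np.ndarray,
                  pred_mask: np.ndarray) -> np.ndarray:
    """Color false positives blue and false negatives yellow on the image."""
    out = np.asarray(image, dtype=np.uint8).copy()
    t = np.asarray(true_mask) > 0
    p = np.asarray(pred_mask) > 0
    out[p & ~t] = FP_COLOR
    out[t & ~p] = FN_COLOR
    return out


def save_overlay(image, true_mask, pred_mask, path):
    from PIL import Image

    Image.fromarray(error_overlay(image, true_mask, pred_mask)).save(path)


def confusion_heatmap(confusion: np.ndarray, path, labels=None):
    c = np.asarray(confusion)
    labels = labels or [f"Level {i + 1}" for i in range(c.shape[0])]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(c, cmap="Blues")
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            ax.text(j, i, str(c[i, j]), ha="center", va="center",
                    color="black" if c[i, j] < c.max() / 2 else "white")
    ax.set_xticks(range(len(labels)), labels, rotation=45)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def sampling_points(offsets: np.ndarray, position, grid) -> np.ndarray:
    """Deformed sampling locations (N, 2) for one output position."""
    py, px = position
    return np.asarray(grid, float) + np.array([py, px]) + offsets[py, px]


def plot_sampling_points(offsets, positions, grid, path, extent=None):
    """Scatter the deformed sampling points of a few output positions."""
    fig, ax = plt.subplots(figsize=(4, 4))
    for pos in positions:
        pts = sampling_points(offsets, pos, grid)
        ax.scatter(pts[:, 1], pts[:, 0], s=14, alpha=0.8)
        ax.scatter([pos[1]], [pos[0]], marker="+", c="k")
    ax.invert_yaxis()
    ax.set_aspect("equal")
    if extent:
        ax.set_xlim(-0.5, extent[1] - 0.5)
        ax.set_ylim(extent[0] - 0.5, -0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_loss_curve(runlog_frame, path):
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(runlog_frame["loss"].to_numpy())
    ax.set_xlabel("step")
    ax.set_ylabel("training loss")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
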