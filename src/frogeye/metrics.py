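"""Pixel-level segmentation metrics.

Given a (k+1)x(k+1) pixel confusion matrix p, with p[i, j] the number of
pixels of true class i predicted as class j:

    per-class IoU_i = p_ii / (row_i + col_i - p_ii)       mIoU = mean_i IoU_i
    per-class PA_i  = p_ii / row_i                        mPA  = mean_i PA_i

mPA is algebraically the macro-averaged recall. Report pooling is "micro":
pixel counts are summed over the whole evaluation set before any ratio is
taken, so the report gives single dataset-level numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["BinaryCounts", "precision_recall", "confusion_matrix", "miou", "mpa",
           "per_class_iou", "per_class_pa", "segmentation_report"]


@dataclass(frozen=True)
class BinaryCounts:
    """TP/FP/FN/TN pixel counts for one target class."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


def precision_recall(c: BinaryCounts) -> tuple[float, float]:
    """(TP/(TP+FP), TP/(TP+FN)); an empty denominator yields NaN, never 0 or 1."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    return precision, recall


def confusion_matrix(true_labels: np.ndarray, pred_labels: np.ndarray,
                     num_classes: int) -> np.ndarray:
    """Pixel confusion matrix; entry [i, j] counts true i predicted j."""
    t = np.asarray(true_labels).ravel().astype(np.int64)
    p = np.asarray(pred_labels).ravel().astype(np.int64)
    if t.shape != p.shape:
        raise ValueError("true/pred size mismatch")
    if t.size and (t.min() < 0 or t.max() >= num_classes
                   or p.min() < 0 or p.max() >= num_classes):
        raise ValueError("labels outside [0, num_classes)")
    return np.bincount(t * num_classes + p, minlength=num_classes ** 2
                       ).reshape(num_classes, num_classes)


def _check(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.int64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    if m.sum() == 0:
        raise ValueError("confusion matrix is all zero")
    return m


def per_class_iou(m: np.ndarray) -> np.ndarray:
    m = _check(m)
    diag = np.diag(m).astype(float)
    denom = m.sum(axis=1) + m.sum(axis=0) - np.diag(m)
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, diag / denom, np.nan)


def per_class_pa(m: np.ndarray) -> np.ndarray:
    m = _check(m)
    row = m.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(row > 0, np.diag(m) / row, np.nan)


def _present_mean(values: np.ndarray, what: str) -> float:
    absent = np.isnan(values)
    if absent.any():
        logger.warning("%s: %d class(es) with no pixels excluded from the mean",
                       what, int(absent.sum()))
    return float(np.nanmean(values))


def miou(m: np.ndarray) -> float:
    """Mean IoU over classes; classes with no pixels at all are excluded."""
    return _present_mean(per_class_iou(m), "mIoU")


def mpa(m: np.ndarray) -> float:
    """Mean per-class pixel accuracy (macro recall); empty rows excluded."""
    return _present_mean(per_class_pa(m), "mPA")


def segmentation_report(true_masks, pred_masks, class_names=("background", "leaf"),
                        pooling: str = "micro"):
    """Per-class IoU/PA/precision/recall and their means.

    ``true_masks``/``pred_masks`` are aligned lists of integer label images
    with values indexing ``class_names``. With the default ``micro`` pooling,
    counts are summed over all images before any ratio is taken (single
    dataset-level numbers); ``macro`` averages the per-image ratios instead.
    Returns a dict; percentages rounded to 2 decimals by the CSV writer,
    not here.
    """
    if pooling not in ("micro", "macro"):
        raise ValueError(f"unknown pooling {pooling!r}")
    k = len(class_names)
    per_image = []
    total = np.zeros((k, k), dtype=np.int64)
    for i, (t, p) in enumerate(zip(true_masks, pred_masks)):
        t, p = np.asarray(t), np.asarray(p)
        if t.shape != p.shape:
            raise ValueError(f"record {i}: mask size mismatch {t.shape} vs {p.shape}")
        m = confusion_matrix(t, p, k)
        total += m
        per_image.append(m)
    if pooling == "macro":
        with np.errstate(invalid="ignore"):
            iou = np.nanmean([per_class_iou(m) for m in per_image], axis=0)
            pa = np.nanmean([per_class_pa(m) for m in per_image], axis=0)
            prec = np.nanmean([
                np.where(m.sum(axis=0) > 0, np.diag(m) / m.sum(axis=0), np.nan)
                for m in per_image], axis=0)
    else:
        iou = per_class_iou(total)
        pa = per_class_pa(total)
        col = total.sum(axis=0)
        with np.errstate(invalid="ignore"):
            prec = np.where(col > 0, np.diag(total) / col, np.nan)
    rec = pa  # per-class recall == per-class pixel accuracy
    return {
        "classes": list(class_names),
        "confusion": total,
        "iou_percent": (100 * iou).tolist(),
        "pa_percent": (100 * pa).tolist(),
        "precision_percent": (100 * prec).tolist(),
        "recall_percent": (100 * rec).tolist(),
        "miou_percent": 100 * _present_mean(iou, "mIoU"),
        "mpa_percent": 100 * _present_mean(pa, "mPA"),
        "mprecision_percent": 100 * _present_mean(prec, "mPrecision"),
        "mrecall_percent": 100 * _present_mean(rec, "mRecall"),
    }


def report_to_frame(report: dict):
    """Tabular (CSV-ready) view of a segmentation report, 2-decimal percents."""
    import pandas as pd

    rows = []
    for i, name in enumerate(report["classes"]):
        rows.append({
            "class": name,
            "IoU(%)": round(report["iou_percent"][i], 2),
            "PA(%)": round(report["pa_percent"][i], 2),
            "Precision(%)": round(report["precision_percent"][i], 2),
            "Recall(%)": round(report["recall_percent"][i], 2),
        })
    rows.append({
        "class": "mean",
        "IoU(%)": round(report["miou_percent"], 2),
        "PA(%)": round(report["mpa_percent"], 2),
        "Precision(%)": round(report["mprecision_percent"], 2),
        "Recall(%)": round(report["mrecall_percent"], 2),
    })
    return pd.DataFrame(rows)
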