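"""Lesion-to-leaf area ratio and five-level severity grading.

Severity of frog-eye leaf spot is graded from the fraction of the leaf's
area occupied by lesions,

    L = 100 * S_disease / S_leaf   (percent),

where both areas are pixel counts on masks at a common resolution and the
leaf area includes its diseased portion. The grade is a half-open interval
lookup (lower bound inclusive):

    level 1: 0.00 <= L < 0.95
    level 2: 0.95 <= L < 1.50
    level 3: 1.50 <= L < 2.15
    level 4: 2.15 <= L < 3.00
    level 5:         L >= 3.00

The grading report keeps the field's customary "precision" column name for
the per-true-level fraction graded correctly (a per-class recall in
classification terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = ["DEFAULT_THRESHOLDS", "NoLeafError", "AreaPair", "ratio", "grade",
           "grade_from_masks", "GradingReport", "grading_report"]

#: Level 1-4 upper bounds in percent; level 5 is unbounded above.
DEFAULT_THRESHOLDS = (0.95, 1.50, 2.15, 3.00)


class NoLeafError(ValueError):
    """Raised when the leaf area is zero and no ratio can be formed."""


@dataclass(frozen=True)
class AreaPair:
    """Leaf and lesion pixel counts for one image."""

    leaf: int
    disease: int

    def __post_init__(self):
        if self.leaf < 0 or self.disease < 0:
            raise ValueError("areas must be non-negative")
        if self.disease > self.leaf:
            raise ValueError(
                f"lesion area {self.disease} exceeds leaf area {self.leaf}"
            )


def ratio(areas: AreaPair) -> float:
    """Percent of the leaf area occupied by lesions (exact rational, then float)."""
    if areas.leaf == 0:
        raise NoLeafError("leaf area is zero; image is ungradable")
    return float(Fraction(100 * areas.disease, areas.leaf))


def grade(L: float, thresholds=DEFAULT_THRESHOLDS) -> int:
    """Severity level 1..5 for a ratio L in percent."""
    if not np.isfinite(L) or L < 0:
        raise ValueError(f"ratio must be finite and non-negative, got {L!r}")
    t = tuple(thresholds)
    if len(t) != 4 or any(a >= b for a, b in zip(t, t[1:])):
        raise ValueError(f"thresholds must be 4 strictly increasing values, got {t}")
    for level, bound in enumerate(t, start=1):
        if L < bound:
            return level
    return 5


def grade_from_masks(leaf_mask: np.ndarray, lesion_mask: np.ndarray,
                     thresholds=DEFAULT_THRESHOLDS) -> tuple[float, int]:
    """Ratio and level from binary masks (lesion counted inside the leaf)."""
    leaf = int(np.count_nonzero(leaf_mask))
    lesion = int(np.count_nonzero(np.logical_and(lesion_mask, leaf_mask)))
    L = ratio(AreaPair(leaf, lesion))
    return L, grade(L, thresholds)


@dataclass
class GradingReport:
    """Per-level and macro grading accuracy plus the 5x5 level confusion."""

    n_images: list[int]
    n_correct: list[int]
    precision_percent: list[float]
    macro_precision_percent: float
    macro_precision_levels_1_3_percent: float
    confusion: np.ndarray = field(repr=False)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "Disease Classification": f"Level {i + 1}",
                "Number of dataset": self.n_images[i],
                "Correct Grading": self.n_correct[i],
                "Precision(%)": round(self.precision_percent[i], 2),
            }
            for i in range(5)
        ]
        rows.append({
            "Disease Classification": "Total",
            "Number of dataset": sum(self.n_images),
            "Correct Grading": sum(self.n_correct),
            "Precision(%)": round(self.macro_precision_percent, 2),
        })
        return pd.DataFrame(rows)


def grading_report(true_levels, pred_levels) -> GradingReport:
    """Grade-vs-truth report over a set of images.

    Per-level precision is 100 * correct / total within each true level; the
    macro precisions are unweighted means of the per-level column (all five
    levels, and levels 1-3), not the pooled micro accuracy.
    """
    true_levels = [int(v) for v in true_levels]
    pred_levels = [int(v) for v in pred_levels]
    if not true_levels:
        raise ValueError("empty grading input")
    if len(true_levels) != len(pred_levels):
        raise ValueError("true/pred length mismatch")
    for v in true_levels + pred_levels:
        if not 1 <= v <= 5:
            raise ValueError(f"severity level {v} outside 1..5")
    confusion = np.zeros((5, 5), dtype=np.int64)
    for t, p in zip(true_levels, pred_levels):
        confusion[t - 1, p - 1] += 1
    n_images = confusion.sum(axis=1).tolist()
    n_correct = np.diag(confusion).tolist()
    per_level = [
        100.0 * c / n if n else float("nan")
        for c, n in zip(n_correct, n_images)
    ]
    present = [p for p in per_level if not np.isnan(p)]
    present13 = [p for p in per_level[:3] if not np.isnan(p)]
    return GradingReport(
        n_images=n_images,
        n_correct=n_correct,
        precision_percent=per_level,
        macro_precision_percent=float(np.mean(present)),
        macro_precision_levels_1_3_percent=(
            float(np.mean(present13)) if present13 else float("nan")
        ),
        confusion=confusion,
    )
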