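"""Annotation, mask and manifest I/O.

Conventions fixed here and relied on by the tests:

- Pixel coordinates are 0-based, x right / y down, and a pixel is identified
  with its integer center: a pixel belongs to a polygon iff its center lies
  inside or exactly on the polygon boundary. Overlapping polygons union.
- Binary masks hold labels {0, 1} in memory and are written to 8-bit
  single-channel PNG as {0, 255} for viewability; reading maps 255 back to 1
  and rejects any other value.
- Manifests are CSV with columns image, leaf_mask, lesion_mask,
  ratio_percent, level, split (extra columns pass through).

The LabelMe dialect read here is the minimal subset: imageHeight,
imageWidth, shapes[{label, points}]; other keys are ignored.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = ["PolygonAnnotation", "AnnotationDoc", "polygons_to_mask",
           "write_mask_png", "read_mask_png", "write_image_png", "read_image_png",
           "read_manifest", "write_manifest", "split_manifest"]

MANIFEST_COLUMNS = ["image", "leaf_mask", "lesion_mask", "ratio_percent", "level",
                    "split"]


@dataclass(frozen=True)
class PolygonAnnotation:
    """One labeled polygon: a label string and >= 3 (x, y) vertices."""

    label: str
    points: tuple

    def __post_init__(self):
        if len(self.points) < 3:
            raise ValueError(
                f"degenerate polygon for label {self.label!r}: "
                f"{len(self.points)} point(s), need >= 3"
            )


@dataclass
class AnnotationDoc:
    """An image's polygon annotations (LabelMe-style JSON document)."""

    image_size: tuple  # (H, W)
    polygons: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "imageHeight": int(self.image_size[0]),
            "imageWidth": int(self.image_size[1]),
            "shapes": [
                {"label": p.label,
                 "points": [[float(x), float(y)] for x, y in p.points]}
                for p in self.polygons
            ],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AnnotationDoc":
        d = json.loads(text)
        return cls(
            image_size=(int(d["imageHeight"]), int(d["imageWidth"])),
            polygons=[
                PolygonAnnotation(s["label"],
                                  tuple((float(x), float(y)) for x, y in s["points"]))
                for s in d.get("shapes", [])
            ],
        )

    def save(self, path):
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "AnnotationDoc":
        return cls.from_json(Path(path).read_text())


def polygons_to_mask(doc: AnnotationDoc, label: str) -> np.ndarray:
    """Rasterize all polygons with ``label`` to a {0,1} mask (union).

    A pixel is set iff its center (integer coordinates) is inside or on the
    boundary of any matching polygon. An unknown label yields an all-zero
    mask with a warning, not a silent failure.
    """
    h, w = doc.image_size
    mask = np.zeros((h, w), dtype=np.uint8)
    polys = [p for p in doc.polygons if p.label == label]
    if not polys and any(doc.polygons):
        known = sorted({p.label for p in doc.polygons})
        warnings.warn(
            f"label {label!r} not present in document (labels: {known}); "
            "returning empty mask"
        )
        return mask
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    for p in polys:
        geom = Polygon(p.points)
        if not geom.is_valid:
            geom = geom.buffer(0)
        # intersects == inside-or-on-boundary for point queries
        hit = shapely.intersects_xy(geom, xs.ravel(), ys.ravel()).reshape(h, w)
        mask |= hit.astype(np.uint8)
    return mask


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a {0,1} mask as an 8-bit PNG with values {0, 255}."""
    mask = np.asarray(mask)
    bad = np.setdiff1d(np.unique(mask), [0, 1])
    if bad.size:
        raise ValueError(f"mask contains non-binary value(s) {bad.tolist()}")
    Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(path)


def read_mask_png(path) -> np.ndarray:
    """Read a mask PNG written by :func:`write_mask_png`; exact back-mapping."""
    arr = np.asarray(Image.open(path).convert("L"))
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise ValueError(
            f"{path}: mask PNG contains value(s) {bad.tolist()}, expected only 0/255"
        )
    return (arr == 255).astype(np.uint8)


def write_image_png(image: np.ndarray, path) -> None:
    """Write an HxWx3 uint8 RGB image."""
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_image_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "split"]
    if missing:
        raise ValueError(f"manifest {path} missing column(s) {missing}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _round_half_down(x: float) -> int:
    return int(np.ceil(x - 0.5))


def split_manifest(manifest: pd.DataFrame, ratios=(8, 1, 1), seed: int = 0
                   ) -> pd.DataFrame:
    """Stratified train/val/test split at the given ratios (default 8:1:1).

    Within each severity level, validation and test each receive round(n/10)
    items — at an exact .5 tie, test rounds up and validation down — and
    training takes the remainder. Assignment is a seeded permutation, so the
    same seed always reproduces the same split. Levels with fewer than 3
    items go entirely to train, with a warning.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    total = sum(ratios)
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = "train"
    for level, idx in out.groupby("level").groups.items():
        idx = np.asarray(idx)
        n = len(idx)
        if n < 3:
            if n:
                warnings.warn(f"level {level}: only {n} item(s); all go to train")
            continue
        n_test = _round_half_up(n * ratios[2] / total)
        n_val = _round_half_down(n * ratios[1] / total)
        perm = rng.permutation(n)
        out.loc[idx[perm[:n_test]], "split"] = "test"
        out.loc[idx[perm[n_test:n_test + n_val]], "split"] = "val"
    return out
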