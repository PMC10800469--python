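"""Mask-preserving mosaic augmentation.

A mosaic collages random crops of four annotated images into a 2x2 layout
around a jittered junction point, applying the identical geometric transform
to the image and both masks, so annotations stay valid by construction. The
default training policy appends exactly one collage per original: the
original anchors quadrant 0 and the other three quadrants are drawn
uniformly with replacement from the remaining training images, doubling the
training set.

Every collage records per-quadrant provenance (source id, nearest-neighbour
scale size, crop window); :func:`reconstruct` rebuilds the collage from it
bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset_io
from .severity import NoLeafError, grade_from_masks

logger = logging.getLogger(__name__)

__all__ = ["MosaicConfig", "CollageResult", "mosaic4", "reconstruct",
           "augment_training_set"]


@dataclass(frozen=True)
class MosaicConfig:
    output_size: tuple = (128, 128)   # (H, W)
    center_jitter: float = 0.2        # junction sampled within +-jitter * size
    seed: int = 0

    def __post_init__(self):
        h, w = self.output_size
        if h < 64 or w < 64:
            raise ValueError("mosaic output must be at least 64x64")
        if not 0.0 <= self.center_jitter <= 0.4:
            raise ValueError("center_jitter must be in [0, 0.4]")


@dataclass
class CollageResult:
    image: np.ndarray
    leaf_mask: np.ndarray
    lesion_mask: np.ndarray
    provenance: list = field(default_factory=list)  # per-quadrant dicts


def _nearest_size_map(n_out: int, n_in: int) -> np.ndarray:
    """Deterministic nearest-neighbour index map for resizing n_in -> n_out."""
    return np.minimum((np.arange(n_out) * n_in) // n_out, n_in - 1)


def _nearest_resize(arr: np.ndarray, size) -> np.ndarray:
    ridx = _nearest_size_map(size[0], arr.shape[0])
    cidx = _nearest_size_map(size[1], arr.shape[1])
    return arr[np.ix_(ridx, cidx)]


def _quadrant_boxes(out_hw, junction):
    oh, ow = out_hw
    cy, cx = junction
    return [  # (y0, x0, h, w) in collage coordinates, quadrants row-major
        (0, 0, cy, cx),
        (0, cx, cy, ow - cx),
        (cy, 0, oh - cy, cx),
        (cy, cx, oh - cy, ow - cx),
    ]


def _fields(sample):
    if isinstance(sample, dict):
        return sample["image"], sample["leaf_mask"], sample["lesion_mask"]
    return sample.image, sample.leaf_mask, sample.lesion_mask


def mosaic4(samples, config: MosaicConfig) -> CollageResult:
    """Collage four samples (image + leaf/lesion masks) into a 2x2 mosaic.

    Sources smaller than their quadrant are nearest-neighbour scaled up
    first (logged); masks undergo the identical transform as the image.
    """
    if len(samples) != 4:
        raise ValueError("mosaic4 needs exactly four samples")
    rng = np.random.default_rng(config.seed)
    oh, ow = config.output_size
    jy = int(round(rng.uniform(-config.center_jitter, config.center_jitter) * oh))
    jx = int(round(rng.uniform(-config.center_jitter, config.center_jitter) * ow))
    junction = (min(max(oh // 2 + jy, 1), oh - 1), min(max(ow // 2 + jx, 1), ow - 1))

    image = np.zeros((oh, ow, 3), dtype=np.uint8)
    leaf = np.zeros((oh, ow), dtype=np.uint8)
    lesion = np.zeros((oh, ow), dtype=np.uint8)
    provenance = []
    for q, (box, sample) in enumerate(zip(_quadrant_boxes((oh, ow), junction),
                                          samples)):
        y0, x0, qh, qw = box
        img, lm, dm = _fields(sample)
        if img.shape[:2] != lm.shape or lm.shape != dm.shape:
            raise ValueError(f"quadrant {q}: image/mask sizes not aligned")
        sh, sw = img.shape[:2]
        if sh < qh or sw < qw:
            scale = max(qh / sh, qw / sw)
            sh, sw = int(np.ceil(sh * scale)), int(np.ceil(sw * scale))
            logger.info("mosaic quadrant %d: source %s scaled to %s for crop %s",
                        q, img.shape[:2], (sh, sw), (qh, qw))
            img = _nearest_resize(img, (sh, sw))
            lm = _nearest_resize(lm, (sh, sw))
            dm = _nearest_resize(dm, (sh, sw))
        cy0 = int(rng.integers(0, sh - qh + 1))
        cx0 = int(rng.integers(0, sw - qw + 1))
        image[y0:y0 + qh, x0:x0 + qw] = img[cy0:cy0 + qh, cx0:cx0 + qw]
        leaf[y0:y0 + qh, x0:x0 + qw] = lm[cy0:cy0 + qh, cx0:cx0 + qw]
        lesion[y0:y0 + qh, x0:x0 + qw] = dm[cy0:cy0 + qh, cx0:cx0 + qw]
        provenance.append({
            "source": q, "scaled_size": (sh, sw),
            "window": (cy0, cx0, qh, qw), "quadrant": (y0, x0, qh, qw),
        })
    return CollageResult(image, leaf, lesion, provenance)


def reconstruct(samples, provenance, output_size) -> CollageResult:
    """Rebuild a collage from its provenance records, bit-exactly."""
    oh, ow = output_size
    image = np.zeros((oh, ow, 3), dtype=np.uint8)
    leaf = np.zeros((oh, ow), dtype=np.uint8)
    lesion = np.zeros((oh, ow), dtype=np.uint8)
    for rec in provenance:
        img, lm, dm = _fields(samples[rec["source"]])
        sh, sw = rec["scaled_size"]
        if img.shape[:2] != (sh, sw):
            img = _nearest_resize(img, (sh, sw))
            lm = _nearest_resize(lm, (sh, sw))
            dm = _nearest_resize(dm, (sh, sw))
        cy0, cx0, qh, qw = rec["window"]
        y0, x0, _, _ = rec["quadrant"]
        image[y0:y0 + qh, x0:x0 + qw] = img[cy0:cy0 + qh, cx0:cx0 + qw]
        leaf[y0:y0 + qh, x0:x0 + qw] = lm[cy0:cy0 + qh, cx0:cx0 + qw]
        lesion[y0:y0 + qh, x0:x0 + qw] = dm[cy0:cy0 + qh, cx0:cx0 + qw]
    return CollageResult(image, leaf, lesion, list(provenance))


def augment_training_set(manifest: pd.DataFrame, config: MosaicConfig | None = None,
                         out_dir=None) -> pd.DataFrame:
    """Append one mosaic collage per training original (default policy).

    Each collage anchors its original in quadrant 0, draws the other three
    quadrants uniformly with replacement from the remaining training images,
    and uses an output size of twice the anchor's size unless the config
    fixes one. The manifest ``level`` column of a collage is regraded from
    its own masks; ``anchor_level`` keeps the anchor attribution used for
    per-level accounting. Returns originals + collages (2x the rows).
    """
    if "split" in manifest.columns:
        train = manifest[manifest["split"] == "train"].reset_index(drop=True)
    else:
        train = manifest.reset_index(drop=True)
    n = len(train)
    if n < 4:
        raise ValueError(f"need at least 4 training images to mosaic, got {n}")
    if out_dir is None:
        raise ValueError("out_dir is required: collages are written to disk")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if config is not None else 0
    ss = np.random.SeedSequence(seed)
    pick_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]

    cache: dict[int, tuple] = {}

    def load(i):
        if i not in cache:
            row = train.iloc[i]
            cache[i] = (
                dataset_io.read_image_png(row["image"]),
                dataset_io.read_mask_png(row["leaf_mask"]),
                dataset_io.read_mask_png(row["lesion_mask"]),
            )
        return dict(zip(("image", "leaf_mask", "lesion_mask"), cache[i]))

    rows = []
    for i in range(n):
        anchor = load(i)
        others = [int(j) for j in pick_rng.choice(
            [j for j in range(n) if j != i], size=3, replace=True)]
        h, w = anchor["image"].shape[:2]
        if config is not None and config.output_size != (2 * h, 2 * w):
            out_size = config.output_size
        else:
            out_size = (2 * h, 2 * w)
        cfg = MosaicConfig(output_size=out_size,
                           center_jitter=config.center_jitter if config else 0.2,
                           seed=child_seeds[i])
        collage = mosaic4([anchor] + [load(j) for j in others], cfg)
        stem = f"mosaic_{i:05d}"
        img_p, leaf_p, les_p = (out_dir / f"{stem}{sfx}.png"
                                for sfx in ("", "_leaf", "_disease"))
        dataset_io.write_image_png(collage.image, img_p)
        dataset_io.write_mask_png(collage.leaf_mask, leaf_p)
        dataset_io.write_mask_png(collage.lesion_mask, les_p)
        anchor_level = int(train.iloc[i]["level"])
        try:
            ratio, level = grade_from_masks(collage.leaf_mask, collage.lesion_mask)
        except NoLeafError:
            logger.warning("collage %s contains no leaf pixels; keeping anchor level",
                           stem)
            ratio, level = float("nan"), anchor_level
        rows.append({
            "image": str(img_p), "leaf_mask": str(leaf_p), "lesion_mask": str(les_p),
            "ratio_percent": ratio, "level": level, "split": "train",
            "anchor_level": anchor_level,
        })
    collages = pd.DataFrame(rows)
    out = pd.concat([train.assign(anchor_level=train["level"]), collages],
                    ignore_index=True)
    dataset_io.write_manifest(out, out_dir / "train_augmented.csv")
    return out
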