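"""Synthetic orchard scenes with known leaf/lesion masks.

Each scene is a single apple leaf — a rotated ellipse with sinusoidal
boundary jitter, optionally partly occluded by a foreground blob — on a
cluttered background (grass, trunk, shadow, healthy leaves, fruit or an
occluding branch). Round "frog-eye" spots (tan center, darker ring) are
placed fully inside the visible leaf by rejection sampling until the
lesion-to-leaf pixel ratio reaches a requested target, so severity grading
can be tested against exact ground truth without any external imagery.

One integer seed drives a hierarchical generator (scene -> leaf -> lesion);
identical specs and seed reproduce byte-identical samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from . import dataset_io
from .severity import DEFAULT_THRESHOLDS, grade

__all__ = ["BACKGROUND_KINDS", "SceneSpec", "LeafSpec", "LesionSpec",
           "SyntheticSample", "generate_scene", "generate_dataset",
           "specs_for_level"]

BACKGROUND_KINDS = ("grass", "trunk", "shadow", "healthy_leaves", "fruit",
                    "occlusion")


@dataclass(frozen=True)
class SceneSpec:
    canvas_size: tuple = (64, 64)  # (H, W)
    background_kind: str = "grass"
    seed: int = 0

    def __post_init__(self):
        h, w = self.canvas_size
        if h < 32 or w < 32:
            raise ValueError("canvas must be at least 32x32")
        if self.background_kind not in BACKGROUND_KINDS:
            raise ValueError(f"unknown background kind {self.background_kind!r}")


@dataclass(frozen=True)
class LeafSpec:
    center: tuple | None = None          # defaults to canvas center
    axes: tuple | None = None            # (semi-major, semi-minor) px
    rotation: float = 25.0               # degrees
    boundary_jitter: float = 0.08        # fraction of axis length
    occlusion_fraction: float = 0.0      # of leaf area hidden by a foreground blob

    def __post_init__(self):
        if not 0.0 <= self.occlusion_fraction <= 0.4:
            raise ValueError("occlusion_fraction must be in [0, 0.4]")
        if not 0.0 <= self.boundary_jitter < 0.5:
            raise ValueError("boundary_jitter must be in [0, 0.5)")


@dataclass(frozen=True)
class LesionSpec:
    target_ratio_percent: float = 2.0
    spot_radius_range: tuple = (2, 4)    # px, inclusive
    ring_contrast: float = 0.5           # 0 = no ring, 1 = black ring

    def __post_init__(self):
        if not 0.0 <= self.target_ratio_percent <= 20.0:
            raise ValueError("target_ratio_percent must be in [0, 20]")
        lo, hi = self.spot_radius_range
        if lo < 1 or hi < lo:
            raise ValueError("spot_radius_range must satisfy 1 <= lo <= hi")


@dataclass
class SyntheticSample:
    image: np.ndarray                    # HxWx3 uint8
    leaf_mask: np.ndarray                # HxW {0,1}
    lesion_mask: np.ndarray              # HxW {0,1}, subset of leaf_mask
    true_ratio_percent: float
    true_level: int
    spec: tuple = field(default=None, repr=False)


def _texture(rng, shape, base, amplitude, smooth=3):
    """Low-frequency RGB noise texture around a base color."""
    noise = rng.standard_normal((shape[0], shape[1], 3))
    k = np.ones(smooth) / smooth
    for ax in (0, 1):
        noise = np.apply_along_axis(lambda v: np.convolve(v, k, mode="same"), ax, noise)
    img = np.asarray(base, float) + amplitude * noise
    return np.clip(img, 0, 255)


def _paint_background(rng, kind, shape):
    h, w = shape
    if kind == "grass":
        return _texture(rng, shape, (60, 110, 45), 45)
    if kind == "trunk":
        img = _texture(rng, shape, (95, 70, 45), 25)
        stripes = 12 * np.sin(np.arange(w) / 2.5 + rng.uniform(0, 6))
        return np.clip(img + stripes[None, :, None], 0, 255)
    if kind == "shadow":
        img = _texture(rng, shape, (55, 75, 45), 30)
        yy, xx = np.mgrid[0:h, 0:w]
        dark = 0.45 + 0.55 * ((xx + yy) > (h + w) / 2)
        return np.clip(img * dark[..., None], 0, 255)
    if kind == "healthy_leaves":
        img = _texture(rng, shape, (70, 125, 60), 35)
        for _ in range(4):
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            r = rng.integers(min(h, w) // 6, min(h, w) // 3)
            yy, xx = np.mgrid[0:h, 0:w]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            img[blob] = np.clip(img[blob] + rng.uniform(-25, 25, 3), 0, 255)
        return img
    if kind == "fruit":
        img = _texture(rng, shape, (60, 110, 45), 40)
        for _ in range(2):
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            r = rng.integers(min(h, w) // 8, min(h, w) // 5)
            yy, xx = np.mgrid[0:h, 0:w]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            img[blob] = (185, 60, 50)
        return img
    # "occlusion": grass plus a dark diagonal branch in front of the scene
    img = _texture(rng, shape, (60, 110, 45), 45)
    yy, xx = np.mgrid[0:h, 0:w]
    c = rng.uniform(-0.2, 0.2)
    band = np.abs((yy - h / 2) - (xx - w / 2) * (0.6 + c)) < max(2, h // 16)
    img[band] = (70, 55, 40)
    return img


def _leaf_mask(rng, shape, leaf: LeafSpec):
    h, w = shape
    cy, cx = leaf.center if leaf.center is not None else (h / 2, w / 2)
    if leaf.axes is not None:
        a, b = leaf.axes
    else:
        a, b = 0.42 * min(h, w), 0.27 * min(h, w)
    th = math.radians(leaf.rotation)
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
    v = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    ang = np.arctan2(v / b, u / a)
    lobes = rng.integers(4, 8)
    phase = rng.uniform(0, 2 * np.pi)
    limit = 1.0 + leaf.boundary_jitter * np.sin(lobes * ang + phase)
    mask = (rho <= limit).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError("leaf specification yields an empty mask")
    return mask, (cy, cx, a, b, th)


def _occlude(rng, mask, fraction, image):
    """Hide ``fraction`` of the leaf behind a foreground blob; returns new mask."""
    if fraction <= 0:
        return mask
    h, w = mask.shape
    edge = np.argwhere(mask.astype(bool) ^ (np.roll(mask, 1, 0) & mask).astype(bool))
    cy, cx = edge[rng.integers(len(edge))] if len(edge) else (h // 2, w // 2)
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    leaf_area = mask.sum()
    lo, hi = 1.0, float(max(h, w))
    for _ in range(25):
        r = 0.5 * (lo + hi)
        cover = (mask & (d2 <= r * r)).sum() / leaf_area
        if cover < fraction:
            lo = r
        else:
            hi = r
    blob = d2 <= hi * hi
    image[blob] = (75, 60, 42)
    out = mask.copy()
    out[blob] = 0
    if out.sum() == 0:
        raise ValueError("occlusion removed the entire leaf")
    return out


def _place_spots(rng, leaf_mask, lesion: LesionSpec, image):
    """Greedy spot placement until the area ratio is within tolerance."""
    h, w = leaf_mask.shape
    lesion_mask = np.zeros_like(leaf_mask)
    leaf_area = int(leaf_mask.sum())
    target_px = lesion.target_ratio_percent / 100.0 * leaf_area
    if target_px == 0:
        return lesion_mask
    rmin, rmax = lesion.spot_radius_range
    min_spot_area = np.pi * rmin ** 2
    tol_px = max(0.10 * target_px, min_spot_area)
    inside = np.argwhere(leaf_mask > 0)
    yy, xx = np.mgrid[0:h, 0:w]
    failures = 0
    while True:
        achieved = int(lesion_mask.sum())
        remaining = target_px - achieved
        # stop once within tolerance, or when even the smallest spot would
        # overshoot by more than it helps
        if (abs(remaining) <= tol_px and achieved > 0) or \
                remaining <= min_spot_area / 2:
            break
        # undershoot by flooring the radius; small remainders fill with
        # minimum-size spots so quantization stays one small spot's area
        r = int(np.clip(math.floor(math.sqrt(remaining / np.pi)), rmin, rmax))
        cy, cx = inside[rng.integers(len(inside))]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        spot = d2 <= r * r
        if (spot & (leaf_mask == 0)).any():
            failures += 1
            if failures > 500:
                raise ValueError(
                    "requested lesion ratio unattainable: no room for a spot of "
                    f"radius {r} inside the leaf"
                )
            continue
        lesion_mask |= spot.astype(np.uint8)
        ring = (d2 <= r * r) & (d2 >= (0.55 * r) ** 2)
        center = d2 < (0.55 * r) ** 2
        image[center] = (150, 120, 80)
        dark = np.clip(110 * (1 - lesion.ring_contrast), 0, 255)
        image[ring] = (dark, dark * 0.75, dark * 0.45)
    return lesion_mask


def generate_scene(scene: SceneSpec, leaf: LeafSpec | None = None,
                   lesion: LesionSpec | None = None,
                   thresholds=DEFAULT_THRESHOLDS) -> SyntheticSample:
    """Render one scene; achieved lesion ratio lands within +-10% relative of
    the target (or one spot's area, whichever is larger)."""
    leaf = leaf if leaf is not None else LeafSpec()
    lesion = lesion if lesion is not None else LesionSpec()
    ss = np.random.SeedSequence(scene.seed)
    rng_scene, rng_leaf, rng_lesion = (np.random.default_rng(s) for s in ss.spawn(3))
    h, w = scene.canvas_size

    image = _paint_background(rng_scene, scene.background_kind, (h, w))
    leaf_mask, _ = _leaf_mask(rng_leaf, (h, w), leaf)
    veins = 12 * np.sin(np.mgrid[0:h, 0:w][0] / 3.0)
    leaf_color = np.clip(
        np.asarray((65, 140, 55), float)
        + 18 * rng_leaf.standard_normal((h, w, 3))
        + veins[..., None] * 0.4,
        0, 255,
    )
    image = np.where(leaf_mask[..., None] > 0, leaf_color, image)
    leaf_mask = _occlude(rng_leaf, leaf_mask, leaf.occlusion_fraction, image)
    lesion_mask = _place_spots(rng_lesion, leaf_mask, lesion, image)

    leaf_area = int(leaf_mask.sum())
    ratio = 100.0 * int(lesion_mask.sum()) / leaf_area
    return SyntheticSample(
        image=np.clip(image, 0, 255).astype(np.uint8),
        leaf_mask=leaf_mask.astype(np.uint8),
        lesion_mask=lesion_mask.astype(np.uint8),
        true_ratio_percent=ratio,
        true_level=grade(ratio, thresholds),
        spec=(scene, leaf, lesion),
    )


#: Per-level target-ratio sampling windows (percent), kept away from the
#: grading thresholds so the achieved ratio stays inside the level.
_LEVEL_WINDOWS = {1: (0.15, 0.80), 2: (1.05, 1.40), 3: (1.60, 2.05),
                  4: (2.25, 2.90), 5: (3.30, 6.00)}


def specs_for_level(level: int, rng, canvas_size=(64, 64), background=None
                    ) -> tuple:
    """Draw (SceneSpec, LeafSpec, LesionSpec) whose target ratio sits inside
    the given severity level, away from its boundaries."""
    lo, hi = _LEVEL_WINDOWS[level]
    kind = background or BACKGROUND_KINDS[int(rng.integers(len(BACKGROUND_KINDS)))]
    scene = SceneSpec(canvas_size=canvas_size, background_kind=kind,
                      seed=int(rng.integers(2 ** 31)))
    leaf = LeafSpec(rotation=float(rng.uniform(0, 180)),
                    boundary_jitter=float(rng.uniform(0.02, 0.12)),
                    occlusion_fraction=float(rng.uniform(0, 0.15)))
    lesion = LesionSpec(target_ratio_percent=float(rng.uniform(lo, hi)),
                        spot_radius_range=(1, 3))
    return scene, leaf, lesion


def _mask_polygons(mask: np.ndarray, label: str):
    polys = []
    for contour in measure.find_contours(mask.astype(float), 0.5):
        if len(contour) < 3:
            continue
        pts = tuple((float(x), float(y)) for y, x in contour[::3])
        if len(pts) >= 3:
            polys.append(dataset_io.PolygonAnnotation(label, pts))
    return polys


def generate_dataset(n_per_level, out_dir, seed: int = 0, canvas_size=(64, 64),
                     thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Generate samples per level and write images, masks, annotations and a
    manifest under ``out_dir``. Returns the manifest DataFrame.

    ``n_per_level`` gives counts for levels 1..5. Each emitted sample's level
    is re-derived from its own masks, so the manifest level column always
    matches a regrade of the stored files.
    """
    counts = list(n_per_level)
    if len(counts) != 5 or any(c < 0 for c in counts):
        raise ValueError("n_per_level must be 5 non-negative counts")
    out_dir = Path(out_dir)
    if sum(counts):
        out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for level, n in zip(range(1, 6), counts):
        for _ in range(n):
            for _attempt in range(40):
                scene, leaf, lesion = specs_for_level(level, rng, canvas_size)
                sample = generate_scene(scene, leaf, lesion, thresholds)
                if sample.true_level == level:
                    break
            else:
                raise RuntimeError(f"could not hit level {level} in 40 attempts")
            stem = f"sample_{idx:05d}_L{level}"
            img_p = out_dir / f"{stem}.png"
            leaf_p = out_dir / f"{stem}_leaf.png"
            les_p = out_dir / f"{stem}_disease.png"
            ann_p = out_dir / f"{stem}.json"
            dataset_io.write_image_png(sample.image, img_p)
            dataset_io.write_mask_png(sample.leaf_mask, leaf_p)
            dataset_io.write_mask_png(sample.lesion_mask, les_p)
            doc = dataset_io.AnnotationDoc(
                image_size=canvas_size,
                polygons=_mask_polygons(sample.leaf_mask, "leaf")
                + _mask_polygons(sample.lesion_mask, "disease"),
            )
            doc.save(ann_p)
            rows.append({
                "image": str(img_p), "leaf_mask": str(leaf_p),
                "lesion_mask": str(les_p),
                "ratio_percent": sample.true_ratio_percent,
                "level": level, "split": "train",
            })
            idx += 1
    manifest = pd.DataFrame(rows, columns=dataset_io.MANIFEST_COLUMNS)
    if sum(counts):
        dataset_io.write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
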