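"""Training, two-stage inference and evaluation.

The inference path mirrors the deployment pipeline: the image is
letterboxed to the stage-1 input size, the predicted leaf mask is mapped
back to the original resolution (nearest-neighbour, so it stays binary),
background pixels are zeroed, the masked image is letterboxed to the
stage-2 input size, and the predicted lesion mask is mapped back and
intersected with the leaf mask. Areas are counted at the original image
resolution, so the severity ratio is taken where the annotation lives. An
image whose predicted leaf mask is empty is surfaced as ungradable, never
silently graded level 1.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset_io, metrics, severity
from .dunet import DUNet, DUNetConfig
from .geometry import letterbox_image, letterbox_mask, unletterbox_mask, valid_region
from .ldpnet import LDPNet, LDPNetConfig
from .nn import Adam, Tensor, exp_decay, focal_softmax_loss, step_decay

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "InferenceConfig", "RunLog", "UngradableImageError",
           "ModelPredictor", "GroundTruthPredictor", "train", "train_two_stage",
           "infer_two_stage", "evaluate", "build_model"]


@dataclass(frozen=True)
class TrainConfig:
    """Per-stage training hyperparameters.

    Defaults are the published modeling parameters for each stage: 200
    epochs, base learning rate 1e-4, two classes, batch 16 with decay factor
    0.1 for the leaf stage and batch 4 with decay factor 0.96 for the lesion
    stage. The leaf stage applies the factor as step decay at 60%/90% of the
    epochs; the lesion stage applies it per-epoch (exponential).
    """

    stage: str = "leaf"                  # "leaf" | "lesion"
    input_size: tuple | None = None      # None -> stage default
    epochs: int = 200
    base_lr: float = 0.0001
    batch_size: int | None = None        # None -> stage default
    lr_decay_gamma: float | None = None  # None -> stage default
    num_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.stage not in ("leaf", "lesion"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.epochs <= 0 or self.base_lr <= 0:
            raise ValueError("epochs and base_lr must be positive")

    def resolved(self) -> "TrainConfig":
        d = asdict(self)
        if d["input_size"] is None:
            d["input_size"] = (473, 473) if self.stage == "leaf" else (512, 512)
        if d["batch_size"] is None:
            d["batch_size"] = 16 if self.stage == "leaf" else 4
        if d["lr_decay_gamma"] is None:
            d["lr_decay_gamma"] = 0.1 if self.stage == "leaf" else 0.96
        return TrainConfig(**d)

    def to_dict(self) -> dict:
        """Plain key-value snapshot using the published parameter names."""
        r = self.resolved()
        return {
            "Input size": f"{r.input_size[0]}x{r.input_size[1]}",
            "Training number of epochs": r.epochs,
            "Base learning rate": r.base_lr,
            "Image input batch size": r.batch_size,
            "Gamma": r.lr_decay_gamma,
            "Number of classes": r.num_classes,
        }


@dataclass(frozen=True)
class InferenceConfig:
    resize_policy: str = "letterbox"
    leaf_input_size: tuple = (473, 473)
    lesion_input_size: tuple = (512, 512)
    leaf_application: str = "zero-out-background"
    lesion_gating: str = "intersect-with-leaf"
    area_resolution: str = "original-image"

    def to_dict(self):
        return asdict(self)


@dataclass
class RunLog:
    """Step-level loss trace plus the exact configuration that produced it."""

    stage: str
    seed: int
    config: dict
    losses: list = field(default_factory=list)   # (epoch, step, lr, loss)
    val_metrics: list = field(default_factory=list)
    artifact_hash: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.losses, columns=["epoch", "step", "lr", "loss"])

    def save(self, out_dir):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / f"loss_{self.stage}.csv", index=False)
        meta = {"stage": self.stage, "seed": self.seed, "config": self.config,
                "artifact_hash": self.artifact_hash,
                "val_metrics": self.val_metrics}
        (out_dir / f"run_{self.stage}.json").write_text(json.dumps(meta, indent=1))


class UngradableImageError(RuntimeError):
    """Stage 1 predicted no leaf pixels; no severity ratio can be formed."""


def build_model(stage: str, tiny: bool = False, seed: int = 0):
    if stage == "leaf":
        return LDPNet(LDPNetConfig.tiny() if tiny else LDPNetConfig(), seed=seed)
    if stage == "lesion":
        return DUNet(DUNetConfig.tiny() if tiny else DUNetConfig(), seed=seed)
    raise ValueError(f"unknown stage {stage!r}")


def _normalize(image: np.ndarray) -> np.ndarray:
    return (np.asarray(image, np.float32) / 127.5 - 1.0).transpose(2, 0, 1)


def _params_hash(model) -> str:
    h = hashlib.sha1()
    for name, p in sorted(model.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def _load_stage_samples(manifest: pd.DataFrame, stage: str, split: str = "train"):
    rows = manifest[manifest["split"] == split] if "split" in manifest else manifest
    out = []
    for _, row in rows.iterrows():
        image = dataset_io.read_image_png(row["image"])
        leaf = dataset_io.read_mask_png(row["leaf_mask"])
        lesion = dataset_io.read_mask_png(row["lesion_mask"])
        out.append((image, leaf, lesion))
    return out


def _stage_pair(image, leaf, lesion, stage):
    if stage == "leaf":
        return image, leaf
    return image * leaf[..., None], lesion  # stage 2 sees the masked image


def train(stage: str, manifest: pd.DataFrame | None = None,
          cfg: TrainConfig | None = None, model=None, samples=None,
          out_dir=None):
    """Train one stage; returns (model, RunLog).

    ``samples`` may supply in-memory (image, leaf_mask, lesion_mask) triples
    instead of a manifest. The leaf stage trains with per-pixel
    cross-entropy, the lesion stage with focal loss (gamma 2); letterbox
    padding is excluded from the loss. Seed-fixed runs are reproducible on
    CPU.
    """
    cfg = (cfg if cfg is not None else TrainConfig(stage=stage)).resolved()
    if cfg.stage != stage:
        raise ValueError("cfg.stage does not match requested stage")
    if samples is None:
        if manifest is None:
            raise ValueError("provide a manifest or in-memory samples")
        samples = _load_stage_samples(manifest, stage)
    if not samples:
        raise ValueError("empty training set")
    if model is None:
        model = build_model(stage, seed=cfg.seed)

    xs, ts, vs = [], [], []
    for image, leaf, lesion in samples:
        img, target = _stage_pair(image, leaf, lesion, stage)
        if img.shape[:2] != target.shape:
            raise ValueError("image/mask size mismatch in training data")
        lb_img, meta = letterbox_image(img, cfg.input_size)
        lb_t, _ = letterbox_mask(target, cfg.input_size)
        xs.append(_normalize(lb_img))
        ts.append(lb_t.astype(np.int64))
        vs.append(valid_region(meta))
    xs, ts, vs = np.stack(xs), np.stack(ts), np.stack(vs)

    gamma_focal = 0.0 if stage == "leaf" else 2.0
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.base_lr)
    n = len(samples)
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    log = RunLog(stage=stage, seed=cfg.seed, config=cfg.to_dict())
    model.train()
    for epoch in range(cfg.epochs):
        if stage == "leaf":
            lr = step_decay(cfg.base_lr, epoch,
                            [int(cfg.epochs * 0.6), int(cfg.epochs * 0.9)],
                            cfg.lr_decay_gamma)
        else:
            lr = exp_decay(cfg.base_lr, epoch, cfg.lr_decay_gamma)
        opt.lr = lr
        order = rng.permutation(n)
        for step in range(steps_per_epoch):
            idx = order[step * cfg.batch_size:(step + 1) * cfg.batch_size]
            logits = model(Tensor(xs[idx]))
            loss = focal_softmax_loss(logits, ts[idx], gamma=gamma_focal,
                                      valid=vs[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            log.losses.append((epoch, step, lr, loss.item()))
    log.artifact_hash = _params_hash(model)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        model.save(out_dir / f"{stage}_model.npz")
        log.save(out_dir)
    return model, log


def train_two_stage(samples, leaf_cfg: TrainConfig, lesion_cfg: TrainConfig,
                    leaf_model=None, lesion_model=None, out_dir=None):
    """Train the full cascade: leaf stage first, then the lesion stage on
    images masked by the *predicted* leaf masks.

    Training stage 2 on predicted rather than ground-truth leaf masks keeps
    its input distribution identical between training and deployment, which
    measurably reduces systematic lesion under-detection downstream of an
    imperfect stage 1. Lesion targets are intersected with the predicted
    leaf so the learning problem matches the gated inference path. Samples
    whose predicted leaf is empty fall back to their annotated mask.

    Returns (leaf_model, lesion_model, (leaf_log, lesion_log)).
    """
    leaf_model, leaf_log = train("leaf", cfg=leaf_cfg, model=leaf_model,
                                 samples=samples, out_dir=out_dir)
    predictor = ModelPredictor(leaf_model, leaf_cfg.resolved().input_size)
    cascade = []
    for image, leaf, lesion in samples:
        pred_leaf = predictor(image)
        if pred_leaf.sum() == 0:
            logger.warning("cascade: empty predicted leaf, using annotation")
            pred_leaf = leaf
        cascade.append((image, pred_leaf, lesion & pred_leaf))
    lesion_model, lesion_log = train("lesion", cfg=lesion_cfg,
                                     model=lesion_model, samples=cascade,
                                     out_dir=out_dir)
    return leaf_model, lesion_model, (leaf_log, lesion_log)


class ModelPredictor:
    """Letterbox-in / unletterbox-out wrapper making a model a mask oracle
    at original image resolution."""

    def __init__(self, model, input_size):
        self.model = model
        self.input_size = tuple(input_size)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        lb, meta = letterbox_image(image, self.input_size)
        mask = self.model.predict(lb)
        return unletterbox_mask(mask, meta)


class GroundTruthPredictor:
    """Oracle stub returning a fixed ground-truth mask (for pipeline tests)."""

    def __init__(self, mask: np.ndarray):
        self.mask = np.asarray(mask, dtype=np.uint8)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return self.mask


@dataclass
class TwoStageResult:
    leaf_mask: np.ndarray
    lesion_mask: np.ndarray
    ratio_percent: float
    level: int


def infer_two_stage(image: np.ndarray, leaf_predictor, lesion_predictor,
                    cfg: InferenceConfig | None = None) -> TwoStageResult:
    """Leaf -> lesion -> ratio -> level for one image.

    Predictors are callables mapping an original-resolution image to a
    binary mask at the same resolution (see :class:`ModelPredictor`).
    Raises :class:`UngradableImageError` when no leaf is predicted.
    """
    cfg = cfg if cfg is not None else InferenceConfig()
    image = np.asarray(image)
    leaf_mask = np.asarray(leaf_predictor(image), dtype=np.uint8)
    if leaf_mask.shape != image.shape[:2]:
        raise ValueError("leaf predictor returned a mask of the wrong size")
    if leaf_mask.sum() == 0:
        raise UngradableImageError("no leaf predicted; image is ungradable")
    masked = image * leaf_mask[..., None]
    lesion_mask = np.asarray(lesion_predictor(masked), dtype=np.uint8)
    lesion_mask = lesion_mask & leaf_mask  # gating keeps S_disease <= S_leaf
    L, level = severity.grade_from_masks(leaf_mask, lesion_mask)
    return TwoStageResult(leaf_mask, lesion_mask, L, level)


def evaluate(manifest: pd.DataFrame, leaf_predictor, lesion_predictor,
             out_dir=None, cfg: InferenceConfig | None = None,
             split: str = "test") -> dict:
    """Segmentation + grading reports over a manifest split.

    Builds the combined three-class labeling {background, leaf, disease}
    (disease pixels excluded from leaf) from ground truth and predictions,
    micro-pools the confusion over the split, and grades every image.
    Ungradable images are recorded and excluded from the grading report.
    """
    rows = manifest[manifest["split"] == split] if "split" in manifest else manifest
    if len(rows) == 0:
        raise ValueError(f"no images in split {split!r}")
    true_labels, pred_labels = [], []
    true_levels, pred_levels, ungradable = [], [], []
    first_overlay = None
    for _, row in rows.iterrows():
        image = dataset_io.read_image_png(row["image"])
        gt_leaf = dataset_io.read_mask_png(row["leaf_mask"])
        gt_lesion = dataset_io.read_mask_png(row["lesion_mask"])
        t = np.zeros(gt_leaf.shape, np.int64)
        t[gt_leaf > 0] = 1
        t[(gt_lesion > 0) & (gt_leaf > 0)] = 2
        try:
            res = infer_two_stage(image, leaf_predictor, lesion_predictor, cfg)
        except UngradableImageError:
            ungradable.append(row["image"])
            true_labels.append(t)
            pred_labels.append(np.zeros_like(t))
            continue
        p = np.zeros_like(t)
        p[res.leaf_mask > 0] = 1
        p[res.lesion_mask > 0] = 2
        true_labels.append(t)
        pred_labels.append(p)
        true_levels.append(int(row["level"]))
        pred_levels.append(res.level)
        if first_overlay is None:
            first_overlay = (image, gt_leaf, res.leaf_mask)
    seg = metrics.segmentation_report(true_labels, pred_labels,
                                      ("background", "leaf", "disease"))
    grading = severity.grading_report(true_levels, pred_levels) if true_levels else None
    if ungradable:
        logger.warning("%d image(s) ungradable (no leaf predicted)", len(ungradable))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg_used = cfg if cfg is not None else InferenceConfig()
        (out_dir / "inference_config.json").write_text(
            json.dumps(cfg_used.to_dict(), indent=1))
        metrics.report_to_frame(seg).to_csv(out_dir / "segmentation_report.csv",
                                            index=False)
        payload = {k: v for k, v in seg.items() if k != "confusion"}
        payload["confusion"] = seg["confusion"].tolist()
        (out_dir / "segmentation_report.json").write_text(json.dumps(payload, indent=1))
        if grading is not None:
            grading.to_frame().to_csv(out_dir / "grading_report.csv", index=False)
            (out_dir / "grading_report.json").write_text(json.dumps({
                "n_images": grading.n_images, "n_correct": grading.n_correct,
                "precision_percent": grading.precision_percent,
                "macro_precision_percent": grading.macro_precision_percent,
                "macro_precision_levels_1_3_percent":
                    grading.macro_precision_levels_1_3_percent,
                "confusion": grading.confusion.tolist(),
            }, indent=1))
            from . import viz
            viz.confusion_heatmap(grading.confusion, out_dir / "confusion.png")
        if first_overlay is not None:
            from . import viz
            viz.save_overlay(*first_overlay, out_dir / "overlay_example.png")
    return {"segmentation": seg, "grading": grading, "ungradable": ungradable}
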