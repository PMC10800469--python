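"""Shared fixtures: synthetic scenes and (session-scoped) trained tiny models."""

from __future__ import annotations

import numpy as np
import pytest

from frogeye import pipeline, synthetic_data as sd
from frogeye.dunet import DUNet, DUNetConfig
from frogeye.ldpnet import LDPNet, LDPNetConfig

TINY = (64, 64)


def make_samples(n, levels, seed, canvas=TINY):
    """n synthetic scenes cycling through the given severity levels."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        level = levels[i % len(levels)]
        scene, leaf, lesion = sd.specs_for_level(level, rng, canvas)
        out.append(sd.generate_scene(scene, leaf, lesion))
    return out


@pytest.fixture(scope="session")
def overfit_scenes():
    """8 mixed-level scenes used by both overfit fixtures."""
    return make_samples(8, [1, 2, 3, 4, 5], seed=7)


@pytest.fixture(scope="session")
def leaf_overfit(overfit_scenes):
    """Thin leaf model trained to convergence on 8 scenes (fixed seed)."""
    samples = [(s.image, s.leaf_mask, s.lesion_mask) for s in overfit_scenes]
    cfg = pipeline.TrainConfig(stage="leaf", input_size=TINY, epochs=200,
                               batch_size=8, base_lr=1e-3, seed=0)
    model = LDPNet(LDPNetConfig.tiny(TINY), seed=0)
    model, log = pipeline.train("leaf", cfg=cfg, model=model, samples=samples)
    return model, log, overfit_scenes


@pytest.fixture(scope="session")
def lesion_overfit(overfit_scenes):
    """Thin lesion model trained to convergence on the same 8 scenes."""
    samples = [(s.image, s.leaf_mask, s.lesion_mask) for s in overfit_scenes]
    cfg = pipeline.TrainConfig(stage="lesion", input_size=TINY, epochs=300,
                               batch_size=8, base_lr=2e-3, lr_decay_gamma=1.0,
                               seed=0)
    model = DUNet(DUNetConfig.tiny(TINY), seed=0)
    model, log = pipeline.train("lesion", cfg=cfg, model=model, samples=samples)
    return model, log, overfit_scenes


PIPELINE_CANVAS = (96, 96)
HELDOUT_WINDOWS = {1: (0.10, 0.60), 4: (2.45, 2.70), 5: (3.40, 6.00)}


def heldout_sample(level, rng, canvas=PIPELINE_CANVAS, margin=0.3):
    """Scene whose true ratio sits >= ``margin`` percentage points from every
    grading threshold (only levels with wide-enough intervals qualify)."""
    lo, hi = HELDOUT_WINDOWS[level]
    while True:
        scene, leaf, _ = sd.specs_for_level(level, rng, canvas)
        lesion = sd.LesionSpec(target_ratio_percent=float(rng.uniform(lo, hi)),
                               spot_radius_range=(1, 3))
        s = sd.generate_scene(scene, leaf, lesion)
        dist = min(abs(s.true_ratio_percent - t)
                   for t in sd.DEFAULT_THRESHOLDS)
        if s.true_level == level and dist >= margin:
            return s


@pytest.fixture(scope="session")
def trained_pipeline():
    """Cascade-trained tiny two-stage pipeline (48 scenes at 96x96) plus a
    disjoint 20-scene held-out set drawn from the same generator stream."""
    cv = PIPELINE_CANVAS
    rng = np.random.default_rng(11)
    train_scenes = []
    for i in range(48):
        scene, leaf, lesion = sd.specs_for_level([1, 2, 3, 4, 5][i % 5], rng, cv)
        train_scenes.append(sd.generate_scene(scene, leaf, lesion))
    held = [heldout_sample(lv, rng, cv) for lv in [1] * 7 + [4] * 7 + [5] * 6]
    samples = [(s.image, s.leaf_mask, s.lesion_mask) for s in train_scenes]
    leaf_cfg = pipeline.TrainConfig(stage="leaf", input_size=cv, epochs=200,
                                    batch_size=8, base_lr=1e-3, seed=0)
    les_cfg = pipeline.TrainConfig(stage="lesion", input_size=cv, epochs=100,
                                   batch_size=8, base_lr=2e-3,
                                   lr_decay_gamma=1.0, seed=0)
    leaf_model, les_model, _ = pipeline.train_two_stage(
        samples, leaf_cfg, les_cfg,
        leaf_model=LDPNet(LDPNetConfig.tiny(cv), seed=0),
        lesion_model=DUNet(DUNetConfig.tiny(cv), seed=0))
    return leaf_model, les_model, held
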