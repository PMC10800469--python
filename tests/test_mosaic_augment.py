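"""Mosaic collaging: layout, provenance traceability, default-policy counts."""

import numpy as np
import pandas as pd
import pytest

from frogeye import dataset_io
from frogeye.mosaic_augment import (MosaicConfig, augment_training_set, mosaic4,
                                    reconstruct)
from frogeye.synthetic_data import generate_dataset


def _sample(rng, h=64, w=64, leaf_fill=None, lesion_fill=None):
    image = rng.integers(0, 256, (h, w, 3)).astype(np.uint8)
    leaf = (np.ones if leaf_fill else np.zeros)((h, w)) if leaf_fill is not None \
        else rng.integers(0, 2, (h, w))
    lesion = (np.ones if lesion_fill else np.zeros)((h, w)) if lesion_fill is not None \
        else rng.integers(0, 2, (h, w))
    return {"image": image, "leaf_mask": leaf.astype(np.uint8),
            "lesion_mask": (lesion & leaf).astype(np.uint8)
            if lesion_fill is None else lesion.astype(np.uint8)}


class TestMosaic4:
    def test_all_leaf_sources_give_all_leaf_collage(self):
        rng = np.random.default_rng(0)
        samples = [_sample(rng, leaf_fill=True, lesion_fill=False)
                   for _ in range(4)]
        out = mosaic4(samples, MosaicConfig(output_size=(96, 96), seed=1))
        assert (out.leaf_mask == 1).all()
        assert out.lesion_mask.sum() == 0

    def test_fixed_seed_deterministic(self):
        rng = np.random.default_rng(1)
        samples = [_sample(rng) for _ in range(4)]
        cfg = MosaicConfig(output_size=(100, 120), center_jitter=0.3, seed=7)
        a, b = mosaic4(samples, cfg), mosaic4(samples, cfg)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.lesion_mask, b.lesion_mask)
        assert a.provenance == b.provenance

    def test_known_layout_lesion_count_is_sum_of_quarters(self):
        # zero jitter puts the junction at the exact center; sources exactly
        # the quadrant size leave no crop freedom, so each quadrant is one
        # whole source and collage lesion pixels = sum over the four sources
        rng = np.random.default_rng(2)
        samples = [_sample(rng, h=50, w=60) for _ in range(4)]
        cfg = MosaicConfig(output_size=(100, 120), center_jitter=0.0, seed=0)
        out = mosaic4(samples, cfg)
        expected = sum(s["lesion_mask"].sum() for s in samples)
        assert out.lesion_mask.sum() == expected

    def test_masks_and_image_share_the_transform(self):
        rng = np.random.default_rng(3)
        samples = [_sample(rng) for _ in range(4)]
        out = mosaic4(samples, MosaicConfig(output_size=(96, 96), seed=4))
        for rec in out.provenance:
            y0, x0, qh, qw = rec["quadrant"]
            cy0, cx0, _, _ = rec["window"]
            src = samples[rec["source"]]
            if rec["scaled_size"] == src["image"].shape[:2]:
                assert np.array_equal(
                    out.image[y0:y0 + qh, x0:x0 + qw],
                    src["image"][cy0:cy0 + qh, cx0:cx0 + qw])
                assert np.array_equal(
                    out.leaf_mask[y0:y0 + qh, x0:x0 + qw],
                    src["leaf_mask"][cy0:cy0 + qh, cx0:cx0 + qw])

    def test_provenance_reconstruction_bit_exact(self):
        rng = np.random.default_rng(5)
        samples = [_sample(rng, h=40, w=40) for _ in range(4)]
        cfg = MosaicConfig(output_size=(96, 96), center_jitter=0.35, seed=11)
        out = mosaic4(samples, cfg)  # forces scale-then-crop on some quadrants
        rebuilt = reconstruct(samples, out.provenance, cfg.output_size)
        assert np.array_equal(out.image, rebuilt.image)
        assert np.array_equal(out.leaf_mask, rebuilt.leaf_mask)
        assert np.array_equal(out.lesion_mask, rebuilt.lesion_mask)

    def test_wrong_sample_count_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            mosaic4([_sample(rng)] * 3, MosaicConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MosaicConfig(output_size=(32, 32))
        with pytest.raises(ValueError):
            MosaicConfig(center_jitter=0.5)


@pytest.fixture(scope="module")
def small_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("ds")
    manifest = generate_dataset([2, 1, 1, 1, 1], out, seed=3,
                                canvas_size=(48, 48))
    return manifest, out


class TestAugmentTrainingSet:
    def test_default_policy_doubles_the_training_set(self, small_dataset,
                                                     tmp_path):
        manifest, _ = small_dataset
        out = augment_training_set(manifest, MosaicConfig(seed=0), tmp_path)
        assert len(out) == 2 * len(manifest)
        assert (out["split"] == "train").all()

    def test_anchor_level_accounting_doubles_each_level(self, small_dataset,
                                                        tmp_path):
        manifest, _ = small_dataset
        out = augment_training_set(manifest, MosaicConfig(seed=0), tmp_path)
        before = manifest["level"].value_counts()
        after = out["anchor_level"].value_counts()
        for level, n in before.items():
            assert after[level] == 2 * n

    def test_collage_level_regraded_from_own_masks(self, small_dataset,
                                                   tmp_path):
        from frogeye.severity import grade

        manifest, _ = small_dataset
        out = augment_training_set(manifest, MosaicConfig(seed=1), tmp_path)
        collages = out.iloc[len(manifest):]
        for _, row in collages.iterrows():
            leaf = dataset_io.read_mask_png(row["leaf_mask"])
            lesion = dataset_io.read_mask_png(row["lesion_mask"])
            if leaf.sum():
                ratio = 100 * (lesion & leaf).sum() / leaf.sum()
                assert grade(ratio) == row["level"]

    def test_fewer_than_four_training_images_rejected(self, tmp_path):
        manifest = pd.DataFrame({
            "image": ["a.png"], "leaf_mask": ["b.png"], "lesion_mask": ["c.png"],
            "ratio_percent": [0.0], "level": [1], "split": ["train"],
        })
        with pytest.raises(ValueError, match="4"):
            augment_training_set(manifest, MosaicConfig(seed=0), tmp_path)

    def test_empty_training_manifest_rejected(self, tmp_path):
        manifest = pd.DataFrame(columns=["image", "leaf_mask", "lesion_mask",
                                         "ratio_percent", "level", "split"])
        with pytest.raises(ValueError):
            augment_training_set(manifest, MosaicConfig(seed=0), tmp_path)
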