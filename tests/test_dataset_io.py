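"""Annotation rasterization, mask PNG round-trips, manifest splitting."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from frogeye.dataset_io import (AnnotationDoc, PolygonAnnotation,
                                polygons_to_mask, read_mask_png, split_manifest,
                                write_mask_png)


def brute_force_mask(doc, label):
    """Exhaustive point-in-polygon over all pixel centers (boundary counts)."""
    h, w = doc.image_size
    mask = np.zeros((h, w), np.uint8)
    geoms = [Polygon(p.points) for p in doc.polygons if p.label == label]
    for y in range(h):
        for x in range(w):
            from shapely.geometry import Point

            pt = Point(x, y)
            if any(g.covers(pt) for g in geoms):
                mask[y, x] = 1
    return mask


class TestPolygonsToMask:
    def test_no_polygons_gives_empty_mask(self):
        doc = AnnotationDoc((16, 16), [])
        assert polygons_to_mask(doc, "leaf").sum() == 0

    def test_square_with_inclusive_boundary(self):
        square = PolygonAnnotation("leaf", ((10, 10), (20, 10), (20, 20), (10, 20)))
        doc = AnnotationDoc((32, 32), [square])
        mask = polygons_to_mask(doc, "leaf")
        assert mask.sum() == 121  # 11x11 pixel centers inside or on the boundary

    def test_overlapping_squares_union_not_sum(self):
        a = PolygonAnnotation("leaf", ((0, 0), (10, 0), (10, 10), (0, 10)))
        b = PolygonAnnotation("leaf", ((5, 5), (15, 5), (15, 15), (5, 15)))
        doc = AnnotationDoc((20, 20), [a, b])
        mask = polygons_to_mask(doc, "leaf")
        assert mask.sum() == 121 + 121 - 36  # overlap counted once

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_exhaustive_point_in_polygon(self, seed):
        rng = np.random.default_rng(seed)
        # star-shaped polygon (vertices sorted by angle) so it is simple/valid
        raw = rng.uniform(2, 28, size=(6, 2))
        center = raw.mean(axis=0)
        order = np.argsort(np.arctan2(*(raw - center).T[::-1]))
        pts = tuple((float(x), float(y)) for x, y in raw[order])
        doc = AnnotationDoc((30, 30), [PolygonAnnotation("leaf", pts)])
        assert np.array_equal(polygons_to_mask(doc, "leaf"),
                              brute_force_mask(doc, "leaf"))

    def test_unknown_label_warns_and_returns_empty(self):
        doc = AnnotationDoc((8, 8), [PolygonAnnotation(
            "leaf", ((1, 1), (6, 1), (6, 6)))])
        with pytest.warns(UserWarning, match="disease"):
            mask = polygons_to_mask(doc, "disease")
        assert mask.sum() == 0

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            PolygonAnnotation("leaf", ((0, 0), (1, 1)))


class TestAnnotationJson:
    def test_json_roundtrip_lossless(self):
        doc = AnnotationDoc((48, 64), [
            PolygonAnnotation("leaf", ((1.5, 2.0), (10.0, 2.0), (5.0, 9.25))),
            PolygonAnnotation("disease", ((3, 3), (4, 3), (4, 4), (3, 4))),
        ])
        back = AnnotationDoc.from_json(doc.to_json())
        assert back.image_size == doc.image_size
        assert back.polygons == doc.polygons


class TestMaskPng:
    def test_random_mask_roundtrips_exactly(self, tmp_path):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 2, (32, 32)).astype(np.uint8)
        p = tmp_path / "m.png"
        write_mask_png(mask, p)
        assert np.array_equal(read_mask_png(p), mask)

    def test_all_ones_roundtrip(self, tmp_path):
        mask = np.ones((8, 8), np.uint8)
        p = tmp_path / "m.png"
        write_mask_png(mask, p)
        assert np.array_equal(read_mask_png(p), mask)

    def test_foreign_value_named_in_error(self, tmp_path):
        from PIL import Image

        p = tmp_path / "bad.png"
        Image.fromarray(np.full((4, 4), 2, np.uint8), mode="L").save(p)
        with pytest.raises(ValueError, match="2"):
            read_mask_png(p)

    def test_non_binary_mask_rejected_on_write(self, tmp_path):
        with pytest.raises(ValueError, match="3"):
            write_mask_png(np.full((4, 4), 3, np.uint8), tmp_path / "m.png")


def _manifest(levels):
    return pd.DataFrame({
        "image": [f"i{i}.png" for i in range(len(levels))],
        "leaf_mask": [f"l{i}.png" for i in range(len(levels))],
        "lesion_mask": [f"d{i}.png" for i in range(len(levels))],
        "ratio_percent": [0.5] * len(levels),
        "level": levels,
    })


class TestSplitManifest:
    def test_ten_items_split_8_1_1(self):
        out = split_manifest(_manifest([1] * 10), seed=0)
        counts = out["split"].value_counts()
        assert counts["train"] == 8 and counts["val"] == 1 and counts["test"] == 1

    def test_empty_manifest_empty_splits(self):
        out = split_manifest(_manifest([]), seed=0)
        assert len(out) == 0

    def test_fixed_seed_is_deterministic(self):
        m = _manifest([1] * 40 + [2] * 35 + [3] * 25)
        a = split_manifest(m, seed=123)["split"]
        b = split_manifest(m, seed=123)["split"]
        assert a.tolist() == b.tolist()

    def test_different_seed_changes_assignment(self):
        m = _manifest([1] * 50)
        a = split_manifest(m, seed=1)["split"]
        b = split_manifest(m, seed=2)["split"]
        assert a.tolist() != b.tolist()

    @pytest.mark.parametrize("n", [5, 17, 100, 238])
    def test_split_conserves_items_and_stratifies(self, n):
        m = _manifest([1] * n + [2] * n)
        out = split_manifest(m, seed=0)
        assert len(out) == len(m)
        for level in (1, 2):
            sub = out[out["level"] == level]
            expected_test = int(np.floor(n / 10 + 0.5))
            expected_val = int(np.ceil(n / 10 - 0.5))
            assert (sub["split"] == "test").sum() == expected_test
            assert (sub["split"] == "val").sum() == expected_val

    def test_tie_goes_to_test(self):
        # n=15: n/10 = 1.5 -> test rounds up to 2, val rounds down to 1
        out = split_manifest(_manifest([1] * 15), seed=0)
        c = out["split"].value_counts()
        assert c["test"] == 2 and c["val"] == 1 and c["train"] == 12

    def test_small_level_all_to_train_with_warning(self):
        with pytest.warns(UserWarning, match="train"):
            out = split_manifest(_manifest([1, 1]), seed=0)
        assert (out["split"] == "train").all()

    def test_invalid_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_manifest(_manifest([1] * 10), ratios=(8, 0, 1), seed=0)
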