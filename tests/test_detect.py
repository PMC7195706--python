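"""IoU, filtering, NMS, raw-grid decoding and the letterbox transform."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strigacount.annotations import Box
from strigacount.detect import (
    Detection,
    RawOutputGrid,
    decode_raw,
    iou,
    letterbox,
    load_raw_grid,
    nms,
    objectness_filter,
    save_raw_grid,
)


def det(x0, y0, x1, y1, obj, label="seed"):
    other = "radicle" if label == "seed" else "seed"
    return Detection(
        box=Box(x0, y0, x1, y1, label),
        objectness=obj,
        class_probs={label: obj, other: 0.01},
    )


boxes_strategy = st.builds(
    lambda x0, y0, w, h: Box(x0, y0, x0 + w, y0 + h, "seed"),
    x0=st.floats(0, 500), y0=st.floats(0, 500),
    w=st.floats(1, 200), h=st.floats(1, 200),
)


class TestIou:
    def test_identical_boxes(self):
        b = Box(3, 4, 10, 12, "seed")
        assert iou(b, b) == pytest.approx(1.0)

    def test_disjoint_boxes(self):
        assert iou(Box(0, 0, 5, 5, "seed"), Box(10, 10, 20, 20, "seed")) == 0.0

    def test_hand_computed_overlap(self):
        # intersection 1, union 4 + 4 - 1 = 7
        a = Box(0, 0, 2, 2, "seed")
        b = Box(1, 1, 3, 3, "seed")
        assert iou(a, b) == pytest.approx(1 / 7)

    @settings(derandomize=True, max_examples=100)
    @given(a=boxes_strategy, b=boxes_strategy)
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b, a))

    @settings(derandomize=True, max_examples=50)
    @given(a=boxes_strategy, b=boxes_strategy)
    def test_matches_shapely(self, a, b):
        from shapely.geometry import box as shapely_box

        pa = shapely_box(a.x_min, a.y_min, a.x_max, a.y_max)
        pb = shapely_box(b.x_min, b.y_min, b.x_max, b.y_max)
        expected = pa.intersection(pb).area / pa.union(pb).area
        assert iou(a, b) == pytest.approx(expected, abs=1e-9)


class TestObjectnessFilter:
    def test_threshold_is_inclusive(self):
        dets = [det(0, 0, 10, 10, o) for o in (0.05, 0.06, 0.9)]
        kept = objectness_filter(dets, 0.06)
        assert [d.objectness for d in kept] == [0.06, 0.9]

    def test_boundary_thresholds(self):
        dets = [det(0, 0, 10, 10, o) for o in (0.0, 0.5, 1.0)]
        assert len(objectness_filter(dets, 0.0)) == 3
        assert [d.objectness for d in objectness_filter(dets, 1.0)] == [1.0]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            objectness_filter([], 1.5)

    @settings(derandomize=True, max_examples=30)
    @given(objs=st.lists(st.floats(0, 1), max_size=20),
           p1=st.floats(0, 1), p2=st.floats(0, 1))
    def test_monotone_in_threshold(self, objs, p1, p2):
        dets = [det(0, 0, 10, 10, o) for o in objs]
        lo, hi = sorted((p1, p2))
        assert len(objectness_filter(dets, hi)) <= len(objectness_filter(dets, lo))


def oracle_nms(dets, thr):
    """Independent suppression rule: a detection survives iff no surviving
    same-class detection with strictly higher objectness overlaps it beyond
    the threshold (IoU via shapely).  Assumes distinct objectness values."""
    from shapely.geometry import box as shapely_box

    def sh_iou(a, b):
        pa = shapely_box(a.x_min, a.y_min, a.x_max, a.y_max)
        pb = shapely_box(b.x_min, b.y_min, b.x_max, b.y_max)
        return pa.intersection(pb).area / pa.union(pb).area

    by_score = sorted(dets, key=lambda d: -d.objectness)
    surviving: list[Detection] = []
    for d in by_score:
        if not any(
            s.predicted_class == d.predicted_class
            and s.objectness > d.objectness
            and sh_iou(s.box, d.box) > thr
            for s in surviving
        ):
            surviving.append(d)
    return surviving


def random_instance(rng, n_max=10):
    n = int(rng.integers(1, n_max + 1))
    objs = rng.permutation(np.linspace(0.1, 0.95, n))  # distinct scores
    dets = []
    for k in range(n):
        x0, y0 = rng.uniform(0, 80, 2)
        w, h = rng.uniform(5, 40, 2)
        label = "seed" if rng.uniform() < 0.7 else "radicle"
        dets.append(det(x0, y0, x0 + w, y0 + h, float(objs[k]), label))
    return dets


class TestNms:
    def test_single_detection_survives(self):
        d = det(0, 0, 10, 10, 0.5)
        assert nms([d]) == [d]

    def test_overlapping_same_class_suppressed(self):
        hi = det(0, 0, 10, 10, 0.9)
        lo = det(1, 1, 11, 11, 0.8)   # IoU ~0.68 > 0.45
        assert nms([hi, lo], 0.45) == [hi]

    def test_cross_class_overlap_retained(self):
        seed = det(0, 0, 10, 10, 0.9, "seed")
        radicle = det(0, 0, 10, 10, 0.8, "radicle")
        assert len(nms([seed, radicle], 0.45)) == 2

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            nms([], 0.0)

    def test_suppression_free_and_matches_oracle(self, rng):
        for _ in range(100):
            dets = random_instance(rng)
            kept = nms(dets, 0.45)
            # suppression-free: no retained same-class pair above threshold
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    if a.predicted_class == b.predicted_class:
                        assert iou(a.box, b.box) <= 0.45
            expected = {id(d) for d in oracle_nms(dets, 0.45)}
            assert {id(d) for d in kept} == expected


class TestDecodeRaw:
    def make_grid(self, S=19, A=1, fill=0.0):
        return RawOutputGrid(values=np.full((S, S, A, 7), fill))

    def test_zero_logits_give_cell_center_and_anchor_size(self):
        raw = self.make_grid()
        dets = decode_raw(raw, [(10, 14)], input_resolution=608)
        # cell (0, 0): sigmoid(0)=0.5 -> center at half a 32 px cell
        d0 = dets[0]
        cx, cy = d0.box.center
        assert (cx, cy) == pytest.approx((16.0, 16.0))
        assert d0.box.width == pytest.approx(10.0)
        assert d0.box.height == pytest.approx(14.0)
        assert d0.objectness == pytest.approx(0.5)

    def test_detection_count_is_grid_times_anchors(self):
        raw = RawOutputGrid(values=np.zeros((5, 5, 3, 7)))
        dets = decode_raw(raw, [(10, 14), (20, 20), (30, 40)])
        assert len(dets) == 5 * 5 * 3

    def test_large_negative_objectness_logit(self):
        raw = RawOutputGrid(values=np.zeros((3, 3, 1, 7)))
        raw.values[..., 4] = -10.0
        dets = decode_raw(raw, [(10, 10)])
        assert all(d.objectness < 1e-4 for d in dets)

    def test_hand_computed_cell(self):
        raw = RawOutputGrid(values=np.zeros((19, 19, 1, 7)))
        t_xy = 0.4055  # sigmoid -> 0.600
        raw.values[2, 3, 0, 0] = t_xy
        raw.values[2, 3, 0, 1] = t_xy
        raw.values[2, 3, 0, 2] = math.log(2.0)
        dets = decode_raw(raw, [(10, 14)], input_resolution=608)
        d = dets[2 * 19 + 3]
        cx, cy = d.box.center
        assert cx == pytest.approx((3 + 0.6) * 32, abs=0.01)
        assert cy == pytest.approx((2 + 0.6) * 32, abs=0.01)
        assert d.box.width == pytest.approx(20.0, abs=1e-6)
        assert d.box.height == pytest.approx(14.0, abs=1e-6)

    def test_anchor_count_mismatch(self):
        raw = RawOutputGrid(values=np.zeros((3, 3, 2, 7)))
        with pytest.raises(ValueError, match="anchor"):
            decode_raw(raw, [(10, 10)])

    def test_grid_shape_validation(self):
        with pytest.raises(ValueError):
            RawOutputGrid(values=np.zeros((3, 4, 2, 7)))
        with pytest.raises(ValueError):
            RawOutputGrid(values=np.zeros((3, 3, 2, 6)))

    def test_save_load_round_trip(self, tmp_path, rng):
        raw = RawOutputGrid(values=rng.normal(size=(7, 7, 3, 7)))
        save_raw_grid(raw, tmp_path / "grid")
        again = load_raw_grid(tmp_path / "grid")
        assert np.array_equal(again.values, raw.values)
        assert again.input_resolution == raw.input_resolution
        assert again.class_names == raw.class_names


class TestLetterbox:
    def test_square_image_pure_scale(self):
        img = np.zeros((2500, 2500), dtype=np.uint8)
        resized, t = letterbox(img, 608)
        assert resized.shape == (608, 608)
        assert (t.pad_x, t.pad_y) == (0.0, 0.0)
        assert t.scale == pytest.approx(608 / 2500)

    def test_capture_aspect_gets_vertical_padding(self):
        # the raw two-shot capture frame: 2560 x 1920 landscape
        img = np.zeros((1920, 2560), dtype=np.uint8)
        resized, t = letterbox(img, 608)
        assert resized.shape == (608, 608)
        assert t.scale == pytest.approx(608 / 2560)
        assert t.pad_y == 76.0 and t.pad_x == 0.0

    def test_box_round_trip_within_one_pixel(self, rng):
        img = np.zeros((1920, 2560), dtype=np.uint8)
        _, t = letterbox(img, 608)
        for _ in range(100):
            x0, y0 = rng.uniform(0, 2000, 2) * [1.0, 0.9]
            w, h = rng.uniform(2, 300, 2)
            b = Box(x0, min(y0, 1600), x0 + w, min(y0, 1600) + h, "seed")
            back = t.unmap_box(t.map_box(b))
            assert abs(back.x_min - b.x_min) <= 1.0
            assert abs(back.y_min - b.y_min) <= 1.0
            assert abs(back.x_max - b.x_max) <= 1.0
            assert abs(back.y_max - b.y_max) <= 1.0

    def test_invalid_resolution(self):
        with pytest.raises(ValueError):
            letterbox(np.zeros((10, 10)), 0)
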