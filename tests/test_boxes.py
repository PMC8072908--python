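import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammocad.boxes import (
    BoundingBox,
    Candidate,
    crop_patch,
    iou,
    load_candidates_csv,
    load_candidates_json,
    merge_candidates,
    save_candidates_csv,
    save_candidates_json,
)


def iou_by_pixel_counting(a: BoundingBox, b: BoundingBox) -> float:
    """Rasterized oracle for integer boxes: count covered unit cells."""
    x2 = int(max(a.x2, b.x2)) + 1
    y2 = int(max(a.y2, b.y2)) + 1
    ga = np.zeros((y2, x2), dtype=bool)
    gb = np.zeros((y2, x2), dtype=bool)
    ga[int(a.y):int(a.y2), int(a.x):int(a.x2)] = True
    gb[int(b.y):int(b.y2), int(b.x):int(b.x2)] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union


int_boxes = st.builds(
    BoundingBox,
    x=st.integers(0, 30), y=st.integers(0, 30),
    w=st.integers(1, 20), h=st.integers(1, 20),
)


class TestIoU:
    def test_identical_boxes(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 5, 5), BoundingBox(10, 10, 5, 5)) == 0.0
        # touching edges share zero area
        assert iou(BoundingBox(0, 0, 5, 5), BoundingBox(5, 0, 5, 5)) == 0.0

    def test_half_overlap(self):
        assert iou(BoundingBox(0, 0, 10, 10), BoundingBox(5, 0, 10, 10)) \
            == pytest.approx(1 / 3)

    @settings(max_examples=100, derandomize=True)
    @given(a=int_boxes, b=int_boxes)
    def test_matches_pixel_counting_oracle(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == iou(b, a)
        assert v == pytest.approx(iou_by_pixel_counting(a, b))
        if v == 1.0:
            assert (a.x, a.y, a.w, a.h) == (b.x, b.y, b.w, b.h)


class TestMerge:
    def test_disjoint_candidates_unchanged(self):
        cands = [Candidate(BoundingBox(0, 0, 10, 10), 0.9),
                 Candidate(BoundingBox(50, 50, 10, 10), 0.8)]
        out = merge_candidates(cands, 0.3)
        assert len(out) == 2

    def test_identical_candidates_collapse(self):
        c = Candidate(BoundingBox(5, 5, 20, 20), 0.8)
        out = merge_candidates([c, c], 0.3)
        assert len(out) == 1
        assert out[0].box == c.box

    def test_overlapping_chain_collapses_to_union(self):
        # five 20x20 boxes stepped 5 px apart: consecutive IoU = 300/500 > 0.3
        cands = [Candidate(BoundingBox(i * 5, 0, 20, 20), 0.5 + 0.05 * i)
                 for i in range(5)]
        out = merge_candidates(cands, 0.3)
        assert len(out) == 1
        assert (out[0].box.x, out[0].box.y) == (0, 0)
        assert (out[0].box.w, out[0].box.h) == (40, 20)
        assert out[0].degree == pytest.approx(0.7)

    def test_result_has_no_pair_above_threshold_and_is_idempotent(self, rng):
        for _ in range(30):
            cands = [
                Candidate(BoundingBox(*rng.integers(0, 40, 2), *rng.integers(5, 30, 2)),
                          float(rng.random()))
                for _ in range(rng.integers(2, 9))
            ]
            out = merge_candidates(cands, 0.3)
            for i in range(len(out)):
                for j in range(i + 1, len(out)):
                    assert iou(out[i].box, out[j].box) <= 0.3
            again = merge_candidates(out, 0.3)
            assert [c.box for c in again] == [c.box for c in out]

    def test_merge_never_loses_coverage(self, rng):
        for _ in range(20):
            cands = [
                Candidate(BoundingBox(*rng.integers(0, 30, 2), *rng.integers(5, 20, 2)))
                for _ in range(6)
            ]
            out = merge_candidates(cands, 0.3)
            grid_in = np.zeros((60, 60), dtype=bool)
            grid_out = np.zeros((60, 60), dtype=bool)
            for c in cands:
                grid_in[int(c.box.y):int(c.box.y2), int(c.box.x):int(c.box.x2)] = True
            for c in out:
                grid_out[int(c.box.y):int(c.box.y2), int(c.box.x):int(c.box.x2)] = True
            assert (grid_out | grid_in).sum() == grid_out.sum()

    def test_order_independence(self, rng):
        cands = [
            Candidate(BoundingBox(*rng.integers(0, 40, 2), *rng.integers(5, 25, 2)),
                      float(rng.random()))
            for _ in range(7)
        ]
        a = merge_candidates(cands, 0.3)
        b = merge_candidates(cands[::-1], 0.3)
        assert [c.box for c in a] == [c.box for c in b]


class TestCrop:
    def test_whole_image_resized(self, rng):
        img = rng.integers(0, 256, size=(100, 120)).astype(np.uint8)
        out = crop_patch(img, BoundingBox(0, 0, 120, 100), (200, 200))
        assert out.shape == (200, 200)

    def test_exact_size_box_is_identity(self, rng):
        img = rng.integers(0, 256, size=(400, 400)).astype(np.uint8)
        out = crop_patch(img, BoundingBox(37, 51, 200, 200), (200, 200))
        assert np.array_equal(out, img[51:251, 37:237].astype(np.float32))

    def test_constant_box_stays_constant(self):
        img = np.full((300, 300), 77, dtype=np.uint8)
        out = crop_patch(img, BoundingBox(10, 10, 100, 100), (200, 200))
        assert out.shape == (200, 200)
        np.testing.assert_allclose(out, 77.0)

    def test_box_outside_image_rejected(self):
        img = np.zeros((50, 50), dtype=np.uint8)
        with pytest.raises(ValueError):
            crop_patch(img, BoundingBox(100, 100, 10, 10))

    def test_box_clipped_at_border(self):
        img = np.arange(2500, dtype=np.float64).reshape(50, 50)
        out = crop_patch(img, BoundingBox(-20, -20, 40, 40), (20, 20))
        assert out.shape == (20, 20)
        assert out[0, 0] == img[0, 0]


class TestSerialization:
    def records(self):
        return [
            ("img1", Candidate(BoundingBox(1, 2, 30, 40), 0.9, 0.8)),
            ("img2", Candidate(BoundingBox(5.5, 6.25, 10, 12), 0.7, None)),
        ]

    @pytest.mark.parametrize("save,load,ext", [
        (save_candidates_csv, load_candidates_csv, "csv"),
        (save_candidates_json, load_candidates_json, "json"),
    ])
    def test_roundtrip(self, tmp_path, save, load, ext):
        path = tmp_path / f"boxes.{ext}"
        save(path, self.records())
        back = load(path)
        for (id0, c0), (id1, c1) in zip(self.records(), back):
            assert id0 == id1
            assert c1.box == c0.box
            assert c1.degree == pytest.approx(c0.degree)
            assert c1.probability == c0.probability

    def test_center_format_flag(self, tmp_path):
        path = tmp_path / "boxes.csv"
        save_candidates_csv(path, [("a", Candidate(BoundingBox(10, 20, 30, 40)))])
        (_, cand), = load_candidates_csv(path, fmt="center")
        # (10, 20) reinterpreted as the box centre
        assert cand.box == BoundingBox.from_center(10, 20, 30, 40)

    def test_center_corner_conversion_lossless(self):
        b = BoundingBox(10, 20, 30, 40)
        assert BoundingBox.from_center(*b.center, b.w, b.h) == b
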