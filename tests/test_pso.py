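import numpy as np
import pytest

from mammocad.boxes import BoundingBox
from mammocad.pso import (
    MIN_BOX_SIZE,
    SwarmConfig,
    decode,
    encode,
    pso_refine,
    search_region,
)


def planted_box_fitness(target: BoundingBox, region: BoundingBox):
    """Smooth separable fitness peaking at the target box: 1 minus the mean
    normalized absolute coordinate error.  Defined on cropped patches is not
    needed here; the helper below adapts it to box coordinates."""
    span = np.array([region.w, region.h, region.w, region.h])
    tvec = np.array([*target.center, target.w, target.h])

    def fit_of_box(box: BoundingBox) -> float:
        v = np.array([*box.center, box.w, box.h])
        return float(max(0.0, 1.0 - np.abs((v - tvec) / span).mean()))

    return fit_of_box


class TestSearchRegion:
    def test_thirty_percent_expansion(self):
        region = search_region(BoundingBox(100, 100, 100, 100), 0.3)
        assert (region.x, region.y, region.w, region.h) == (70, 70, 160, 160)

    def test_zero_expansion_is_identity(self):
        b = BoundingBox(10, 20, 30, 40)
        assert search_region(b, 0.0) == b

    def test_clipped_to_image_at_corner(self):
        region = search_region(BoundingBox(0, 0, 100, 100), 0.3, image_size=(200, 150))
        assert region.x == 0 and region.y == 0
        assert region.x2 <= 200 and region.y2 <= 150


class TestEncodeDecode:
    def test_corner_to_center(self):
        assert np.array_equal(encode(BoundingBox(10, 20, 30, 40)), [25, 40, 30, 40])

    def test_roundtrip_identity(self, rng):
        for _ in range(100):
            b = BoundingBox(*rng.uniform(0, 100, 2), *rng.uniform(9, 60, 2))
            r = decode(encode(b))
            assert np.allclose([r.x, r.y, r.w, r.h], [b.x, b.y, b.w, b.h])

    def test_negative_width_clamped_to_minimum(self):
        b = decode(np.array([50.0, 50.0, -5.0, 30.0]))
        assert b.w == MIN_BOX_SIZE
        region = BoundingBox(0, 0, 100, 100)
        b2 = decode(np.array([500.0, -3.0, 20, 20]), region)
        assert b2.center[0] <= region.x2 and b2.center[1] >= region.y

    def test_decode_caps_size_to_region(self):
        region = BoundingBox(10, 10, 50, 40)
        b = decode(np.array([30.0, 30.0, 500.0, 500.0]), region)
        assert b.w == 50 and b.h == 40


def pso_refine_boxfit(image, rough, box_fit, cfg):
    """Drive pso_refine with a fitness defined on boxes rather than pixels.

    pso_refine evaluates fitness on cropped patches; for optimizer-quality
    tests the patch content is irrelevant, so cropping is intercepted to
    tag each patch with the decoded box it came from."""
    import mammocad.pso as pso_mod

    calls = {}
    original_crop = pso_mod.crop_patch

    def fake_crop(arr, box, size):
        key = len(calls)
        calls[key] = box
        out = np.empty((1, 1), dtype=np.float32)
        out[0, 0] = key
        return out

    pso_mod.crop_patch = fake_crop
    try:
        result = pso_mod.pso_refine(
            image, rough,
            fitness=lambda patch: box_fit(calls[int(patch[0, 0])]),
            config=cfg,
        )
    finally:
        pso_mod.crop_patch = original_crop
    return result


class TestPsoRefine:
    def test_constant_fitness_with_rough_init_never_moves(self):
        rough = BoundingBox(100, 100, 60, 60)
        cfg = SwarmConfig(seed=0, init="rough", early_stop_fitness=None)
        box, fit, trace = pso_refine_boxfit(
            np.zeros((300, 300)), rough, lambda b: 0.25, cfg
        )
        assert fit == 0.25
        assert (box.x, box.y, box.w, box.h) == (100, 100, 60, 60)
        assert trace == [0.25] * cfg.max_iterations

    def test_zero_social_terms_return_best_initial_position(self):
        rough = BoundingBox(100, 100, 60, 60)
        target = BoundingBox(120, 90, 70, 80)
        region = search_region(rough, 0.3)
        fit = planted_box_fitness(target, region)
        cfg = SwarmConfig(seed=3, cp=0.0, cg=0.0, init_velocity_frac=0.0,
                          early_stop_fitness=None)
        box, best, trace = pso_refine_boxfit(np.zeros((300, 300)), rough, fit, cfg)
        # replay the initial sampling: best of initial particles must equal output
        assert trace[-1] == best
        assert best == max(trace)
        assert trace == sorted(trace)  # non-decreasing

    def test_gbest_trace_non_decreasing_and_at_least_rough(self, rng):
        rough = BoundingBox(80, 90, 70, 60)
        target = BoundingBox(100, 100, 60, 50)
        region = search_region(rough, 0.3)
        fit = planted_box_fitness(target, region)
        for seed in range(5):
            cfg = SwarmConfig(seed=seed, early_stop_fitness=None)
            _, best, trace = pso_refine_boxfit(np.zeros((300, 300)), rough, fit, cfg)
            assert trace == sorted(trace)
            assert best >= fit(rough)

    def test_seeded_determinism(self):
        rough = BoundingBox(80, 90, 70, 60)
        target = BoundingBox(95, 80, 50, 70)
        region = search_region(rough, 0.3)
        fit = planted_box_fitness(target, region)
        cfg = SwarmConfig(seed=11, early_stop_fitness=None)
        r1 = pso_refine_boxfit(np.zeros((300, 300)), rough, fit, cfg)
        r2 = pso_refine_boxfit(np.zeros((300, 300)), rough, fit, cfg)
        assert r1[0] == r2[0] and r1[1] == r2[1] and r1[2] == r2[2]

    def test_finds_planted_box_close_to_grid_optimum(self):
        """20 particles x 20 iterations reach >= 95% of the per-coordinate
        1-px grid-search optimum of a separable fitness (median of seeds)."""
        rough = BoundingBox(100, 100, 100, 100)
        target = BoundingBox(125, 80, 80, 120)
        region = search_region(rough, 0.3)  # 160 x 160
        fit = planted_box_fitness(target, region)
        # separable fitness: the exhaustive 1-px grid optimum decomposes
        # per coordinate
        span = np.array([region.w, region.h, region.w, region.h])
        tvec = np.array([*target.center, target.w, target.h])
        grids = [
            np.arange(region.x, region.x2 + 1), np.arange(region.y, region.y2 + 1),
            np.arange(MIN_BOX_SIZE, region.w + 1), np.arange(MIN_BOX_SIZE, region.h + 1),
        ]
        err = sum(np.abs((g - t) / s).min() for g, t, s in zip(grids, tvec, span))
        grid_opt = 1.0 - err / 4.0
        ratios = []
        for seed in range(5):
            cfg = SwarmConfig(seed=seed, early_stop_fitness=None)
            _, best, _ = pso_refine_boxfit(np.zeros((300, 300)), rough, fit, cfg)
            ratios.append(best / grid_opt)
        assert np.median(ratios) >= 0.95

    def test_fitness_contract_violation_raises(self):
        rough = BoundingBox(100, 100, 60, 60)
        with pytest.raises(ValueError):
            pso_refine_boxfit(np.zeros((300, 300)), rough, lambda b: 1.5,
                              SwarmConfig(seed=0))

    def test_trace_csv_export(self, tmp_path):
        import mammocad.pso as pso_mod

        rough = BoundingBox(100, 100, 60, 60)
        target = BoundingBox(110, 95, 55, 70)
        region = search_region(rough, 0.3)
        fit = planted_box_fitness(target, region)
        cfg = SwarmConfig(seed=4, early_stop_fitness=None)

        calls = {}
        original_crop = pso_mod.crop_patch

        def fake_crop(arr, box, size):
            key = len(calls)
            calls[key] = box
            out = np.empty((1, 1), dtype=np.float32)
            out[0, 0] = key
            return out

        pso_mod.crop_patch = fake_crop
        try:
            _box, _fit, trace, state = pso_mod.pso_refine(
                np.zeros((300, 300)), rough,
                fitness=lambda patch: fit(calls[int(patch[0, 0])]),
                config=cfg, return_state=True,
            )
        finally:
            pso_mod.crop_patch = original_crop
        assert len(state.trace_boxes) == len(trace) == cfg.max_iterations
        path = tmp_path / "trace.csv"
        pso_mod.save_trace_csv(path, trace, state.trace_boxes)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration,gbest_fitness,x,y,w,h"
        assert len(lines) == cfg.max_iterations + 1

    def test_early_stop_pads_trace(self):
        rough = BoundingBox(100, 100, 60, 60)
        cfg = SwarmConfig(seed=0, init="rough", early_stop_fitness=0.999999)
        _, fit, trace = pso_refine_boxfit(np.zeros((300, 300)), rough,
                                          lambda b: 1.0, cfg)
        assert fit == 1.0
        assert trace == [1.0] * cfg.max_iterations
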