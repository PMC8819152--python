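"""Segmentation interface, overlap rates, and constrained copy-paste."""

import numpy as np
import pytest

from _oracles import pixel_overlap_rates
from psyllidet.augment import (
    InfeasiblePlacementError,
    PasteConfig,
    ThresholdSegmenter,
    copy_paste_augment,
    offline_resample,
    overlap_report,
    propose_paste_location,
    segment_foreground,
)
from psyllidet.boxes import Annotation, Box, DetectionDataset, ForegroundMask, Source
from psyllidet.synthetic import SceneConfig, generate_dataset


def random_mask_and_boxes(rng, size=32, n_boxes=3):
    mask = ForegroundMask(rng.random((size, size)) < 0.7)
    boxes = []
    for _ in range(n_boxes):
        w = int(rng.integers(1, 10))
        h = int(rng.integers(1, 10))
        x = int(rng.integers(0, size - w))
        y = int(rng.integers(0, size - h))
        boxes.append(Box(x, y, x + w, y + h))
    return mask, boxes


class TestSegmentation:
    def test_supplied_mask_passes_through(self, small_scene):
        image, mask, _ = small_scene
        out = segment_foreground(image, mask=mask)
        assert out == mask

    def test_uniform_green_is_all_inner(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[..., 1] = 200
        assert segment_foreground(img).area_inner == 16 * 16

    def test_uniform_black_is_all_outer(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        with pytest.warns(UserWarning, match="all-background"):
            out = segment_foreground(img)
        assert out.area_outer == 16 * 16

    def test_empty_image_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            segment_foreground(np.zeros((0, 0, 3), dtype=np.uint8))

    def test_default_segmenter_on_synthetic_canopy(self, small_scene):
        # canopy pixels are green-dominant and bright; the threshold rule
        # should recover most of the ground-truth foreground
        image, mask, _ = small_scene
        est = ThresholdSegmenter()(image)
        agreement = (est.values == mask.values).mean()
        assert agreement > 0.8


class TestOverlapReport:
    def test_inner_disjoint_box_has_zero_rates(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:35] = True
        rep = overlap_report(Box(10, 10, 20, 20), ForegroundMask(mask), [Box(25, 25, 30, 30)])
        assert rep.u_outer == 0.0 and rep.u_samples == 0.0

    def test_outer_rate_of_box_in_all_outer_mask(self):
        mask = ForegroundMask(np.zeros((100, 100), dtype=bool))
        rep = overlap_report(Box(0, 0, 10, 10), mask, [])
        assert rep.u_outer == pytest.approx(100 / 10000)
        assert rep.samples_undefined and rep.u_samples == 0.0

    def test_self_overlap_with_single_sample(self):
        mask = ForegroundMask(np.ones((50, 50), dtype=bool))
        b = Box(10, 10, 20, 20)
        rep = overlap_report(b, mask, [b])
        assert rep.u_samples == 1.0
        assert rep.outer_undefined and rep.u_outer == 0.0

    def test_matches_pixel_oracle_on_random_cases(self, rng):
        for _ in range(250):
            mask, boxes = random_mask_and_boxes(rng)
            w = int(rng.integers(1, 12))
            h = int(rng.integers(1, 12))
            x = int(rng.integers(0, 32 - w))
            y = int(rng.integers(0, 32 - h))
            copy_box = Box(x, y, x + w, y + h)
            rep = overlap_report(copy_box, mask, boxes)
            u_outer, u_samples = pixel_overlap_rates(copy_box, mask.values, boxes)
            assert rep.u_outer == pytest.approx(u_outer)
            assert rep.u_samples == pytest.approx(u_samples)
            assert (rep.u_outer == 0) == (u_outer == 0)
            assert (rep.u_samples == 0) == (u_samples == 0)


class TestProposePasteLocation:
    def test_unconstrained_case_succeeds_immediately(self, rng):
        mask = ForegroundMask(np.ones((64, 64), dtype=bool))
        box = propose_paste_location(Box(0, 0, 8, 8), mask, [], rng, max_attempts=1)
        assert box is not None and box.width == 8 and box.height == 8

    def test_all_outer_mask_is_guaranteed_failure(self, rng):
        mask = ForegroundMask(np.zeros((64, 64), dtype=bool))
        with pytest.raises(InfeasiblePlacementError):
            propose_paste_location(Box(0, 0, 8, 8), mask, [], rng)

    def test_inner_patch_smaller_than_sample_is_guaranteed_failure(self, rng):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:14, 10:14] = True  # 4x4 patch, 6x6 sample
        with pytest.raises(InfeasiblePlacementError):
            propose_paste_location(Box(0, 0, 6, 6), ForegroundMask(mask), [], rng)

    def test_outputs_verified_against_pixel_oracle(self):
        mask_arr = np.zeros((64, 64), dtype=bool)
        mask_arr[20:40, 20:40] = True  # single 20x20 inner patch
        mask = ForegroundMask(mask_arr)
        sample = Box(0, 0, 6, 6)
        existing = [Box(22, 22, 28, 28)]
        for seed in range(50):
            rng = np.random.default_rng(seed)
            box = propose_paste_location(sample, mask, existing, rng, max_attempts=500)
            if box is None:
                continue
            u_outer, u_samples = pixel_overlap_rates(box, mask_arr, existing)
            assert u_outer == 0.0 and u_samples == 0.0
            assert 0 <= box.x0 and box.x1 <= 64 and 0 <= box.y0 and box.y1 <= 64


class TestCopyPasteAugment:
    def test_zero_copies_is_identity(self, paste_scene, rng):
        image, mask, anns = paste_scene
        out_img, out_anns, reports, outcome = copy_paste_augment(
            image, anns, mask, PasteConfig(copies_per_image=0), rng
        )
        assert np.array_equal(out_img, image)
        assert out_anns == list(anns)
        assert reports == [] and outcome.successes == 0

    def test_pasted_boxes_satisfy_zero_overlap(self, paste_scene):
        image, mask, anns = paste_scene
        rng = np.random.default_rng(1)
        out_img, out_anns, reports, outcome = copy_paste_augment(
            image, anns, mask, PasteConfig(copies_per_image=10), rng
        )
        assert outcome.successes > 0
        assert len(out_anns) == len(anns) + outcome.successes
        assert all(r.u_outer == 0.0 and r.u_samples == 0.0 for r in reports)
        # independent oracle re-check, cumulative over the paste sequence
        existing = [a.box for a in anns]
        for a in out_anns[len(anns) :]:
            u_outer, u_samples = pixel_overlap_rates(a.box, mask.values, existing)
            assert u_outer == 0.0 and u_samples == 0.0
            assert a.source == Source.PASTED
            existing.append(a.box)

    def test_original_annotations_and_pixels_preserved(self, paste_scene):
        image, mask, anns = paste_scene
        rng = np.random.default_rng(2)
        out_img, out_anns, _, _ = copy_paste_augment(
            image, anns, mask, PasteConfig(copies_per_image=5), rng
        )
        assert out_anns[: len(anns)] == list(anns)
        untouched = np.ones(image.shape[:2], dtype=bool)
        for a in out_anns[len(anns) :]:
            untouched[a.box.y0 : a.box.y1, a.box.x0 : a.box.x1] = False
        assert np.array_equal(out_img[untouched], image[untouched])

    def test_deterministic_given_seed(self, paste_scene):
        image, mask, anns = paste_scene
        cfg = PasteConfig(copies_per_image=8)
        r1 = copy_paste_augment(image, anns, mask, cfg, np.random.default_rng(42))
        r2 = copy_paste_augment(image, anns, mask, cfg, np.random.default_rng(42))
        assert np.array_equal(r1[0], r2[0])
        assert r1[1] == r2[1]

    def test_min_targets_mode_fills_sparse_images(self, paste_scene):
        image, mask, anns = paste_scene
        rng = np.random.default_rng(3)
        _, out_anns, _, outcome = copy_paste_augment(
            image, anns, mask, PasteConfig(min_targets=10), rng
        )
        assert outcome.attempts == 10 - len(anns)
        assert len(out_anns) == len(anns) + outcome.successes

    def test_infeasible_scene_warns_and_returns_input(self):
        image = np.zeros((32, 32, 3), dtype=np.uint8)
        mask = ForegroundMask(np.zeros((32, 32), dtype=bool))
        anns = [Annotation(Box(0, 0, 8, 8), 0)]
        with pytest.warns(UserWarning, match="no valid paste"):
            out_img, out_anns, _, outcome = copy_paste_augment(
                image, anns, mask, PasteConfig(copies_per_image=3), np.random.default_rng(0)
            )
        assert np.array_equal(out_img, image) and out_anns == anns
        assert outcome.infeasible_failures == 3


class TestOfflineResample:
    def test_factor_one_is_fresh_identity(self, tmp_path):
        ds = generate_dataset(SceneConfig(width=96, height=96, seed=2), 4)
        out = offline_resample(ds, 1)
        assert len(out) == 4
        for a, b in zip(ds.records, out.records):
            assert a.annotations == b.annotations
            assert a.image is b.image  # same underlying pixels

    def test_factor_two_doubles_record_count(self):
        ds = generate_dataset(SceneConfig(width=96, height=96, seed=2), 10)
        assert len(offline_resample(ds, 2)) == 20

    def test_factor_three_triplicates_each_image(self):
        ds = generate_dataset(SceneConfig(width=96, height=96, seed=2), 7)
        out = offline_resample(ds, 3)
        assert len(out) == 21
        ids = [id(r.image) for r in out.records]
        for rec in ds.records:
            assert ids.count(id(rec.image)) == 3
        assert len({r.record_id for r in out.records}) == 21

    def test_invalid_factor_rejected(self):
        ds = generate_dataset(SceneConfig(width=96, height=96, seed=2), 1)
        with pytest.raises(ValueError):
            offline_resample(ds, 0)
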