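"""Matching, average precision, and mAP arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import greedy_match, threshold_enumeration_ap
from psyllidet.boxes import Annotation, Box, DatasetRecord, DetectionDataset, iou
from psyllidet.evaluation import (
    Detection,
    EvalSummary,
    PRCurve,
    UndefinedAPError,
    average_precision,
    evaluate,
    match_detections,
    mean_average_precision,
)


def det(x0, y0, x1, y1, score, image_id=0, class_id=0):
    return Detection(image_id, class_id, x0, y0, x1, y1, score)


class TestMatching:
    def test_exact_detections_all_true_positive(self):
        gts = [Box(0, 0, 10, 10), Box(20, 20, 40, 40)]
        dets = [det(0, 0, 10, 10, 0.9), det(20, 20, 40, 40, 0.8)]
        assert match_detections(dets, gts) == [True, True]

    def test_no_ground_truth_all_false_positive(self):
        dets = [det(0, 0, 10, 10, 0.9), det(5, 5, 15, 15, 0.3)]
        assert match_detections(dets, []) == [False, False]

    def test_each_ground_truth_consumed_once(self):
        gts = [Box(0, 0, 10, 10)]
        dets = [det(0, 0, 10, 10, 0.9), det(1, 1, 11, 11, 0.8)]
        assert match_detections(dets, gts) == [True, False]

    def test_crafted_overlaps_match_brute_force(self):
        gts = [Box(0, 0, 10, 10), Box(8, 0, 18, 10)]
        dets = [det(1, 0, 11, 10, 0.7), det(0, 0, 10, 10, 0.9), det(9, 0, 19, 10, 0.8)]
        labels = match_detections(dets, gts, 0.5)
        boxes = [Box(int(d.x0), int(d.y0), int(d.x1), int(d.y1)) for d in dets]
        expected = greedy_match(boxes, [d.score for d in dets], gts, iou, 0.5)
        assert labels == expected

    def test_random_instances_match_oracle(self, rng):
        for _ in range(100):
            n_gt = int(rng.integers(0, 5))
            n_det = int(rng.integers(0, 8))
            gts = []
            for _ in range(n_gt):
                x, y = int(rng.integers(0, 20)), int(rng.integers(0, 20))
                gts.append(Box(x, y, x + int(rng.integers(2, 10)), y + int(rng.integers(2, 10))))
            dets, boxes = [], []
            for _ in range(n_det):
                x, y = int(rng.integers(0, 20)), int(rng.integers(0, 20))
                b = Box(x, y, x + int(rng.integers(2, 10)), y + int(rng.integers(2, 10)))
                boxes.append(b)
                dets.append(det(b.x0, b.y0, b.x1, b.y1, float(np.round(rng.random(), 1))))
            got = match_detections(dets, gts, 0.4)
            want = greedy_match(boxes, [d.score for d in dets], gts, iou, 0.4)
            assert got == want


class TestAveragePrecision:
    def test_perfect_ranking_gives_unit_ap(self):
        curve = PRCurve.from_labels([0.9, 0.8, 0.7], [True, True, True], n_gt=3)
        assert average_precision(curve) == 1.0

    def test_single_false_positive_gives_zero(self):
        curve = PRCurve.from_labels([0.9], [False], n_gt=1)
        assert average_precision(curve) == 0.0

    def test_zero_ground_truth_raises_flagged_error(self):
        curve = PRCurve.from_labels([0.5], [False], n_gt=0)
        with pytest.raises(UndefinedAPError):
            average_precision(curve)

    def test_toy_staircase_matches_threshold_enumeration(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5]
        tp = [True, False, True, False, True]
        curve = PRCurve.from_labels(scores, tp, n_gt=3)
        assert average_precision(curve) == pytest.approx(
            threshold_enumeration_ap(scores, tp, 3)
        )

    @settings(max_examples=300, deadline=None)
    @given(
        n_det=st.integers(0, 10),
        n_gt=st.integers(1, 5),
        data=st.data(),
    )
    def test_matches_enumeration_oracle_on_random_instances(self, n_det, n_gt, data):
        # distinct scores: tie ordering is the ranker's documented choice
        # and is invisible to a score-threshold sweep
        scores = data.draw(
            st.lists(
                st.floats(0.01, 0.99, allow_nan=False),
                min_size=n_det,
                max_size=n_det,
                unique=True,
            )
        )
        n_tp = data.draw(st.integers(0, min(n_det, n_gt)))
        tp = [i < n_tp for i in range(n_det)]
        tp = data.draw(st.permutations(tp)) if n_det else []
        curve = PRCurve.from_labels(scores, tp, n_gt)
        assert average_precision(curve) == pytest.approx(
            threshold_enumeration_ap(scores, tp, n_gt)
        )

    def test_recall_is_monotone_along_ranking(self):
        curve = PRCurve.from_labels([0.9, 0.5, 0.7], [True, False, True], n_gt=4)
        r = curve.recall
        assert (np.diff(r) >= 0).all()
        assert ((curve.precision >= 0) & (curve.precision <= 1)).all()

    def test_extra_correct_detection_at_top_never_decreases_ap(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 9))
            scores = rng.random(n)
            tp = rng.random(n) < 0.5
            n_gt = max(1, int(tp.sum()) + int(rng.integers(0, 3)))
            before = average_precision(PRCurve.from_labels(scores, tp, n_gt + 1))
            after = average_precision(
                PRCurve.from_labels(
                    np.concatenate([[1.1], scores]), np.concatenate([[True], tp]), n_gt + 1
                )
            )
            assert after >= before - 1e-12


class TestMeanAveragePrecision:
    def test_two_class_mean(self):
        assert mean_average_precision([0.8878, 0.9164]) == pytest.approx(0.9021)
        assert mean_average_precision([0.674, 0.7848]) == pytest.approx(0.7294)

    def test_single_class_mean_is_identity(self):
        assert mean_average_precision({0: 0.42}) == pytest.approx(0.42)

    def test_permutation_invariance(self, rng):
        aps = list(rng.random(5))
        shuffled = list(rng.permutation(aps))
        assert mean_average_precision(aps) == pytest.approx(mean_average_precision(shuffled))

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            mean_average_precision([])


class TestEvaluate:
    @pytest.fixture
    def dataset(self):
        recs = [
            DatasetRecord(
                record_id=0, image=np.zeros((64, 64, 3), np.uint8), width=64, height=64,
                annotations=[
                    Annotation(Box(5, 5, 15, 15), 0),
                    Annotation(Box(30, 30, 50, 50), 1),
                ],
            ),
            DatasetRecord(
                record_id=1, image=np.zeros((64, 64, 3), np.uint8), width=64, height=64,
                annotations=[Annotation(Box(10, 10, 20, 20), 0)],
            ),
        ]
        return DetectionDataset(records=recs)

    def test_ground_truth_as_detections_scores_perfectly(self, dataset):
        dets = [
            det(*(a.box.x0, a.box.y0, a.box.x1, a.box.y1), 1.0, r.record_id, a.class_id)
            for r in dataset.records
            for a in r.annotations
        ]
        summary = evaluate(dataset, dets)
        assert summary.ap_per_class == {0: 1.0, 1: 1.0}
        assert summary.map == 1.0

    def test_empty_detections_score_zero(self, dataset):
        summary = evaluate(dataset, [])
        assert summary.ap_per_class == {0: 0.0, 1: 0.0} and summary.map == 0.0

    def test_planted_false_positives_match_hand_computation(self, dataset):
        dets = [
            det(5, 5, 15, 15, 0.9, 0, 0),     # TP
            det(40, 40, 60, 60, 0.8, 0, 0),   # FP (wrong place)
            det(10, 10, 20, 20, 0.7, 1, 0),   # TP
        ]
        summary = evaluate(dataset, dets)
        expected = threshold_enumeration_ap([0.9, 0.8, 0.7], [True, False, True], 2)
        assert summary.ap_per_class[0] == pytest.approx(expected)

    def test_unknown_category_is_named_in_error(self, dataset):
        with pytest.raises(ValueError, match="7"):
            evaluate(dataset, [det(0, 0, 5, 5, 0.5, 0, 7)])

    def test_class_without_ground_truth_excluded_with_warning(self):
        recs = [
            DatasetRecord(
                record_id=0, image=np.zeros((32, 32, 3), np.uint8), width=32, height=32,
                annotations=[Annotation(Box(1, 1, 9, 9), 0)],
            )
        ]
        ds = DetectionDataset(records=recs)
        with pytest.warns(UserWarning, match="no ground truths"):
            summary = evaluate(ds, [det(1, 1, 9, 9, 1.0, 0, 0)])
        assert summary.ap_per_class[1] is None
        assert summary.map == 1.0  # mean over the defined class only
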