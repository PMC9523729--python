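"""Detection metrics: IoU, greedy matching, recall/AP, counting error.

Brute-force oracles are reimplemented here from first principles (pixel-set
rasterization for IoU, explicit step-by-step enumeration for the matching
discipline) and compared against the library on small random instances.
"""

import math

import numpy as np
import pytest

from cpblend.annotations import BoundingBox
from cpblend.evaluation import (
    Detection,
    GroundTruth,
    count_rmse,
    evaluate,
    iou,
    match_detections,
)


def rasterized_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Oracle: count pixels of the two half-open boxes explicitly."""
    sa = {(x, y) for x in range(a.x_min, a.x_max) for y in range(a.y_min, a.y_max)}
    sb = {(x, y) for x in range(b.x_min, b.x_max) for y in range(b.y_min, b.y_max)}
    return len(sa & sb) / len(sa | sb)


def oracle_match(detections, ground_truth, threshold):
    """Oracle: literal re-enactment of the greedy discipline with dicts/loops."""
    order = sorted(range(len(detections)), key=lambda i: -detections[i].confidence)
    used = set()
    verdicts, matched_ious = [], []
    for i in order:
        det = detections[i]
        candidates = [
            (rasterized_iou(det.box, g.box), j)
            for j, g in enumerate(ground_truth)
            if j not in used and g.image_id == det.image_id
        ]
        best = max(candidates, default=(0.0, -1))
        if best[1] >= 0 and best[0] > threshold:
            used.add(best[1])
            verdicts.append(True)
            matched_ious.append(best[0])
        else:
            verdicts.append(False)
    tp = sum(verdicts)
    return tp, len(verdicts) - tp, len(ground_truth) - tp, verdicts, matched_ious


def random_instance(rng, max_boxes=6, extent=12):
    def rand_box():
        w = int(rng.integers(1, extent))
        h = int(rng.integers(1, extent))
        x = int(rng.integers(0, extent))
        y = int(rng.integers(0, extent))
        return BoundingBox(0, x, y, w, h)

    n_gt = int(rng.integers(1, max_boxes + 1))
    n_det = int(rng.integers(0, max_boxes + 1))
    gts = [GroundTruth("img", rand_box()) for _ in range(n_gt)]
    confs = rng.permutation(np.linspace(0.1, 0.9, n_det)) if n_det else []
    dets = [Detection("img", rand_box(), float(c)) for c in confs]
    return dets, gts


class TestIou:
    def test_identical_boxes(self):
        b = BoundingBox(0, 3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 0, 5, 5), BoundingBox(0, 10, 10, 5, 5)) == 0.0

    def test_known_overlap_one_third(self):
        a = BoundingBox(0, 0, 0, 2, 2)
        b = BoundingBox(0, 1, 0, 2, 2)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_matches_pixel_rasterization_oracle(self, rng):
        for _ in range(200):
            dets, gts = random_instance(rng, max_boxes=2)
            boxes = [d.box for d in dets] + [g.box for g in gts]
            for i in range(len(boxes)):
                for j in range(i, len(boxes)):
                    assert iou(boxes[i], boxes[j]) == pytest.approx(
                        rasterized_iou(boxes[i], boxes[j])
                    )
                    assert iou(boxes[i], boxes[j]) == iou(boxes[j], boxes[i])


class TestMatching:
    def test_perfect_detections(self):
        gts = [GroundTruth("i", BoundingBox(0, x, 0, 4, 4)) for x in (0, 10, 20)]
        dets = [Detection("i", g.box, 1.0) for g in gts]
        out = match_detections(dets, gts, 0.5)
        assert (out.tp, out.fp, out.fn) == (3, 0, 0)

    def test_no_detections(self):
        gts = [GroundTruth("i", BoundingBox(0, 0, 0, 4, 4))]
        out = match_detections([], gts, 0.5)
        assert (out.tp, out.fp, out.fn) == (0, 0, 1)

    def test_confidence_order_wins_over_iou(self):
        # two detections compete for one truth: the more confident one
        # (lower IoU 0.8) is processed first and takes it
        gt_box = BoundingBox(0, 0, 0, 10, 10)
        box_iou_09 = BoundingBox(0, 0, 0, 10, 9)  # IoU 0.9
        box_iou_08 = BoundingBox(0, 0, 0, 10, 8)  # IoU 0.8
        assert iou(gt_box, box_iou_09) == pytest.approx(0.9)
        assert iou(gt_box, box_iou_08) == pytest.approx(0.8)
        dets = [
            Detection("i", box_iou_09, 0.5),
            Detection("i", box_iou_08, 0.9),
        ]
        out = match_detections(dets, [GroundTruth("i", gt_box)], 0.5)
        assert out.tp == 1 and out.fp == 1
        assert out.matched_ious == [pytest.approx(0.8)]

    def test_greedy_equals_brute_force_on_random_instances(self, rng):
        for _ in range(150):
            dets, gts = random_instance(rng)
            for threshold in (0.25, 0.5, 0.75):
                out = match_detections(dets, gts, threshold)
                tp, fp, fn, verdicts, matched = oracle_match(dets, gts, threshold)
                assert (out.tp, out.fp, out.fn) == (tp, fp, fn)
                assert out.is_tp == verdicts
                assert out.matched_ious == pytest.approx(matched)

    def test_detections_never_cross_images(self):
        gts = [GroundTruth("a", BoundingBox(0, 0, 0, 4, 4))]
        dets = [Detection("b", BoundingBox(0, 0, 0, 4, 4), 1.0)]
        out = match_detections(dets, gts, 0.5)
        assert (out.tp, out.fp, out.fn) == (0, 1, 1)


class TestEvaluate:
    def test_perfect_detections_score_one_everywhere(self):
        gts = [GroundTruth("i", BoundingBox(0, 10 * k, 0, 6, 6)) for k in range(4)]
        dets = [Detection("i", g.box, 1.0) for g in gts]
        res = evaluate(dets, gts, thresholds=(0.5, 0.75))
        assert res.recall_at == {0.5: 1.0, 0.75: 1.0}
        assert res.ap_at == {0.5: 1.0, 0.75: 1.0}
        assert res.average_iou == 1.0

    def test_all_below_threshold(self):
        gts = [GroundTruth("i", BoundingBox(0, 0, 0, 10, 10))]
        dets = [Detection("i", BoundingBox(0, 9, 9, 10, 10), 0.8)]
        res = evaluate(dets, gts, thresholds=(0.5,))
        assert res.recall_at[0.5] == 0.0
        assert res.ap_at[0.5] == 0.0

    def test_toy_pr_curve_matches_hand_enumeration(self):
        # ranked verdicts: TP, FP, TP over 2 truths
        # precision 1, 1/2, 2/3; recall 1/2, 1/2, 1
        # all-point AP = 0.5*1 + 0.5*(2/3) = 5/6
        gts = [
            GroundTruth("i", BoundingBox(0, 0, 0, 10, 10)),
            GroundTruth("i", BoundingBox(0, 20, 20, 10, 10)),
        ]
        dets = [
            Detection("i", BoundingBox(0, 0, 0, 10, 10), 0.9),
            Detection("i", BoundingBox(0, 40, 40, 10, 10), 0.8),
            Detection("i", BoundingBox(0, 20, 20, 10, 10), 0.7),
        ]
        res = evaluate(dets, gts, thresholds=(0.5,))
        assert res.recall_at[0.5] == 1.0
        assert res.ap_at[0.5] == pytest.approx(5 / 6)
        assert res.average_iou == 1.0

    def test_recall_and_ap_monotone_in_threshold(self, rng):
        for _ in range(30):
            dets, gts = random_instance(rng)
            res = evaluate(dets, gts, thresholds=(0.3, 0.5, 0.7, 0.9))
            rs = [res.recall_at[t] for t in (0.3, 0.5, 0.7, 0.9)]
            aps = [res.ap_at[t] for t in (0.3, 0.5, 0.7, 0.9)]
            assert all(a >= b - 1e-12 for a, b in zip(rs, rs[1:]))
            assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))

    def test_permutation_invariance_at_distinct_confidences(self, rng):
        dets, gts = random_instance(rng, max_boxes=5)
        if not dets:
            dets = [Detection("img", gts[0].box, 0.5)]
        res_a = evaluate(dets, gts, thresholds=(0.5,))
        shuffled = [dets[i] for i in rng.permutation(len(dets))]
        res_b = evaluate(shuffled, gts, thresholds=(0.5,))
        assert res_a.recall_at == res_b.recall_at
        assert res_a.ap_at == res_b.ap_at
        assert res_a.average_iou == pytest.approx(res_b.average_iou)

    def test_average_iou_exceeds_half_when_tp_positive(self, rng):
        seen_tp = 0
        for _ in range(100):
            dets, gts = random_instance(rng)
            res = evaluate(dets, gts, thresholds=(0.5,))
            if res.tp[0.5] > 0:
                seen_tp += 1
                assert res.average_iou >= 0.5
        assert seen_tp > 0

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="ground truth"):
            evaluate([], [], thresholds=(0.5,))

    def test_eleven_point_ap_close_to_all_point_for_perfect(self):
        gts = [GroundTruth("i", BoundingBox(0, 0, 0, 5, 5))]
        dets = [Detection("i", gts[0].box, 1.0)]
        res = evaluate(dets, gts, thresholds=(0.5,), eleven_point_ap=True)
        assert res.ap_at[0.5] == pytest.approx(1.0)


class TestCountRmse:
    @pytest.mark.parametrize(
        "pred, true, expected",
        [
            ([4, 2, 7], [4, 2, 7], 0.0),
            ([0], [3], 3.0),
            ([1, 2, 3], [2, 4, 3], math.sqrt(5 / 3)),
        ],
    )
    def test_examples(self, pred, true, expected):
        assert count_rmse(pred, true) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            count_rmse([1, 2], [1])
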