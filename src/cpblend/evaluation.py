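"""IoU-based detection evaluation: recall at IoU thresholds, average IoU,
average precision, and counting error.

Matching follows the greedy confidence-ordered VOC discipline used by the
Darknet evaluators: per image, detections are processed in descending
confidence (ties by insertion order); each detection is matched to the
still-unmatched ground-truth box of highest IoU and counts as a true
positive iff that IoU is strictly greater than the threshold, otherwise as
a false positive.  Each ground truth matches at most once; unmatched ground
truths are false negatives.

``average_iou`` is the mean IoU over the matched (TP) pairs at the 0.50
threshold — a test-time matched-pair mean, which proxies how precisely the
boxes are drawn.  AP is the area under the all-point interpolated
precision-recall curve (VOC2010 style); an 11-point variant is available
for comparison with older protocols.
"""

from __future__ import annotations

import csv
import io
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .annotations import BoundingBox


@dataclass(frozen=True)
class Detection:
    """One detector output: a box with a confidence on a named image."""

    image_id: str
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    image_id: str
    box: BoundingBox


@dataclass
class EvalResult:
    """Detection metrics at each requested IoU threshold."""

    recall_at: dict[float, float] = field(default_factory=dict)
    ap_at: dict[float, float] = field(default_factory=dict)
    average_iou: float = 0.0
    tp: dict[float, int] = field(default_factory=dict)
    fp: dict[float, int] = field(default_factory=dict)
    fn: dict[float, int] = field(default_factory=dict)

    def to_json(self) -> str:
        def keyed(d: dict[float, object]) -> dict[str, object]:
            return {f"{t:.2f}": v for t, v in d.items()}

        return json.dumps(
            {
                "recall_at": keyed(self.recall_at),
                "ap_at": keyed(self.ap_at),
                "average_iou": self.average_iou,
                "tp": keyed(self.tp),
                "fp": keyed(self.fp),
                "fn": keyed(self.fn),
            },
            indent=1,
        )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes under the half-open convention."""
    if a.area == 0 or b.area == 0:
        raise ValueError("zero-area box")
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass
class MatchOutcome:
    """Per-detection verdicts (aligned with the confidence-ranked order)
    plus the matched-pair IoUs and the FN count."""

    is_tp: list[bool]
    confidences: list[float]
    matched_ious: list[float]
    n_gt: int

    @property
    def tp(self) -> int:
        return sum(self.is_tp)

    @property
    def fp(self) -> int:
        return len(self.is_tp) - self.tp

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp


def match_detections(
    detections: Sequence[Detection],
    ground_truth: Sequence[GroundTruth],
    threshold: float,
) -> MatchOutcome:
    """Greedy confidence-ordered matching of detections to ground truth."""
    gt_by_image: dict[str, list[GroundTruth]] = {}
    for g in ground_truth:
        gt_by_image.setdefault(g.image_id, []).append(g)
    matched: dict[str, list[bool]] = {
        k: [False] * len(v) for k, v in gt_by_image.items()
    }

    order = sorted(
        range(len(detections)), key=lambda i: -detections[i].confidence
    )  # stable: ties keep insertion order
    is_tp: list[bool] = []
    confidences: list[float] = []
    matched_ious: list[float] = []
    for i in order:
        det = detections[i]
        confidences.append(det.confidence)
        gts = gt_by_image.get(det.image_id, [])
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if matched[det.image_id][j]:
                continue
            v = iou(det.box, g.box)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou > threshold:
            matched[det.image_id][best_j] = True
            is_tp.append(True)
            matched_ious.append(best_iou)
        else:
            is_tp.append(False)
    return MatchOutcome(
        is_tp=is_tp,
        confidences=confidences,
        matched_ious=matched_ious,
        n_gt=len(ground_truth),
    )


def _ap_from_ranked(is_tp: Sequence[bool], n_gt: int, eleven_point: bool) -> float:
    """Area under the precision-recall curve of a confidence-ranked list."""
    if n_gt == 0:
        return 0.0
    precisions, recalls = [], []
    tp = 0
    for rank, hit in enumerate(is_tp, start=1):
        tp += int(hit)
        precisions.append(tp / rank)
        recalls.append(tp / n_gt)
    if eleven_point:
        total = 0.0
        for r in [i / 10 for i in range(11)]:
            pmax = max(
                (p for p, rc in zip(precisions, recalls) if rc >= r), default=0.0
            )
            total += pmax / 11
        return total
    # all-point interpolation: p_interp(r) = max precision at recall >= r,
    # i.e. the suffix-max envelope evaluated where recall first increases
    envelope = [0.0] * len(precisions)
    running = 0.0
    for k in range(len(precisions) - 1, -1, -1):
        running = max(running, precisions[k])
        envelope[k] = running
    ap = 0.0
    prev_recall = 0.0
    for k in range(len(recalls)):
        if recalls[k] > prev_recall:
            ap += (recalls[k] - prev_recall) * envelope[k]
            prev_recall = recalls[k]
    return ap


def evaluate(
    detections: Sequence[Detection],
    ground_truth: Sequence[GroundTruth],
    thresholds: Sequence[float] = (0.50, 0.75),
    eleven_point_ap: bool = False,
) -> EvalResult:
    """Score detections against ground truth at the given IoU thresholds."""
    if not ground_truth:
        raise ValueError("empty ground truth: recall undefined")
    for t in thresholds:
        if not 0.0 < t < 1.0:
            raise ValueError(f"threshold {t} outside (0, 1)")

    result = EvalResult()
    for t in thresholds:
        outcome = match_detections(detections, ground_truth, t)
        denom = outcome.tp + outcome.fn
        if denom == 0:
            warnings.warn("0/0 recall defined as 0", stacklevel=2)
            recall = 0.0
        else:
            recall = outcome.tp / denom
        result.recall_at[t] = recall
        result.ap_at[t] = _ap_from_ranked(
            outcome.is_tp, outcome.n_gt, eleven_point_ap
        )
        result.tp[t], result.fp[t], result.fn[t] = (
            outcome.tp,
            outcome.fp,
            outcome.fn,
        )

    at50 = match_detections(detections, ground_truth, 0.50)
    result.average_iou = (
        sum(at50.matched_ious) / len(at50.matched_ious) if at50.matched_ious else 0.0
    )
    return result


def count_rmse(predicted_counts: Sequence[float], true_counts: Sequence[float]) -> float:
    """Root-mean-square error between per-image object counts."""
    if len(predicted_counts) != len(true_counts):
        raise ValueError(
            f"length mismatch: {len(predicted_counts)} vs {len(true_counts)}"
        )
    if not predicted_counts:
        return 0.0
    sq = [(p - t) ** 2 for p, t in zip(predicted_counts, true_counts)]
    return math.sqrt(sum(sq) / len(sq))


def read_detections_csv(text: str) -> list[Detection]:
    """Parse a detections file: CSV with header
    ``image_id,class_id,confidence,x_min,y_min,width,height`` (pixels)."""
    reader = csv.DictReader(io.StringIO(text))
    required = {
        "image_id", "class_id", "confidence", "x_min", "y_min", "width", "height",
    }
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValueError(f"detections CSV must have columns {sorted(required)}")
    out = []
    for row in reader:
        out.append(
            Detection(
                image_id=row["image_id"],
                box=BoundingBox(
                    int(row["class_id"]),
                    int(row["x_min"]),
                    int(row["y_min"]),
                    int(row["width"]),
                    int(row["height"]),
                ),
                confidence=float(row["confidence"]),
            )
        )
    return out
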