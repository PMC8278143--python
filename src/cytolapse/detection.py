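"""Detection-quality scoring: matching, confusion, P/R/F1, AP and mAP.

The metrics follow the standard object-detection conventions.  A prediction
is a true positive when it overlaps an unmatched ground-truth box with IoU at
or above the threshold (and, where class-aware, carries the right class);
matching is greedy over predictions in descending confidence.  The average
precision (AP) of a class is the area under the interpolated precision-recall
curve; AP-bar averages AP over the IoU sweep 0.50:0.05:0.95 and the mAP is
the mean of AP-bar over the classes present in the ground truth.  mAP is
reported in percent.

Two interpolation schemes are available: the all-point precision-envelope
integral (default, as used with COCO-style evaluation) and the older 11-point
average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotations import (
    CLASS_ORDER,
    Box,
    CellClass,
    FrameAnnotation,
    VideoAnnotation,
)

__all__ = [
    "DEFAULT_IOU_SWEEP",
    "iou",
    "MatchPair",
    "MatchResult",
    "match_frame",
    "ClassScore",
    "ClassScores",
    "classification_scores",
    "f1_score",
    "APResult",
    "average_precision",
    "ap_bar",
    "map_score",
    "per_frame_report",
]

#: IoU thresholds 0.50, 0.55, ..., 0.95.
DEFAULT_IOU_SWEEP: tuple[float, ...] = tuple(
    float(x) for x in np.round(np.arange(0.50, 0.96, 0.05), 2)
)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 iff identical."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class MatchPair:
    gt_index: int
    pred_index: int
    iou: float
    gt_cls: CellClass
    pred_cls: CellClass


@dataclass
class MatchResult:
    """One-to-one assignment between a frame's ground truth and predictions."""

    pairs: list[MatchPair]
    unmatched_gt: list[int]
    unmatched_pred: list[int]
    gt_classes: list[CellClass]
    pred_classes: list[CellClass]
    iou_threshold: float
    class_aware: bool


def match_frame(
    gt: FrameAnnotation,
    pred: FrameAnnotation,
    iou_threshold: float = 0.5,
    class_aware: bool = True,
) -> MatchResult:
    """Greedily match predictions to ground truth on one frame.

    Predictions are visited in descending confidence (ties broken by input
    order); each takes the unmatched ground-truth box of highest IoU at or
    above ``iou_threshold`` (same class required when ``class_aware``).
    Remaining ground truth are false negatives, remaining predictions false
    positives.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    if gt.frame_index != pred.frame_index:
        raise ValueError(
            f"frame mismatch: gt {gt.frame_index} vs pred {pred.frame_index}"
        )
    order = sorted(
        range(len(pred.objects)), key=lambda i: (-pred.objects[i].confidence, i)
    )
    taken = [False] * len(gt.objects)
    pairs: list[MatchPair] = []
    unmatched_pred: list[int] = []
    for pi in order:
        p = pred.objects[pi]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gt.objects):
            if taken[j]:
                continue
            if class_aware and g.cls is not p.cls:
                continue
            v = iou(g.box, p.box)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            pairs.append(
                MatchPair(best_j, pi, best_iou, gt.objects[best_j].cls, p.cls)
            )
        else:
            unmatched_pred.append(pi)
    unmatched_gt = [j for j, t in enumerate(taken) if not t]
    return MatchResult(
        pairs=pairs,
        unmatched_gt=unmatched_gt,
        unmatched_pred=sorted(unmatched_pred),
        gt_classes=[o.cls for o in gt.objects],
        pred_classes=[o.cls for o in pred.objects],
        iou_threshold=iou_threshold,
        class_aware=class_aware,
    )


def f1_score(precision: float, recall: float) -> Optional[float]:
    """Harmonic mean of precision and recall; None when both are zero."""
    if precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ClassScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d > 0 else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d > 0 else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None:
            return None
        return f1_score(p, r)


@dataclass
class ClassScores:
    """Per-class detection/classification scores plus a confusion matrix.

    ``confusion`` counts matched pairs (true class x predicted class) in the
    order liv, round, div, dead.  The per-class precision/recall/F1 treat a
    cross-class match as a false positive of the predicted class and a false
    negative of the true class.  ``mean_*`` average the defined per-class
    values.
    """

    per_class: dict[CellClass, ClassScore]
    confusion: pd.DataFrame

    def _mean(self, attr: str) -> Optional[float]:
        vals = [
            getattr(s, attr)
            for s in self.per_class.values()
            if getattr(s, attr) is not None
        ]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_precision(self) -> Optional[float]:
        return self._mean("precision")

    @property
    def mean_recall(self) -> Optional[float]:
        return self._mean("recall")

    @property
    def mean_f1(self) -> Optional[float]:
        return self._mean("f1")


def classification_scores(matches: Union[MatchResult, Iterable[MatchResult]]) -> ClassScores:
    """Aggregate one or more class-agnostic match results into scores.

    Matching should be run with ``class_aware=False`` so that cross-class
    pairs land in the off-diagonal of the confusion matrix.
    """
    if isinstance(matches, MatchResult):
        matches = [matches]
    names = [c.value for c in CLASS_ORDER]
    confusion = pd.DataFrame(
        np.zeros((4, 4), dtype=int), index=names, columns=names
    )
    tp = {c: 0 for c in CLASS_ORDER}
    fp = {c: 0 for c in CLASS_ORDER}
    fn = {c: 0 for c in CLASS_ORDER}
    for m in matches:
        for pair in m.pairs:
            confusion.loc[pair.gt_cls.value, pair.pred_cls.value] += 1
            if pair.gt_cls is pair.pred_cls:
                tp[pair.gt_cls] += 1
            else:
                fp[pair.pred_cls] += 1
                fn[pair.gt_cls] += 1
        for j in m.unmatched_gt:
            fn[m.gt_classes[j]] += 1
        for i in m.unmatched_pred:
            fp[m.pred_classes[i]] += 1
    per_class = {c: ClassScore(tp[c], fp[c], fn[c]) for c in CLASS_ORDER}
    confusion.index.name = "true"
    confusion.columns.name = "predicted"
    return ClassScores(per_class=per_class, confusion=confusion)


# ---------------------------------------------------------------------------
# Average precision

FrameSet = Union[FrameAnnotation, Sequence[FrameAnnotation], VideoAnnotation]


def _as_frames(x: FrameSet) -> list[FrameAnnotation]:
    if isinstance(x, VideoAnnotation):
        return list(x.frames)
    if isinstance(x, FrameAnnotation):
        return [x]
    return list(x)


@dataclass
class APResult:
    cls: CellClass
    iou_threshold: float
    pr_points: list[tuple[float, float]]  # (recall, precision), score order
    ap: float
    n_gt: int


def _class_detections(
    gt_frames: list[FrameAnnotation], pred_frames: list[FrameAnnotation], cls: CellClass
):
    """Pool class detections over frames and precompute GT IoU rows.

    Returns (n_gt, detections) where each detection is
    (confidence, frame_key, iou_row) with iou_row over that frame's GT boxes
    of the class.
    """
    gt_by_frame: dict[int, list] = {}
    for f in gt_frames:
        gt_by_frame[f.frame_index] = [o.box for o in f.objects if o.cls is cls]
    n_gt = sum(len(v) for v in gt_by_frame.values())
    detections = []
    for f in pred_frames:
        gt_boxes = gt_by_frame.get(f.frame_index, [])
        for o in f.objects:
            if o.cls is not cls:
                continue
            row = np.array([iou(g, o.box) for g in gt_boxes])
            detections.append((o.confidence, f.frame_index, row))
    # Descending confidence; ties by frame then arrival order (stable sort).
    detections.sort(key=lambda d: -d[0])
    return n_gt, gt_by_frame, detections


def _pr_curve(n_gt: int, gt_by_frame, detections, iou_threshold: float):
    matched = {fi: np.zeros(len(boxes), dtype=bool) for fi, boxes in gt_by_frame.items()}
    tps = np.zeros(len(detections), dtype=bool)
    for k, (_conf, fi, row) in enumerate(detections):
        if row.size == 0:
            continue
        free = ~matched[fi]
        cand = np.where(free & (row >= iou_threshold))[0]
        if cand.size:
            j = cand[np.argmax(row[cand])]
            matched[fi][j] = True
            tps[k] = True
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(~tps)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1)
    return recall, precision


def _integrate(recall: np.ndarray, precision: np.ndarray, interpolation: str) -> float:
    if recall.size == 0:
        return 0.0
    if interpolation == "envelope":
        # All-point interpolation: precision envelope over recall.
        r = np.concatenate(([0.0], recall, [recall[-1]]))
        p = np.concatenate(([0.0], precision, [0.0]))
        for i in range(p.size - 2, -1, -1):
            p[i] = max(p[i], p[i + 1])
        idx = np.where(r[1:] != r[:-1])[0]
        return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))
    if interpolation == "11point":
        levels = np.linspace(0.0, 1.0, 11)
        vals = []
        for lv in levels:
            mask = recall >= lv - 1e-12
            vals.append(float(precision[mask].max()) if mask.any() else 0.0)
        return float(np.mean(vals))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def average_precision(
    gt: FrameSet,
    preds: FrameSet,
    cls: CellClass,
    iou_threshold: float = 0.5,
    interpolation: str = "envelope",
) -> Optional[APResult]:
    """AP of one class at one IoU threshold; None when the class is absent
    from the ground truth."""
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    gt_frames, pred_frames = _as_frames(gt), _as_frames(preds)
    n_gt, gt_by_frame, detections = _class_detections(gt_frames, pred_frames, cls)
    if n_gt == 0:
        return None
    recall, precision = _pr_curve(n_gt, gt_by_frame, detections, iou_threshold)
    ap = _integrate(recall, precision, interpolation)
    return APResult(
        cls=cls,
        iou_threshold=iou_threshold,
        pr_points=list(zip(recall.tolist(), precision.tolist())),
        ap=ap,
        n_gt=n_gt,
    )


def ap_bar(
    gt: FrameSet,
    preds: FrameSet,
    cls: CellClass,
    iou_thresholds: Sequence[float] = DEFAULT_IOU_SWEEP,
    interpolation: str = "envelope",
) -> Optional[float]:
    """Mean AP over the IoU sweep; None when the class is absent from GT."""
    gt_frames, pred_frames = _as_frames(gt), _as_frames(preds)
    n_gt, gt_by_frame, detections = _class_detections(gt_frames, pred_frames, cls)
    if n_gt == 0:
        return None
    aps = []
    for thr in iou_thresholds:
        recall, precision = _pr_curve(n_gt, gt_by_frame, detections, thr)
        aps.append(_integrate(recall, precision, interpolation))
    return float(np.mean(aps))


def map_score(
    gt: FrameSet,
    preds: FrameSet,
    scope: str = "pooled",
    iou_thresholds: Sequence[float] = DEFAULT_IOU_SWEEP,
    absent_class: str = "exclude",
    interpolation: str = "envelope",
) -> Union[float, pd.Series]:
    """mAP in percent: mean of per-class AP-bar.

    ``scope="pooled"`` pools all frames and returns one number;
    ``scope="frame"`` scores each frame separately and returns a
    pandas Series indexed by frame.  ``absent_class`` selects how classes
    with no ground-truth instance enter the mean: ``"exclude"`` (default)
    drops them, ``"zero"`` scores them 0 — most frames contain no dividing
    cell, and a forced zero would dominate the mean unfairly.
    """
    if scope not in ("pooled", "frame"):
        raise ValueError(f"scope must be 'pooled' or 'frame', got {scope!r}")
    if absent_class not in ("exclude", "zero"):
        raise ValueError(f"absent_class must be 'exclude' or 'zero', got {absent_class!r}")
    gt_frames, pred_frames = _as_frames(gt), _as_frames(preds)
    if scope == "frame":
        pred_by_index = {f.frame_index: f for f in pred_frames}
        out = {}
        for f in gt_frames:
            p = pred_by_index.get(
                f.frame_index,
                FrameAnnotation(f.frame_index, f.time_min, [], f.image_size),
            )
            out[f.frame_index] = map_score(
                f, p, "pooled", iou_thresholds, absent_class, interpolation
            )
        return pd.Series(out, name="map_percent")
    values = []
    for cls in CLASS_ORDER:
        v = ap_bar(gt_frames, pred_frames, cls, iou_thresholds, interpolation)
        if v is None:
            if absent_class == "zero":
                values.append(0.0)
            continue
        values.append(v)
    if not values:
        raise ValueError("no ground-truth objects in scope; mAP undefined")
    return float(np.mean(values)) * 100.0


def per_frame_report(
    gt: VideoAnnotation,
    preds: VideoAnnotation,
    iou_thresholds: Sequence[float] = DEFAULT_IOU_SWEEP,
    absent_class: str = "exclude",
    interpolation: str = "envelope",
    stride: int = 1,
) -> pd.DataFrame:
    """Per-frame evaluation table: counts, per-class AP-bar and mAP (%).

    ``stride`` scores every ``stride``-th frame, which keeps long videos
    cheap to evaluate.
    """
    pred_by_index = {f.frame_index: f for f in preds.frames}
    rows = []
    for f in gt.frames[::stride]:
        p = pred_by_index.get(
            f.frame_index, FrameAnnotation(f.frame_index, f.time_min, [], f.image_size)
        )
        row: dict = {"frame": f.frame_index, "time_min": f.time_min}
        for cls in CLASS_ORDER:
            row[f"n_gt_{cls.value}"] = f.count(cls)
            row[f"n_pred_{cls.value}"] = p.count(cls)
        for cls in CLASS_ORDER:
            v = ap_bar(f, p, cls, iou_thresholds, interpolation)
            row[f"ap_bar_{cls.value}"] = np.nan if v is None else v
        n_gt_total = len(f.objects)
        row["n_gt_total"] = n_gt_total
        row["n_pred_total"] = len(p.objects)
        row["map_percent"] = (
            map_score(f, p, "pooled", iou_thresholds, absent_class, interpolation)
            if n_gt_total
            else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
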