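"""Detection scoring: IoU, matching, P/R/F1, AP and mAP."""

import itertools

import numpy as np
import pytest

from cytolapse.annotations import (
    CLASS_ORDER,
    Box,
    CellClass,
    FrameAnnotation,
    LabelledObject,
)
from cytolapse.detection import (
    DEFAULT_IOU_SWEEP,
    ap_bar,
    average_precision,
    classification_scores,
    f1_score,
    iou,
    map_score,
    match_frame,
    per_frame_report,
)
from cytolapse.simulate import apply_detector_noise, mild_noise, simulate_population

from conftest import make_box


def _obj(x0, y0, x1, y1, cls=CellClass.LIV, conf=1.0):
    return LabelledObject(Box(x0, y0, x1, y1), cls, conf)


def _frame(objects, index=1):
    return FrameAnnotation(index, index * 5.0, objects)


class TestIoU:
    def test_identical(self):
        b = Box(3, 4, 13, 24)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(Box(0, 0, 10, 10), Box(20, 0, 30, 10)) == 0.0

    def test_half_overlap_arithmetic(self):
        # intersection 50, union 150
        assert iou(Box(0, 0, 10, 10), Box(5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_symmetry_on_random_boxes(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b = make_box(rng), make_box(rng)
            assert iou(a, b) == pytest.approx(iou(b, a))
            assert 0.0 <= iou(a, b) <= 1.0


def brute_force_greedy(gt, pred, thr, class_aware):
    """Independent oracle: walk predictions in confidence order, each taking
    the best remaining ground-truth box, computed by explicit enumeration of
    the candidate set at each step."""
    order = sorted(range(len(pred)), key=lambda i: (-pred[i].confidence, i))
    available = set(range(len(gt)))
    pairs = []
    for pi in order:
        candidates = [
            (iou(gt[j].box, pred[pi].box), -j, j)
            for j in sorted(available)
            if iou(gt[j].box, pred[pi].box) >= thr
            and (not class_aware or gt[j].cls is pred[pi].cls)
        ]
        if candidates:
            _, _, j = max(candidates)
            available.discard(j)
            pairs.append((j, pi))
    return pairs


class TestMatchFrame:
    def test_perfect_predictions_fully_matched(self):
        rng = np.random.default_rng(0)
        objs = [_obj(*(-1, -1, 1, 1))]  # replaced below
        objs = [
            LabelledObject(make_box(rng), CLASS_ORDER[k % 4], 1.0) for k in range(8)
        ]
        gt = _frame(objs)
        pred = _frame(list(objs))
        m = match_frame(gt, pred, 0.9, class_aware=True)
        assert len(m.pairs) == 8 and not m.unmatched_gt and not m.unmatched_pred

    def test_empty_predictions_all_fn(self):
        gt = _frame([_obj(0, 0, 10, 10), _obj(20, 0, 30, 10)])
        m = match_frame(gt, _frame([]), 0.5)
        assert m.unmatched_gt == [0, 1] and not m.pairs and not m.unmatched_pred

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            match_frame(_frame([]), _frame([]), 0.0)

    @pytest.mark.parametrize("class_aware", [True, False])
    def test_agrees_with_enumeration_oracle(self, class_aware):
        rng = np.random.default_rng(17)
        for trial in range(40):
            n_gt = int(rng.integers(1, 6))
            n_pred = int(rng.integers(1, 6))
            field = (60, 60)  # small field forces overlaps
            gt = [
                LabelledObject(make_box(rng, field), CLASS_ORDER[int(rng.integers(4))], 1.0)
                for _ in range(n_gt)
            ]
            pred = [
                LabelledObject(
                    make_box(rng, field),
                    CLASS_ORDER[int(rng.integers(4))],
                    float(np.round(rng.uniform(0, 1), 6)),
                )
                for _ in range(n_pred)
            ]
            thr = float(rng.uniform(0.1, 0.6))
            m = match_frame(_frame(gt), _frame(pred), thr, class_aware)
            expected = brute_force_greedy(gt, pred, thr, class_aware)
            assert sorted((p.gt_index, p.pred_index) for p in m.pairs) == sorted(
                expected
            )


class TestClassificationScores:
    def test_f1_is_harmonic_mean(self):
        assert f1_score(0.90, 0.98) == pytest.approx(0.94, abs=0.005)
        assert f1_score(0.5, 0.5) == pytest.approx(0.5)  # p == r -> f1 == p
        assert f1_score(0.0, 0.0) is None

    def test_benchmark_score_table_mean(self):
        # Reference per-class precision/recall of a four-class cell
        # classifier; the mean F1 over classes rounds to 0.93.
        table = {
            "dead": (0.96, 0.95),
            "div": (0.90, 0.98),
            "liv": (0.97, 0.96),
            "round": (0.87, 0.87),
        }
        f1s = {k: f1_score(p, r) for k, (p, r) in table.items()}
        assert round(f1s["dead"], 2) == 0.95
        assert round(f1s["div"], 2) == 0.94
        assert round(f1s["liv"], 2) == 0.96
        assert round(f1s["round"], 2) == 0.87
        assert round(float(np.mean(list(f1s.values()))), 2) == 0.93

    def test_cross_class_match_fills_confusion(self):
        gt = _frame([_obj(0, 0, 10, 10, CellClass.ROUND)])
        pred = _frame([_obj(0, 0, 10, 10, CellClass.LIV, 0.9)])
        m = match_frame(gt, pred, 0.5, class_aware=False)
        scores = classification_scores(m)
        assert scores.confusion.loc["round", "liv"] == 1
        assert scores.per_class[CellClass.LIV].fp == 1
        assert scores.per_class[CellClass.ROUND].fn == 1
        assert scores.per_class[CellClass.ROUND].tp == 0

    def test_perfect_match_diagonal(self):
        rng = np.random.default_rng(2)
        objs = [
            LabelledObject(make_box(rng), CLASS_ORDER[k % 4], 1.0) for k in range(12)
        ]
        m = match_frame(_frame(objs), _frame(list(objs)), 0.5, class_aware=False)
        scores = classification_scores(m)
        assert np.trace(scores.confusion.to_numpy()) == 12
        assert scores.mean_f1 == pytest.approx(1.0)
        assert scores.per_class[CellClass.LIV].precision == 1.0

    def test_empty_class_reported_absent(self):
        gt = _frame([_obj(0, 0, 10, 10, CellClass.LIV)])
        pred = _frame([_obj(0, 0, 10, 10, CellClass.LIV, 0.9)])
        scores = classification_scores(match_frame(gt, pred, 0.5, class_aware=False))
        assert scores.per_class[CellClass.DIV].precision is None
        assert scores.per_class[CellClass.DIV].f1 is None


class TestAveragePrecision:
    def test_all_true_positives_gives_one(self):
        rng = np.random.default_rng(3)
        objs = [LabelledObject(make_box(rng), CellClass.LIV, 1.0) for _ in range(6)]
        preds = [
            LabelledObject(o.box, o.cls, float(c))
            for o, c in zip(objs, np.linspace(0.3, 0.9, 6))
        ]
        res = average_precision(_frame(objs), _frame(preds), CellClass.LIV, 0.5)
        assert res.ap == pytest.approx(1.0)

    def test_two_prediction_hand_oracle(self):
        gt = _frame([_obj(0, 0, 10, 10)])
        tp = _obj(0, 0, 10, 10, conf=0.9)
        fp = _obj(50, 50, 60, 60, conf=0.9)
        # top-ranked prediction is the TP -> PR points (1, 1), (1, 0.5) -> AP 1
        pred = _frame([LabelledObject(tp.box, tp.cls, 0.9), LabelledObject(fp.box, fp.cls, 0.8)])
        assert average_precision(gt, pred, CellClass.LIV, 0.5).ap == pytest.approx(1.0)
        # top-ranked prediction is the FP -> PR points (0, 0), (1, 0.5) -> AP 0.5
        pred = _frame([LabelledObject(fp.box, fp.cls, 0.9), LabelledObject(tp.box, tp.cls, 0.8)])
        assert average_precision(gt, pred, CellClass.LIV, 0.5).ap == pytest.approx(0.5)

    def test_no_predictions_zero_ap(self):
        gt = _frame([_obj(0, 0, 10, 10)])
        assert average_precision(gt, _frame([]), CellClass.LIV, 0.5).ap == 0.0

    def test_absent_class_returns_none(self):
        gt = _frame([_obj(0, 0, 10, 10, CellClass.LIV)])
        assert average_precision(gt, _frame([]), CellClass.DIV, 0.5) is None
        assert ap_bar(gt, _frame([]), CellClass.DIV) is None

    def test_ap_bar_threshold_counting(self):
        # Every prediction overlaps its ground truth at IoU ~ 0.571: perfect
        # below that threshold, lost above -> exactly 2 of 10 sweep points.
        gt_objs = []
        pred_objs = []
        for k in range(5):
            x = 100.0 * k
            gt_objs.append(_obj(x, 0, x + 20, 20))
            pred_objs.append(_obj(x, 0, x + 20, 35, conf=0.9))  # IoU = 400/700
        v = ap_bar(_frame(gt_objs), _frame(pred_objs), CellClass.LIV)
        assert v == pytest.approx(0.2)

    def test_ap_non_increasing_in_threshold(self):
        from cytolapse.simulate import NoiseConfig, SimConfig

        video, _ = simulate_population(
            SimConfig(n_initial=40, field_size=(700, 600), duration_h=2.0,
                      arrest_h=2.0, seed=2)
        )
        noise = NoiseConfig(miss_prob=0.05, jitter_sd_px=2.0, spurious_rate=1.0, seed=3)
        pred = apply_detector_noise(video, noise)
        for cls in (CellClass.LIV, CellClass.ROUND):
            aps = [
                average_precision(video.frames, pred.frames, cls, thr)
                for thr in DEFAULT_IOU_SWEEP
            ]
            vals = [a.ap for a in aps if a is not None]
            assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


class TestMapScore:
    def _multiclass_frame(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        objs = [
            LabelledObject(make_box(rng), CLASS_ORDER[k % 4], 1.0) for k in range(n)
        ]
        return _frame(objs)

    def test_identical_predictions_score_100(self):
        gt = self._multiclass_frame()
        pred = _frame(list(gt.objects))
        assert map_score(gt, pred) == pytest.approx(100.0)

    def test_all_classes_permuted_scores_0(self):
        gt = self._multiclass_frame()
        permuted = {
            CellClass.LIV: CellClass.ROUND,
            CellClass.ROUND: CellClass.DIV,
            CellClass.DIV: CellClass.DEAD,
            CellClass.DEAD: CellClass.LIV,
        }
        pred = _frame(
            [LabelledObject(o.box, permuted[o.cls], 0.9) for o in gt.objects]
        )
        assert map_score(gt, pred) == pytest.approx(0.0)

    def test_mean_over_present_classes(self):
        # liv scored perfectly (ap_bar 1), round at 0.5 -> mAP 75%
        gt_objs = [
            _obj(0, 0, 10, 10, CellClass.LIV),
            _obj(100, 0, 110, 10, CellClass.ROUND),
        ]
        pred_objs = [
            _obj(0, 0, 10, 10, CellClass.LIV, conf=0.9),
            _obj(200, 200, 210, 210, CellClass.ROUND, conf=0.95),  # FP first
            _obj(100, 0, 110, 10, CellClass.ROUND, conf=0.8),
        ]
        assert map_score(_frame(gt_objs), _frame(pred_objs)) == pytest.approx(75.0)

    def test_absent_class_zero_policy(self):
        gt_objs = [_obj(0, 0, 10, 10, CellClass.LIV)]
        pred_objs = [_obj(0, 0, 10, 10, CellClass.LIV, conf=0.9)]
        assert map_score(_frame(gt_objs), _frame(pred_objs)) == pytest.approx(100.0)
        assert map_score(
            _frame(gt_objs), _frame(pred_objs), absent_class="zero"
        ) == pytest.approx(25.0)

    def test_no_gt_raises(self):
        with pytest.raises(ValueError, match="mAP undefined"):
            map_score(_frame([]), _frame([]))

    def test_frame_scope_returns_series(self):
        gt = self._multiclass_frame()
        pred = _frame(list(gt.objects))
        series = map_score([gt], [pred], scope="frame")
        assert list(series.index) == [1]
        assert series.iloc[0] == pytest.approx(100.0)


class TestPerFrameReport:
    def test_report_columns_and_perfect_scores(self):
        from cytolapse.simulate import SimConfig

        video, _ = simulate_population(
            SimConfig(n_initial=15, field_size=(500, 400), duration_h=1.0,
                      arrest_h=1.0, seed=8)
        )
        report = per_frame_report(video, video, stride=3)
        assert {"frame", "time_min", "map_percent", "n_gt_liv"} <= set(report.columns)
        assert np.allclose(report["map_percent"].dropna(), 100.0)
        assert (report["n_gt_total"] == report["n_pred_total"]).all()
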