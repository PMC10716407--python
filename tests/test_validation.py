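"""MAPE, calibration regression, AP/mAP vs brute-force oracle, confusion, CV."""

import numpy as np
import pytest

from ismpop import (
    BoundingBox,
    Detection,
    average_precision,
    coefficient_of_variation,
    confusion_analysis,
    fit_alpha,
    mape_series,
    mean_average_precision,
)


# --------------------------------------------------------------------------
# Brute-force PR-staircase oracle for average precision
# --------------------------------------------------------------------------

def _greedy_tp_count(preds, gt_boxes, iou_thr):
    """TP count of a prediction prefix by explicit greedy matching."""
    taken = set()
    tp = 0
    for det in preds:
        best, best_j = 0.0, -1
        for j, g in enumerate(gt_boxes):
            if j in taken:
                continue
            iou = det.box.iou(g)
            if iou > best:
                best, best_j = iou, j
        if best_j >= 0 and best >= iou_thr:
            taken.add(best_j)
            tp += 1
    return tp


def ap_oracle(gt_boxes, preds, iou_thr=0.5):
    """AP from the explicit precision–recall staircase.

    For every confidence-ordered prefix the precision/recall pair is
    recomputed from scratch; the all-point area uses the
    max-future-precision form  AP = Σ (R_k − R_{k−1}) · max_{j≥k} P_j.
    """
    n_gt = len(gt_boxes)
    if n_gt == 0:
        return None
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))
    spreds = [preds[i] for i in order]
    points = []
    for k in range(1, len(spreds) + 1):
        tp = _greedy_tp_count(spreds[:k], gt_boxes, iou_thr)
        points.append((tp / n_gt, tp / k))
    ap = 0.0
    prev_r = 0.0
    for k, (r, _) in enumerate(points):
        if r > prev_r:
            p_max = max(p for rr, p in points[k:])
            ap += (r - prev_r) * p_max
            prev_r = r
    return ap


def _random_instance(rng, max_boxes=6):
    def rand_box():
        cx, cy = rng.uniform(0.2, 0.8, 2)
        w, h = rng.uniform(0.08, 0.3, 2)
        return BoundingBox(float(cx), float(cy), float(w), float(h))

    n_gt = int(rng.integers(1, max_boxes + 1))
    n_pred = int(rng.integers(0, max_boxes + 1))
    gt = [rand_box() for _ in range(n_gt)]
    preds = []
    for _ in range(n_pred):
        if gt and rng.random() < 0.6:
            # jittered copy of a gt box
            g = gt[int(rng.integers(len(gt)))]
            j = rng.normal(0, 0.03, 4)
            box = BoundingBox(
                float(np.clip(g.cx + j[0], 0.05, 0.95)),
                float(np.clip(g.cy + j[1], 0.05, 0.95)),
                float(np.clip(g.w + j[2], 0.02, 0.9)),
                float(np.clip(g.h + j[3], 0.02, 0.9)),
            )
        else:
            box = rand_box()
        preds.append(Detection(box=box, class_id=1, confidence=float(rng.uniform())))
    return gt, preds


class TestAveragePrecision:
    def _as_sets(self, gt, preds):
        return {"f": [(1, b) for b in gt]}, {"f": preds}

    def test_perfect_predictions(self):
        rng = np.random.default_rng(0)
        gt, _ = _random_instance(rng)
        preds = [Detection(box=b, class_id=1, confidence=1.0) for b in gt]
        gts, ps = self._as_sets(gt, preds)
        assert average_precision(gts, ps, 1) == pytest.approx(1.0)
        m, per = mean_average_precision(gts, ps)
        assert m == pytest.approx(1.0)
        assert per[2] is None        # class absent from gt, excluded not 0

    def test_no_predictions(self):
        gts = {"f": [(1, BoundingBox(0.5, 0.5, 0.2, 0.2))]}
        assert average_precision(gts, {"f": []}, 1) == 0.0

    def test_two_gt_three_preds_staircase(self):
        g1 = BoundingBox(0.3, 0.3, 0.2, 0.2)
        g2 = BoundingBox(0.7, 0.7, 0.2, 0.2)
        preds = [
            Detection(box=BoundingBox(0.5, 0.1, 0.1, 0.1), class_id=1, confidence=0.95),
            Detection(box=g1, class_id=1, confidence=0.9),
            Detection(box=g2, class_id=1, confidence=0.8),
        ]
        gts, ps = self._as_sets([g1, g2], preds)
        # FP, TP, TP -> PR points (0,0), (1/2,1/2), (1,2/3); all-point area = 2/3
        assert average_precision(gts, ps, 1) == pytest.approx(2.0 / 3.0)
        assert ap_oracle([g1, g2], preds) == pytest.approx(2.0 / 3.0)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            gt, preds = _random_instance(rng)
            gts, ps = self._as_sets(gt, preds)
            fast = average_precision(gts, ps, 1)
            slow = ap_oracle(gt, preds)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_invalid_iou_threshold(self):
        with pytest.raises(ValueError):
            average_precision({}, {}, 1, iou_threshold=1.5)


class TestPooledViableMap:
    def test_pooling_beats_separate_aps_under_1_4_swaps(self):
        """When the only errors are viable <-> bulged swaps, evaluating the
        two morphotypes as one pooled class recovers a perfect score."""
        rng = np.random.default_rng(7)
        gt = {}
        preds = {}
        for f in range(30):
            boxes = []
            dets = []
            for i in range(4):
                cx = 0.15 + 0.22 * i
                box = BoundingBox(cx, 0.5, 0.15, 0.15)
                true_cls = 1 if rng.random() < 0.5 else 4
                pred_cls = true_cls
                if rng.random() < 0.3:     # symmetric 1<->4 swap errors
                    pred_cls = 5 - true_cls
                boxes.append((true_cls, box))
                dets.append(Detection(box=box, class_id=pred_cls,
                                      confidence=float(rng.uniform(0.5, 1.0))))
            gt[f] = boxes
            preds[f] = dets
        _, separate = mean_average_precision(gt, preds, pool_viable=False)
        pooled_map, pooled = mean_average_precision(gt, preds, pool_viable=True)
        mean_separate = np.mean([separate[1], separate[4]])
        assert pooled[1] >= mean_separate
        assert pooled[1] == pytest.approx(1.0)


class TestMape:
    def test_identical_series_zero(self):
        assert mape_series([0, 1], [5.0, 6.0], [0, 1], [5.0, 6.0]) == 0.0

    def test_hand_mean(self):
        assert mape_series([0, 1], [100.0, 200.0], [0, 1], [110.0, 180.0]) == pytest.approx(10.0)

    def test_scale_invariance(self):
        a = mape_series([0, 1], [100.0, 200.0], [0, 1], [90.0, 230.0])
        b = mape_series([0, 1], [300.0, 600.0], [0, 1], [270.0, 690.0])
        assert a == pytest.approx(b)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="t=1"):
            mape_series([0, 1], [10.0, 0.0], [0, 1], [10.0, 1.0])

    def test_alignment_gap_enforced(self):
        with pytest.raises(ValueError):
            mape_series([5.0], [10.0], [0.0, 1.0], [10.0, 10.0], max_gap_h=1.0)


class TestFitAlpha:
    def test_noiseless_recovery_exact(self):
        y = np.linspace(0.05, 0.5, 20)
        x_dens = 3.2e6 * y
        model = fit_alpha(list(zip(y, x_dens)))
        assert model.alpha == pytest.approx(3.2e6, rel=1e-12)
        assert model.r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_point_closed_form(self):
        model = fit_alpha([(0.1, 3.2e5), (0.2, 6.4e5)])
        assert model.alpha == pytest.approx(3.2e6)

    def test_noisy_recovery_within_5pct(self):
        rng = np.random.default_rng(42)
        y = rng.uniform(0.05, 0.5, 200)
        sigma = np.sqrt(np.log(1 + 0.2 ** 2))
        x_dens = 3.2e6 * y * np.exp(rng.normal(0, sigma, 200) - sigma ** 2 / 2)
        model = fit_alpha(list(zip(y, x_dens)))
        assert model.alpha == pytest.approx(3.2e6, rel=0.05)

    def test_degenerate_fit_rejected(self):
        with pytest.raises(ValueError):
            fit_alpha([(0.0, 1.0), (0.0, 2.0)])


class TestConfusionAnalysis:
    def test_identical_labels_no_error(self):
        pairs = [(c, c) for c in (1, 2, 3, 4, 5, 6) for _ in range(5)]
        rep = confusion_analysis(pairs)
        assert all(rep.error_pct[c] == 0.0 for c in range(1, 7))

    def test_quarter_misclassified(self):
        pairs = [(1, 1)] * 75 + [(1, 4)] * 25
        rep = confusion_analysis(pairs)
        assert rep.error_pct[1] == pytest.approx(25.0)

    def test_symmetric_swaps_cancel_in_net_counts(self):
        pairs = [(1, 1)] * 40 + [(4, 4)] * 40 + [(1, 4)] * 10 + [(4, 1)] * 10
        rep = confusion_analysis(pairs)
        assert rep.net_count_diff_pct[1] == 0.0
        assert rep.net_count_diff_pct[4] == 0.0
        assert rep.error_pct[1] == pytest.approx(20.0)

    def test_empty_input(self):
        rep = confusion_analysis([])
        assert rep.matrix.sum() == 0
        assert all(v is None for v in rep.error_pct.values())


class TestCoefficientOfVariation:
    def test_identical_replicates(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_hand_value(self):
        # sd(10,20) = 7.071, mean 15 -> 47.1%
        assert coefficient_of_variation([10.0, 20.0]) == pytest.approx(47.14, abs=0.01)

    def test_scale_invariance(self):
        reps = [10.0, 12.0, 9.0, 14.0]
        assert coefficient_of_variation(reps) == pytest.approx(
            coefficient_of_variation([3 * r for r in reps])
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])
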