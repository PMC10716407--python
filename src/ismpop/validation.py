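"""Evaluation statistics: MAPE, calibration fit, AP/mAP, confusion, CV."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .accounting import CalibrationModel
from .core import BoundingBox
from .detection import Detection
from .synthetic import OfflineSample

__all__ = [
    "EvaluationReport",
    "mape",
    "mape_series",
    "fit_alpha",
    "average_precision",
    "mean_average_precision",
    "match_detections",
    "confusion_analysis",
    "coefficient_of_variation",
]


# --------------------------------------------------------------------------
# MAPE against the offline reference
# --------------------------------------------------------------------------

def mape_series(
    ref_times: Sequence[float],
    ref_values: Sequence[float],
    pred_times: Sequence[float],
    pred_values: Sequence[float],
    align: str = "nearest",
    max_gap_h: float = 1.0,
) -> float:
    """Mean absolute percentage error of a predicted series vs reference points.

    For each reference point the predicted value is taken at the nearest
    predicted time within ``max_gap_h`` (``align='nearest'``) or linearly
    interpolated (``align='interpolate'``).
    """
    rt = np.asarray(ref_times, dtype=float)
    rv = np.asarray(ref_values, dtype=float)
    pt = np.asarray(pred_times, dtype=float)
    pv = np.asarray(pred_values, dtype=float)
    if rt.size == 0:
        raise ValueError("need at least one reference point")
    zero = np.nonzero(rv == 0)[0]
    if zero.size:
        raise ValueError(
            f"reference value is 0 at t={rt[zero[0]]} h; MAPE is undefined there"
        )
    errors = []
    for t, r in zip(rt, rv):
        if align == "nearest":
            i = int(np.argmin(np.abs(pt - t)))
            if abs(pt[i] - t) > max_gap_h:
                raise ValueError(
                    f"no predicted point within {max_gap_h} h of reference t={t} h"
                )
            p = pv[i]
        elif align == "interpolate":
            if t < pt[0] or t > pt[-1]:
                raise ValueError(f"reference t={t} h outside the predicted series")
            p = float(np.interp(t, pt, pv))
        else:
            raise ValueError(f"unknown alignment {align!r}")
        errors.append(abs(p - r) / abs(r) * 100.0)
    return float(np.mean(errors))


def mape(
    reference: Sequence[OfflineSample],
    predicted,
    quantity: str = "density",
    align: str = "nearest",
    max_gap_h: float = 1.0,
) -> float:
    """MAPE of a predicted :class:`~ismpop.accounting.DensitySeries` against
    offline reference samples, for ``quantity`` 'density' (total cell/mL)
    or 'viability' (%)."""
    rt = [s.time for s in reference]
    if quantity == "density":
        rv = [s.density for s in reference]
        pv = predicted.total
    elif quantity == "viability":
        rv = [s.viability for s in reference]
        pv = predicted.viability
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return mape_series(rt, rv, predicted.time, pv, align=align, max_gap_h=max_gap_h)


# --------------------------------------------------------------------------
# Calibration regression
# --------------------------------------------------------------------------

def fit_alpha(pairs: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Least-squares fit of X = α·y through the origin.

    ``pairs`` are (y cells/image, X cell/mL).  The Pearson correlation r of
    (y, X) and its square are reported alongside the slope; the model has
    no intercept, matching the probe-volume interpretation of α.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (y, X) pairs")
    y, x_dens = arr[:, 0], arr[:, 1]
    sy2 = float(np.sum(y * y))
    if sy2 == 0:
        raise ValueError("degenerate fit: all counts per image are 0")
    alpha = float(np.sum(y * x_dens)) / sy2
    if np.std(y) == 0 or np.std(x_dens) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(y, x_dens)[0, 1])
    return CalibrationModel(alpha=alpha, r=r, r2=r * r if np.isfinite(r) else float("nan"))


# --------------------------------------------------------------------------
# Object-detection evaluation
# --------------------------------------------------------------------------

AnnotationSet = Mapping[object, Sequence[tuple[int, BoundingBox]]]


def _pool_class(cls: int, pool_viable: bool) -> int:
    # pooling merges the bulge-displaying viable class into plain viable
    return 1 if (pool_viable and cls == 4) else cls


def _match_class(
    gt: AnnotationSet,
    preds: Mapping[object, Sequence[Detection]],
    class_id: int,
    iou_threshold: float,
    pool_viable: bool,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Greedy one-to-one matching; returns (tp, fp) flags sorted by
    descending confidence and the number of ground-truth instances."""
    gt_boxes: dict[object, list[BoundingBox]] = {}
    n_gt = 0
    for fid, anns in gt.items():
        boxes = [b for c, b in anns if _pool_class(c, pool_viable) == class_id]
        if boxes:
            gt_boxes[fid] = boxes
            n_gt += len(boxes)
    records = []
    for fid, dets in preds.items():
        for order, d in enumerate(dets):
            if _pool_class(int(d.class_id), pool_viable) == class_id:
                records.append((-d.confidence, order, fid, d))
    records.sort(key=lambda r: (r[0], r[1]))
    matched: dict[object, set[int]] = {fid: set() for fid in gt_boxes}
    tp = np.zeros(len(records))
    fp = np.zeros(len(records))
    for k, (_, _, fid, det) in enumerate(records):
        best_iou, best_j = 0.0, -1
        for j, box in enumerate(gt_boxes.get(fid, [])):
            if j in matched.get(fid, set()):
                continue
            iou = det.box.iou(box)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            tp[k] = 1
            matched[fid].add(best_j)
        else:
            fp[k] = 1
    return tp, fp, n_gt


def average_precision(
    gt: AnnotationSet,
    preds: Mapping[object, Sequence[Detection]],
    class_id: int,
    iou_threshold: float = 0.5,
    pool_viable: bool = False,
) -> float | None:
    """All-point interpolated average precision for one class.

    Predictions are matched greedily by descending confidence, one-to-one,
    requiring IoU ≥ ``iou_threshold``.  Returns ``None`` when the ground
    truth contains no instance of the class (the class is then absent from
    the mAP mean, never counted as 0).
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must lie in (0, 1)")
    tp, fp, n_gt = _match_class(gt, preds, class_id, iou_threshold, pool_viable)
    if n_gt == 0:
        return None
    if len(tp) == 0:
        return 0.0
    ctp = np.cumsum(tp)
    cfp = np.cumsum(fp)
    recall = ctp / n_gt
    precision = ctp / np.maximum(ctp + cfp, 1e-12)
    # all-point interpolation: integrate the monotone precision envelope
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.nonzero(np.diff(mrec) > 0)[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def mean_average_precision(
    gt: AnnotationSet,
    preds: Mapping[object, Sequence[Detection]],
    iou_threshold: float = 0.5,
    pool_viable: bool = False,
) -> tuple[float | None, dict[int, float | None]]:
    """Unweighted mean AP over classes present in the ground truth.

    With ``pool_viable=True`` the two viable morphotypes (plain and
    bulge-displaying) are evaluated as one class, the strategy that
    suppresses their mutual confusion.
    """
    class_ids = [1, 2, 3, 5, 6] if pool_viable else [1, 2, 3, 4, 5, 6]
    per_class = {
        c: average_precision(gt, preds, c, iou_threshold, pool_viable)
        for c in class_ids
    }
    present = [ap for ap in per_class.values() if ap is not None]
    return (float(np.mean(present)) if present else None), per_class


def match_detections(
    gt: Sequence[tuple[int, BoundingBox]],
    preds: Sequence[Detection],
    iou_threshold: float = 0.5,
) -> list[tuple[int, int]]:
    """Class-agnostic greedy box matching; returns (gt_class, pred_class) pairs."""
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))
    taken: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i in order:
        det = preds[i]
        best_iou, best_j = 0.0, -1
        for j, (_, box) in enumerate(gt):
            if j in taken:
                continue
            iou = det.box.iou(box)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            taken.add(best_j)
            pairs.append((int(gt[best_j][0]), int(det.class_id)))
    return pairs


@dataclass
class ConfusionReport:
    """6×6 confusion counts with per-class error and count-difference rates."""

    matrix: np.ndarray                       # rows: true class, cols: predicted
    error_pct: dict[int, float | None]       # misclassified / gt of that class
    net_count_diff_pct: dict[int, float | None]  # |#pred − #gt| / #gt

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "error_pct": {str(k): v for k, v in self.error_pct.items()},
            "net_count_diff_pct": {str(k): v for k, v in self.net_count_diff_pct.items()},
        }


def confusion_analysis(pairs: Sequence[tuple[int, int]]) -> ConfusionReport:
    """Summarize matched (true class, predicted class) label pairs."""
    matrix = np.zeros((6, 6), dtype=int)
    for true_c, pred_c in pairs:
        matrix[true_c - 1, pred_c - 1] += 1
    error_pct: dict[int, float | None] = {}
    diff_pct: dict[int, float | None] = {}
    for c in range(1, 7):
        n_gt = int(matrix[c - 1].sum())
        n_pred = int(matrix[:, c - 1].sum())
        if n_gt == 0:
            error_pct[c] = None
            diff_pct[c] = None
        else:
            error_pct[c] = 100.0 * (n_gt - int(matrix[c - 1, c - 1])) / n_gt
            diff_pct[c] = 100.0 * abs(n_pred - n_gt) / n_gt
    return ConfusionReport(matrix=matrix, error_pct=error_pct, net_count_diff_pct=diff_pct)


# --------------------------------------------------------------------------
# Replicate statistics
# --------------------------------------------------------------------------

def coefficient_of_variation(replicates: Sequence[float]) -> float:
    """Sample coefficient of variation in percent (sd with n−1 / mean · 100)."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two replicates")
    m = float(np.mean(x))
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(np.std(x, ddof=1) / m * 100.0)


# --------------------------------------------------------------------------
# Aggregate report
# --------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Bundle of the monitoring-validation statistics, JSON-serializable."""

    mape_density: float | None = None
    mape_viability: float | None = None
    per_class_ap: dict[int, float | None] = field(default_factory=dict)
    map_value: float | None = None
    confusion: ConfusionReport | None = None
    calibration: CalibrationModel | None = None
    cv: float | None = None

    def to_dict(self) -> dict:
        return {
            "mape_density_pct": self.mape_density,
            "mape_viability_pct": self.mape_viability,
            "per_class_ap": {str(k): v for k, v in self.per_class_ap.items()},
            "mAP": self.map_value,
            "confusion": self.confusion.to_dict() if self.confusion else None,
            "calibration": self.calibration.to_dict() if self.calibration else None,
            "cv_pct": self.cv,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
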