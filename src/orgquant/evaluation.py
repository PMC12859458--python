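"""Accuracy metrics for both halves of the pipeline.

Counting accuracy follows the relative-error convention of the field:
the real nuclei count divided by the predicted count, reported on a log10
scale per organoid and aggregated as the mean of absolute values with a
t-based 95% confidence interval; per-well accuracy is the percent
deviation of the estimated total from the real total.

Detection accuracy is mean average precision (mAP): predictions are
greedily matched to ground-truth masks at a mask-IoU threshold (default
0.5) in descending confidence order, and AP is the area under the
precision-recall envelope (all-points interpolation).  With a single
object class, mAP equals AP.

Threshold selection: a classical ROC needs a fixed negative count, which
a detection task does not have, so the confidence threshold is chosen on
a surrogate curve — recall (TPR) against spurious detections per image
min-max normalized over the candidate grid — maximizing the Youden-style
objective TPR - normalizedFP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import DetectionSet, OrganoidInstance, OrgquantError

#: Benchmark figures reported for the original trained Mask R-CNN organoid
#: detectors evaluated on their private patient-derived image sets.  They
#: are carried as documented reference values for context (and the two
#: thresholds as configuration defaults); reproducing them requires those
#: trained weights and images, which no classical stand-in detector can
#: substitute for.
REFERENCE_BENCHMARKS = {
    "map_cystic": 0.855,
    "map_budded": 0.81,
    "mean_abs_log10_re_training": 0.1624,
    "mean_abs_log10_re_validation": 0.1785,
    "mean_abs_log10_re_pancreatic": 0.1653,
    "well_deviation_pct": 16.0,
    "well_deviation_ci_pct": (11.0, 20.0),
    "confidence_threshold_cystic": 0.795,
    "confidence_threshold_budded": 0.836,
}


# ---------------------------------------------------------------------------
# Count metrics

def log10_relative_error(real_n, predicted_n) -> float:
    """log10(real / predicted); 0 means perfect, 1 means a decade off."""
    real_n = float(real_n)
    predicted_n = float(predicted_n)
    if real_n < 1:
        raise OrgquantError(f"real count must be >= 1, got {real_n}")
    if predicted_n <= 0:
        raise OrgquantError(f"predicted count must be positive, got {predicted_n}")
    return math.log10(real_n / predicted_n)


def mean_abs_log10_re(
    errors: Sequence[float], ci_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Mean of |log10 RE| with a t-based confidence interval.

    Returns (mean, (lo, hi)); with a single error the interval collapses
    to the point.
    """
    e = np.abs(np.asarray(errors, dtype=float))
    if e.size == 0:
        raise OrgquantError("no errors to aggregate")
    m = float(e.mean())
    if e.size < 2:
        return m, (m, m)
    sem = float(e.std(ddof=1) / math.sqrt(e.size))
    t = stats.t.ppf(0.5 + ci_level / 2.0, df=e.size - 1)
    return m, (m - t * sem, m + t * sem)


def well_deviation(real_total: float, est_total: float) -> float:
    """Percent deviation of the estimated well total from the real total."""
    if real_total <= 0:
        raise OrgquantError(f"real total must be positive, got {real_total}")
    return 100.0 * abs(real_total - est_total) / real_total


# ---------------------------------------------------------------------------
# Detection metrics

def mask_iou(a: OrganoidInstance, b: OrganoidInstance) -> float:
    inter = a.intersection_area(b)
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def match_instances(
    pred: DetectionSet, truth: DetectionSet, iou_threshold: float = 0.5
) -> list[tuple[int, Optional[int], float]]:
    """Greedy one-to-one matching of predictions to ground truth.

    Predictions are visited in descending confidence (ties by id); each
    claims the still-unmatched truth instance of maximal IoU, provided
    IoU >= iou_threshold.  Returns one row per prediction:
    (pred_id, matched_truth_id or None, iou).
    """
    if (pred.image_width, pred.image_height) != (truth.image_width, truth.image_height):
        raise OrgquantError("prediction and truth sets have different image dimensions")
    order = sorted(pred.instances, key=lambda i: (-i.confidence, i.id))
    unmatched = {t.id: t for t in truth.instances}
    rows: list[tuple[int, Optional[int], float]] = []
    for p in order:
        best_id, best_iou = None, 0.0
        for tid, t in unmatched.items():
            iou = mask_iou(p, t)
            if iou > best_iou or (iou == best_iou and best_id is not None and tid < best_id):
                if iou > 0:
                    best_id, best_iou = tid, iou
        if best_id is not None and best_iou >= iou_threshold:
            rows.append((p.id, best_id, best_iou))
            del unmatched[best_id]
        else:
            rows.append((p.id, None, best_iou))
    return rows


def mean_average_precision(
    pred: DetectionSet, truth: DetectionSet, iou_threshold: float = 0.5
) -> float:
    """Single-class mAP: area under the all-points precision-recall envelope.

    1.0 for a detector reproducing the truth exactly; 0.0 when no
    prediction matches any truth instance.
    """
    n_truth = len(truth)
    if n_truth == 0:
        raise OrgquantError("ground truth is empty")
    if len(pred) == 0:
        return 0.0
    matches = match_instances(pred, truth, iou_threshold)
    # match_instances already visits predictions in descending confidence.
    tp = np.array([1.0 if m[1] is not None else 0.0 for m in matches])
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_truth
    precision = cum_tp / (cum_tp + cum_fp)
    # All-points interpolation: envelope of precision from the right.
    mrec = np.concatenate(([0.0], recall))
    mpre = np.concatenate(([1.0], precision))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    return float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))


# ---------------------------------------------------------------------------
# Threshold selection

@dataclass
class ThresholdCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    spurious_per_image: np.ndarray
    normalized_fp: np.ndarray
    objective: np.ndarray
    chosen: float


def _filtered(pred: DetectionSet, threshold: float) -> DetectionSet:
    kept = [p for p in pred.instances if p.confidence >= threshold]
    return DetectionSet(
        instances=kept,
        image_width=pred.image_width,
        image_height=pred.image_height,
        deduplicated=pred.deduplicated,
    )


def select_threshold(
    pred: DetectionSet,
    truth: DetectionSet,
    grid: Sequence[float],
    iou_threshold: float = 0.5,
) -> ThresholdCurve:
    """Choose the confidence threshold maximizing TPR - normalizedFP.

    For each candidate the predictions are filtered, matched to truth, and
    recall plus the spurious-detection count are computed; spurious counts
    are min-max normalized over the grid.  Ties go to the smallest
    threshold.  The full curve is returned for inspection.
    """
    if len(truth) == 0:
        raise OrgquantError("cannot select a threshold against empty ground truth")
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0 or grid.min() < 0 or grid.max() > 1:
        raise OrgquantError("threshold grid must be non-empty within [0, 1]")
    tpr = np.empty(grid.size)
    spurious = np.empty(grid.size)
    for k, thr in enumerate(grid):
        matches = match_instances(_filtered(pred, thr), truth, iou_threshold)
        n_tp = sum(1 for m in matches if m[1] is not None)
        tpr[k] = n_tp / len(truth)
        spurious[k] = len(matches) - n_tp
    span = spurious.max() - spurious.min()
    norm_fp = (spurious - spurious.min()) / span if span > 0 else np.zeros_like(spurious)
    objective = tpr - norm_fp
    chosen = float(grid[int(np.argmax(objective))])  # argmax takes first = smallest
    return ThresholdCurve(
        thresholds=grid,
        tpr=tpr,
        spurious_per_image=spurious,
        normalized_fp=norm_fp,
        objective=objective,
        chosen=chosen,
    )


# ---------------------------------------------------------------------------
# Report container

@dataclass
class EvalReport:
    """Bundle of detection and counting metrics for one evaluation run."""

    log10_errors: list[float] = field(default_factory=list)
    mean_abs_log10_re: Optional[float] = None
    mean_abs_log10_re_ci: Optional[tuple[float, float]] = None
    mean_signed_log10_re: Optional[float] = None
    well_deviations_pct: list[float] = field(default_factory=list)
    mean_well_deviation_pct: Optional[float] = None
    map_score: Optional[float] = None
    n_matched: int = 0
    n_missed: int = 0
    n_spurious: int = 0
    chosen_threshold: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "log10_errors": list(map(float, self.log10_errors)),
            "mean_abs_log10_re": self.mean_abs_log10_re,
            "mean_abs_log10_re_ci": self.mean_abs_log10_re_ci,
            "mean_signed_log10_re": self.mean_signed_log10_re,
            "well_deviations_pct": list(map(float, self.well_deviations_pct)),
            "mean_well_deviation_pct": self.mean_well_deviation_pct,
            "mAP": self.map_score,
            "n_matched": self.n_matched,
            "n_missed": self.n_missed,
            "n_spurious": self.n_spurious,
            "chosen_threshold": self.chosen_threshold,
        }


def detection_report(
    pred: DetectionSet, truth: DetectionSet, iou_threshold: float = 0.5
) -> EvalReport:
    """Match predictions to truth and summarize detection performance."""
    matches = match_instances(pred, truth, iou_threshold)
    n_matched = sum(1 for m in matches if m[1] is not None)
    report = EvalReport(
        map_score=mean_average_precision(pred, truth, iou_threshold),
        n_matched=n_matched,
        n_missed=len(truth) - n_matched,
        n_spurious=len(pred) - n_matched,
    )
    return report


def count_report(
    real_counts: Sequence[float], predicted_counts: Sequence[float]
) -> EvalReport:
    """Per-organoid log10 relative errors and their aggregate statistics."""
    if len(real_counts) != len(predicted_counts):
        raise OrgquantError("real and predicted count lists differ in length")
    errors = [
        log10_relative_error(r, p) for r, p in zip(real_counts, predicted_counts)
    ]
    mean_abs, ci = mean_abs_log10_re(errors)
    return EvalReport(
        log10_errors=errors,
        mean_abs_log10_re=mean_abs,
        mean_abs_log10_re_ci=ci,
        mean_signed_log10_re=float(np.mean(errors)),
    )
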