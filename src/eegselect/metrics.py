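"""Evaluation metrics for heavily imbalanced seizure detection.

The headline metric is the recall-restricted, renormalized area under the
precision-recall curve,

    AUC-PR-0.7 = (1 / 0.3) * integral_{0.7}^{1} p(r) dr,

where p(r) is precision as a function of recall along the decision-threshold
sweep.  Restricting to recall >= 0.7 scores only the clinically acceptable
sensitivity range, and the 1/0.3 normalization maps a perfect classifier to
1.  Conventional ROC-AUC is kept alongside, and subset models are reported
as a percentage of the corresponding full-montage model
("percent-of-full-AUC-PR-0.7"), summarized by the median across data splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall points, one per distinct score threshold, descending.

    ``recall`` is non-decreasing along the array (threshold descending) and
    ends at 1.0; the degenerate recall-0 anchor is not included.
    """

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray


def _validate_binary(labels: np.ndarray) -> None:
    pos = int((labels == 1).sum())
    if pos == 0 or pos == len(labels):
        raise ValueError("both classes must be present")


def pr_curve(labels, scores) -> PRCurve:
    """Precision-recall curve over the distinct-threshold sweep.

    Ties in scores collapse to a single threshold, so the curve is
    independent of sample order.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    _validate_binary(labels)
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    # sklearn orders by increasing threshold and appends a (recall=0, p=1)
    # anchor; re-order to threshold-descending and drop the anchor.
    precision, recall = precision[:-1][::-1], recall[:-1][::-1]
    thresholds = thresholds[::-1]
    # thresholds below the first reaching recall 1 only add false positives
    # at constant recall; the curve ends at its first full-recall point
    stop = int(np.argmax(recall >= 1.0)) + 1
    return PRCurve(recall=recall[:stop], precision=precision[:stop], thresholds=thresholds[:stop])


def auc_pr_restricted(curve: PRCurve, r_min: float = 0.7) -> float:
    """Normalized area under the PR curve over recall in [r_min, 1].

    Trapezoidal integration along the threshold-descending curve; precision
    exactly at ``r_min`` is obtained by linear interpolation between the
    bracketing curve points, and the result is divided by (1 - r_min) so a
    perfect classifier scores 1.  Zero-width recall steps (thresholds that
    only add false positives) contribute no area, as they must.
    """
    if not 0 <= r_min < 1:
        raise ValueError("r_min must be in [0, 1)")
    r = curve.recall
    p = curve.precision
    area = 0.0
    for i in range(len(r) - 1):
        r0, r1 = r[i], r[i + 1]
        p0, p1 = p[i], p[i + 1]
        if r1 <= r_min or r1 == r0:
            continue
        if r0 < r_min:
            # clip the segment at r_min by linear interpolation
            p0 = p0 + (p1 - p0) * (r_min - r0) / (r1 - r0)
            r0 = r_min
        area += 0.5 * (p0 + p1) * (r1 - r0)
    if r[0] > r_min:
        # curve starts above r_min: anchor precision horizontally down to r_min
        area += p[0] * (r[0] - r_min)
    return float(area / (1.0 - r_min))


def auc_pr_07(labels, scores, r_min: float = 0.7) -> float:
    """Convenience wrapper: AUC-PR-0.7 straight from labels and scores."""
    return auc_pr_restricted(pr_curve(labels, scores), r_min)


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve (Mann-Whitney probability; ties count 1/2)."""
    labels = np.asarray(labels)
    _validate_binary(labels)
    return float(roc_auc_score(labels, scores))


def percent_of_full(subset_auc: float, full_auc: float) -> float:
    """A subset model's AUC-PR-0.7 as a percentage of the full model's."""
    if full_auc <= 0:
        raise ValueError("full-model AUC must be positive for normalization")
    return 100.0 * subset_auc / full_auc


def median_across_splits(values) -> float:
    """Median over per-split values (mean of the central pair when even)."""
    values = np.asarray(list(values), float)
    if values.size == 0:
        raise ValueError("no values to summarize")
    return float(np.median(values))
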