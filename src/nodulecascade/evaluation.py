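"""Detection metrics at pixel and lesion level.

Pixel-level metrics tally per-pixel confusion counts; lesion-level
metrics extract 8-connected components of the binarised prediction and
match each against the annotated nodule centers (a component is a hit
when its centroid lies within the annotation's radius; each annotation
claims at most one component, greedily nearest-first).

Accuracy, sensitivity and specificity follow the standard confusion
ratios ``(TP+TN)/total``, ``TP/(TP+FN)`` and ``TN/(TN+FP)``.  Detector
quality across thresholds is summarised by the precision-recall curve
and its trapezoidal area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .phantom import NoduleAnnotation

__all__ = [
    "ConfusionCounts",
    "PRCurve",
    "confusion_counts",
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "dice_coefficient",
    "match_lesions",
    "pr_curve",
    "interpolated_pr_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype != bool and not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return arr.astype(bool)


def confusion_counts(pred_bin, gt_bin) -> ConfusionCounts:
    """Exhaustive, mutually exclusive pixel tally of a binary prediction."""
    p = _check_binary(pred_bin, "prediction")
    g = _check_binary(gt_bin, "ground truth")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)),
        tn=int(np.sum(~p & ~g)), fn=int(np.sum(~p & g)),
    )


def accuracy(c: ConfusionCounts) -> float:
    total = c.tp + c.fp + c.tn + c.fn
    if total == 0:
        raise ZeroDivisionError("accuracy undefined: empty confusion table")
    return (c.tp + c.tn) / total


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive samples")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative samples")
    return c.tn / (c.tn + c.fp)


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        raise ZeroDivisionError("precision undefined: no predicted positives")
    return c.tp / (c.tp + c.fp)


def dice_coefficient(pred_bin, gt_bin) -> float:
    """Overlap similarity ``2|A ∩ B| / (|A| + |B|)`` of two binary masks."""
    p = _check_binary(pred_bin, "prediction")
    g = _check_binary(gt_bin, "ground truth")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = p.sum() + g.sum()
    if denom == 0:
        raise ZeroDivisionError("dice undefined: both masks empty")
    return 2.0 * np.sum(p & g) / denom


def match_lesions(pred_mask, annotations: list[NoduleAnnotation],
                  criterion: str = "center", iou_threshold: float = 0.1,
                  image_shape=None) -> ConfusionCounts:
    """Lesion-level TP/FP/FN of a binary prediction against annotations.

    Connected components (8-connectivity) of ``pred_mask`` are candidate
    detections.  With ``criterion='center'`` (the LUNA16-style hit rule)
    a component hits an annotation when its centroid lies within
    ``diameter/2`` of the annotation center; ``criterion='iou'`` instead
    requires component/disc IoU above ``iou_threshold``.  Each
    annotation claims at most one component (greedy nearest-first);
    unclaimed components are FP, unclaimed annotations FN.
    """
    p = _check_binary(pred_mask, "prediction")
    labels = measure.label(p, connectivity=2)
    props = measure.regionprops(labels)
    if criterion not in ("center", "iou"):
        raise ValueError("criterion must be 'center' or 'iou'")

    pairs = []  # (distance, annotation idx, component idx)
    for ai, ann in enumerate(annotations):
        for ci, prop in enumerate(props):
            cy, cx = prop.centroid
            dist = float(np.hypot(cy - ann.center_row, cx - ann.center_col))
            if criterion == "center":
                if dist <= ann.diameter / 2.0:
                    pairs.append((dist, ai, ci))
            else:
                from .phantom import rasterize_disc
                disc = rasterize_disc(p.shape, ann.center_row, ann.center_col,
                                      ann.diameter)
                comp = labels == prop.label
                iou = np.sum(disc & comp) / np.sum(disc | comp)
                if iou > iou_threshold:
                    pairs.append((dist, ai, ci))
    pairs.sort(key=lambda t: t[0])
    used_ann: set[int] = set()
    used_comp: set[int] = set()
    tp = 0
    for _, ai, ci in pairs:
        if ai in used_ann or ci in used_comp:
            continue
        used_ann.add(ai)
        used_comp.add(ci)
        tp += 1
    return ConfusionCounts(tp=tp, fp=len(props) - len(used_comp),
                           tn=0, fn=len(annotations) - len(used_ann))


@dataclass
class PRCurve:
    """Precision-recall pairs over a threshold sweep and their area.

    The stored pairs include a (recall=0, precision=1) anchor; ``auc`` is
    the trapezoidal integral of the interpolated upper envelope of the
    stored pairs (see :func:`interpolated_pr_auc`), so a perfect detector
    scores exactly 1.0.
    """

    recalls: np.ndarray
    precisions: np.ndarray
    thresholds: np.ndarray
    auc: float


def pr_curve(prob_maps, gts, thresholds=None, level: str = "lesion",
             annotations_per_sample: list[list[NoduleAnnotation]] | None = None) -> PRCurve:
    """Precision/recall across a descending threshold sweep, with AUC.

    ``level='lesion'`` scores connected components against annotations
    (``annotations_per_sample``; when omitted they are derived from each
    ground-truth mask's components).  ``level='pixel'`` scores per-pixel.
    Thresholds default to 99 evenly spaced cut-offs in (0, 1); they are
    swept from high to low so recall is non-decreasing along the curve.
    """
    if len(prob_maps) == 0 or len(prob_maps) != len(gts):
        raise ValueError("need equally many probability maps and ground truths")
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    if thresholds.min() <= 0 or thresholds.max() >= 1:
        raise ValueError("thresholds must lie in (0, 1)")

    if level == "lesion" and annotations_per_sample is None:
        annotations_per_sample = []
        for gt in gts:
            labels = measure.label(_check_binary(gt, "gt"), connectivity=2)
            anns = []
            for prop in measure.regionprops(labels):
                cy, cx = prop.centroid
                anns.append(NoduleAnnotation(cy, cx, float(prop.equivalent_diameter)))
            annotations_per_sample.append(anns)

    recalls, precisions = [], []
    for thr in thresholds[::-1]:  # descending: recall grows along the sweep
        if level == "pixel":
            counts = ConfusionCounts()
            for pm, gt in zip(prob_maps, gts):
                counts = counts + confusion_counts(np.asarray(pm) >= thr, gt)
        elif level == "lesion":
            counts = ConfusionCounts()
            for pm, anns in zip(prob_maps, annotations_per_sample):
                counts = counts + match_lesions(np.asarray(pm) >= thr, anns)
        else:
            raise ValueError("level must be 'lesion' or 'pixel'")
        tp, fp, fn = counts.tp, counts.fp, counts.fn
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
        precisions.append(tp / (tp + fp) if tp + fp else 1.0)

    rec = np.concatenate([[0.0], recalls])
    prec = np.concatenate([[1.0], precisions])
    return PRCurve(recalls=rec, precisions=prec,
                   thresholds=thresholds[::-1],
                   auc=interpolated_pr_auc(rec, prec))


def interpolated_pr_auc(recalls, precisions) -> float:
    """Area under the interpolated (upper-envelope) precision-recall curve.

    For every recall ``r`` the achievable precision is the best precision
    of any operating point with recall at least ``r`` — the standard
    interpolation for detection PR curves, which makes the area
    insensitive to degenerate extreme-threshold operating points (at a
    near-zero threshold all lesions merge into one component, so raw
    recall collapses even for a perfect detector).
    """
    rec = np.asarray(recalls, dtype=float)
    prec = np.asarray(precisions, dtype=float)
    order = np.argsort(rec, kind="stable")
    rec, prec = rec[order], prec[order]
    envelope = np.maximum.accumulate(prec[::-1])[::-1]
    return float(np.trapezoid(envelope, rec))
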