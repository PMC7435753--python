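"""Metric formulas, lesion matching and the precision-recall sweep."""

import numpy as np
import pytest

from nodulecascade.evaluation import (
    ConfusionCounts,
    accuracy,
    confusion_counts,
    dice_coefficient,
    match_lesions,
    pr_curve,
    sensitivity,
    specificity,
)
from nodulecascade.phantom import NoduleAnnotation, generate_phantom, rasterize_disc


def brute_force_counts(pred, gt):
    tp = fp = tn = fn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def test_perfect_prediction_counts():
    gt = np.zeros((4, 4), bool)
    gt.ravel()[:5] = True
    c = confusion_counts(gt, gt)
    assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 11, 0)


def test_inverted_prediction_has_no_true_counts():
    gt = np.random.default_rng(0).random((5, 5)) > 0.5
    c = confusion_counts(~gt, gt)
    assert c.tp == 0 and c.tn == 0


def test_counts_match_brute_force_enumeration(rng):
    pred = rng.random((4, 4)) > 0.4
    gt = rng.random((4, 4)) > 0.6
    c = confusion_counts(pred, gt)
    assert (c.tp, c.fp, c.tn, c.fn) == brute_force_counts(pred, gt)
    assert c.tp + c.fp + c.tn + c.fn == pred.size


def test_counts_reject_non_binary():
    with pytest.raises(ValueError):
        confusion_counts(np.full((2, 2), 0.5), np.zeros((2, 2)))


def test_metric_formulas():
    assert accuracy(ConfusionCounts(1, 1, 1, 1)) == pytest.approx(0.5)
    assert sensitivity(ConfusionCounts(tp=90, fn=10, fp=3, tn=7)) == pytest.approx(0.9)
    assert specificity(ConfusionCounts(tn=95, fp=5, tp=1, fn=1)) == pytest.approx(0.95)


def test_metrics_raise_on_zero_denominator():
    with pytest.raises(ZeroDivisionError):
        sensitivity(ConfusionCounts(tp=0, fn=0, fp=1, tn=1))
    with pytest.raises(ZeroDivisionError):
        specificity(ConfusionCounts(tp=1, fn=1, fp=0, tn=0))


def test_dice_coefficient_fixtures():
    gt = np.zeros((4, 4), bool)
    gt[:2, :2] = True
    assert dice_coefficient(gt, gt) == pytest.approx(1.0)
    other = np.zeros((4, 4), bool)
    other[2:, 2:] = True
    assert dice_coefficient(other, gt) == pytest.approx(0.0)
    half = np.zeros((4, 4), bool)
    half[0, :2] = half[3, :2] = True
    assert dice_coefficient(half, gt) == pytest.approx(0.5)
    with pytest.raises(ZeroDivisionError):
        dice_coefficient(np.zeros((2, 2), bool), np.zeros((2, 2), bool))


# -- lesion matching ---------------------------------------------------------

def test_ground_truth_rasterization_is_all_true_positives(default_params):
    s = generate_phantom(default_params, seed=5)
    c = match_lesions(s.nodule_mask, s.nodules)
    assert c.tp == len(s.nodules) and c.fp == 0 and c.fn == 0


def test_empty_prediction_is_all_false_negatives():
    anns = [NoduleAnnotation(5, 5, 4), NoduleAnnotation(10, 10, 4),
            NoduleAnnotation(15, 15, 4)]
    c = match_lesions(np.zeros((20, 20), bool), anns)
    assert c.fn == 3 and c.tp == 0 and c.fp == 0


def test_component_within_hit_radius_is_true_positive():
    ann = NoduleAnnotation(10, 10, 9)  # hit radius 4.5
    pred = rasterize_disc((21, 21), 11, 10, 5)  # centroid 1 px from center
    c = match_lesions(pred, [ann])
    assert c.tp == 1 and c.fp == 0 and c.fn == 0


def test_each_annotation_claims_one_component():
    ann = NoduleAnnotation(10, 10, 12)
    pred = rasterize_disc((21, 21), 8, 10, 3) | rasterize_disc((21, 21), 13, 10, 3)
    c = match_lesions(pred, [ann])
    assert c.tp == 1 and c.fp == 1  # second component is an over-detection


def test_far_component_is_false_positive():
    ann = NoduleAnnotation(5, 5, 4)
    pred = rasterize_disc((30, 30), 25, 25, 4)
    c = match_lesions(pred, [ann])
    assert c.tp == 0 and c.fp == 1 and c.fn == 1


# -- precision-recall curve --------------------------------------------------

def test_perfect_detector_has_unit_auc(default_params):
    samples = [generate_phantom(default_params, seed) for seed in range(4)]
    probs = [s.nodule_mask.astype(float) for s in samples]
    curve = pr_curve(probs, [s.nodule_mask for s in samples],
                     annotations_per_sample=[s.nodules for s in samples])
    assert curve.auc == pytest.approx(1.0)


def test_auc_equals_independent_envelope_reintegration(default_params):
    """AUC matches a brute-force re-integration of the stored pairs."""
    rng = np.random.default_rng(0)
    samples = [generate_phantom(default_params, seed) for seed in range(4)]
    probs = [np.clip(s.nodule_mask * 0.8 + rng.random(s.image.shape) * 0.3, 0, 1)
             for s in samples]
    curve = pr_curve(probs, [s.nodule_mask for s in samples],
                     annotations_per_sample=[s.nodules for s in samples])
    # brute force: best precision at recall >= r for every stored pair,
    # then trapezoid over recall
    pairs = sorted(zip(curve.recalls, curve.precisions))
    env = [max(p for r2, p in pairs if r2 >= r - 1e-12) for r, _ in pairs]
    recs = [r for r, _ in pairs]
    re_auc = np.trapezoid(env, recs)
    assert curve.auc == pytest.approx(re_auc)


def test_constant_probability_precision_approximates_prevalence(rng):
    """Pixel-level: an uninformative detector's precision is the prevalence."""
    gts = [rng.random((32, 32)) > 0.5 for _ in range(4)]
    probs = [np.full((32, 32), 0.6) for _ in range(4)]
    prevalence = np.mean([g.mean() for g in gts])
    curve = pr_curve(probs, gts, thresholds=np.linspace(0.1, 0.5, 5), level="pixel")
    assert np.allclose(curve.precisions[1:], prevalence, atol=0.05)


def test_recall_never_increases_with_threshold(default_params, rng):
    samples = [generate_phantom(default_params, seed) for seed in range(3)]
    probs = [np.clip(s.nodule_mask * rng.random(s.image.shape), 0, 1)
             for s in samples]
    curve = pr_curve(probs, [s.nodule_mask for s in samples],
                     annotations_per_sample=[s.nodules for s in samples])
    # thresholds stored descending, so recall must be non-decreasing
    assert np.all(np.diff(curve.recalls) >= -1e-12)


def test_pr_curve_rejects_bad_thresholds():
    with pytest.raises(ValueError):
        pr_curve([np.zeros((4, 4))], [np.zeros((4, 4), bool)],
                 thresholds=[0.0, 0.5])
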