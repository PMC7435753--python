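"""A reproducible desk-scale end-to-end study on synthetic phantoms.

Generates a seeded phantom population, trains the smallest cascade
configuration end to end on CPU, and scores the held-out samples at
pixel and lesion level.  The study conditions (200 training + 50 test
phantoms of 64x64 pixels, 20 epochs at batch 10, auxiliary per-stage
supervision, the small fixed perceptual extractor) are chosen so the
whole run completes in minutes on one CPU core while still exercising
every part of the pipeline: stage gating, the empty-mask dice branch,
lesion matching and the PR sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ConfusionCounts, confusion_counts, match_lesions, pr_curve, specificity
from .losses import LossWeights
from .networks import NoduleCascade, tiny_cascade_config
from .phantom import PhantomParams, generate_dataset
from .training import Hyperparameters, TrainingHistory, train

__all__ = ["StudyResult", "run_phantom_study"]


@dataclass
class StudyResult:
    """Held-out metrics of one end-to-end phantom study."""

    lesion_sensitivity: float
    lesion_tp: int
    lesion_fp: int
    lesion_fn: int
    pixel_specificity: float
    pixel_accuracy: float
    lesion_pr_auc: float
    mean_dice: float
    history: TrainingHistory
    n_train: int
    n_test: int


def run_phantom_study(seed: int, n_train: int = 200, n_test: int = 50,
                      epochs: int = 20, batch_size: int = 10,
                      params: PhantomParams | None = None,
                      threshold: float = 0.5) -> StudyResult:
    """Train the smallest cascade on seeded phantoms and score held-out ones.

    All randomness (phantom geometry, weight initialisation, batch order,
    the fixed perceptual extractor) derives from ``seed``.
    """
    params = params if params is not None else PhantomParams()
    train_set = generate_dataset(n_train, params, seed=seed, negative_fraction=0.3)
    test_set = generate_dataset(n_test, params, seed=seed + 100_000,
                                negative_fraction=0.3)

    cascade = NoduleCascade(tiny_cascade_config(seed=seed))
    hyper = Hyperparameters(learning_rate=1e-3, batch_size=batch_size,
                            epochs=epochs, loss_weights=LossWeights(),
                            seed=seed, validation_fraction=0.0,
                            aux_stage_weight=0.5, perceptual="small")
    history = train(cascade, train_set, hyper)

    probs = [cascade.predict(s.image).nodule_prob for s in test_set]
    lesion = ConfusionCounts()
    pixel = ConfusionCounts()
    dices = []
    for prob, s in zip(probs, test_set):
        pred = prob >= threshold
        lesion = lesion + match_lesions(pred, s.nodules)
        pixel = pixel + confusion_counts(pred, s.nodule_mask)
        if s.nodule_mask.sum() or pred.sum():
            inter = np.sum(pred & s.nodule_mask)
            dices.append(2.0 * inter / (pred.sum() + s.nodule_mask.sum()))
    curve = pr_curve(probs, [s.nodule_mask for s in test_set],
                     annotations_per_sample=[s.nodules for s in test_set])

    positives = lesion.tp + lesion.fn
    total_px = pixel.tp + pixel.fp + pixel.tn + pixel.fn
    return StudyResult(
        lesion_sensitivity=lesion.tp / positives if positives else float("nan"),
        lesion_tp=lesion.tp, lesion_fp=lesion.fp, lesion_fn=lesion.fn,
        pixel_specificity=specificity(pixel),
        pixel_accuracy=(pixel.tp + pixel.tn) / total_px,
        lesion_pr_auc=curve.auc,
        mean_dice=float(np.mean(dices)) if dices else float("nan"),
        history=history, n_train=n_train, n_test=n_test,
    )
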