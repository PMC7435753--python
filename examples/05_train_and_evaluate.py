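"""Train the smallest cascade on a small phantom set and score it.

A shortened version of the package's desk-scale study (fewer phantoms
and epochs, so it finishes in a few minutes; expect a weaker detector
than the full 200-phantom, 20-epoch study).  For the full study use
nodulecascade.study.run_phantom_study or scripts/acceptance.py.
"""

from nodulecascade import (
    ConfusionCounts,
    Hyperparameters,
    LossWeights,
    NoduleCascade,
    PhantomParams,
    confusion_counts,
    generate_dataset,
    match_lesions,
    specificity,
    tiny_cascade_config,
    train,
)

params = PhantomParams()
train_set = generate_dataset(100, params, seed=1, negative_fraction=0.3)
test_set = generate_dataset(10, params, seed=900, negative_fraction=0.3)

cascade = NoduleCascade(tiny_cascade_config(seed=1))
hyper = Hyperparameters(learning_rate=1e-3, batch_size=10, epochs=14,
                        loss_weights=LossWeights(), seed=1,
                        validation_fraction=0.0, aux_stage_weight=0.5)
history = train(cascade, train_set, hyper)
print("epoch losses:", [round(l, 3) for l in history.epoch_losses])

lesion = ConfusionCounts()
pixel = ConfusionCounts()
for s in test_set:
    pred = cascade.predict(s.image).nodule_prob >= 0.5
    lesion = lesion + match_lesions(pred, s.nodules)
    pixel = pixel + confusion_counts(pred, s.nodule_mask)
sens = lesion.tp / (lesion.tp + lesion.fn) if lesion.tp + lesion.fn else float("nan")
print(f"lesion TP {lesion.tp}  FP {lesion.fp}  FN {lesion.fn}  "
      f"sensitivity {sens:.2f}")
print(f"pixel specificity {specificity(pixel):.4f}")
# Sensitivity counts annotated nodules hit by a predicted component whose
# centroid falls within the nodule radius; specificity is per-pixel.
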