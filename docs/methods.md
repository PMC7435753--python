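# Methods

## The detection problem and the cascade

Pulmonary nodules are small, roughly circular bright lesions on chest CT
slices.  Detecting them is hard not because they are faint but because
they are *confusable*: vessel cross-sections, calcifications and
outside-lung structures (ribs, sternum) share their size and intensity.
The package decomposes detection into three map-to-map stages, each a
U-Net-like network, chained coarse-to-fine:

1. **Parenchyma segmentation** — nodules occur only inside the lung
   parenchyma, so stage 1 predicts a lung mask from the raw slice and
   removes all outside-lung confounders at once.  The network uses an
   inception stem (parallel 1×1 / factorized 1×3–3×1 branches, trailing
   1×1 projection) for multi-receptive-field features, and *dense*
   skip connections: every layer receives all shallower feature maps,
   resampled by their power-of-two resolution ratio (average pooling
   down, nearest-neighbour up) and channel-concatenated.
2. **Candidate detection** — on the parenchyma-gated image, stage 2
   flags every small bright inside-lung structure.  It is deliberately
   over-inclusive (vessels are in its ground truth).  All of its
   convolution blocks pair an inception module with a 3×3 dilation-2
   convolution; dilation widens the receptive field
   (n = k + (k−1)(d−1), so 3→5) without pooling away resolution.
   Decoder blocks append two dilation-2 convolutions after each
   stride-2 transposed convolution and skip concatenation.
3. **Nodule determination** — on the candidate-gated input (by default a
   2-channel stack: gated image + candidate probability), stage 3
   separates true nodules from vessels.  Its encoder alternates
   multi-resolution convolution blocks (three parallel routes: full
   resolution, rows halved, columns halved, each restored by an
   axis-wise transposed convolution; channels triple) with multi-scale
   pooling (four stride-2 convolutions of kernel 2/3/4/5, each
   projected to m/4 channels so the concatenation conserves m channels
   at half resolution).

The three networks are trained **as one network**: a single Adam
optimizer covers the union of their parameters, and the joint loss on
the final nodule map back-propagates through the stage boundaries.
Gating is *soft* during training (the image is multiplied by the
upstream probability map, keeping the composition differentiable) and
*hard* (thresholded at 0.5) at inference.

## The joint loss

`L_j = μ1·L_pix + μ2·L_perc + μ3·L_d` with defaults μ = (0.9, 0.9, 0.999):

* `L_pix` — mean squared error `(1/WH)‖F(y) − x‖²`.
* `L_perc` — squared distance between fixed deep features of prediction
  and ground truth, normalised by the feature map's spatial size (and
  the batch size, so the per-slice scale is batch-independent).
* `L_d` — soft dice `1 − 2Σpg/(Σp + Σg)` when the ground truth contains
  nodules; for empty ground truth (a negative slice) the dice is
  undefined, so the loss falls back to the prediction's pixel-normalised
  L1 magnitude.  The soft form coincides with the set-count dice on
  binary inputs and is differentiable; the L1 normalisation keeps the
  negative branch on the dice's [0, 1] scale.

**Perceptual extractor.** The canonical choice is the VGG-19
convolutional trunk tapped at its 12th convolution (conv-only counting;
a flag counts pooling layers instead).  This package uses *seeded random
fixed* weights for the extractor: a perceptual distance only needs a
fixed, deterministic feature map, and random convolutional features
preserve local image structure.  The default `small` topology (three
3×3 convolutions, widths 8/16/16, one 2×2 max-pool) gives the same kind
of signal at a fraction of the cost and is what CPU training uses;
`vgg19` is available when the full-depth features are wanted.
Grayscale inputs are replicated across the extractor's expected
channels.

## NumPy autodiff core

The networks run on a small reverse-mode automatic-differentiation core
(`nodulecascade.autograd`) written directly on NumPy: broadcasting
arithmetic, im2col-based 2D convolution and transposed convolution with
per-axis stride/padding/dilation, average/max pooling, nearest
up-sampling, a fused batch normalisation, and Adam.  Convolutions lower
to a single BLAS matmul per pass; im2col buffers are rebuilt during the
backward pass rather than retained, which keeps activation memory
proportional to the network itself.  Every primitive is checked against
central finite differences in the test suite.  All computation is
float32, which bounds gradient-check tolerances at ~1e-2.

## Synthetic phantoms

The phantom generator (`nodulecascade.phantom`) emulates exactly the
confusion structure the cascade targets, in 2D (the pipeline is
slice-wise):

* a bright thorax ellipse (tissue intensity 0.65) on a dark background;
* two dark lung fields (parenchyma intensity 0.15);
* 1–3 nodules per positive slice: discs of diameter 3–9 px at intensity
  0.85, strictly inside the parenchyma (the generator supports
  diameters up to 30 px at larger image sizes);
* vessel cross-sections and short vessel segments (intensity 0.55,
  width ~2 px) inside the lungs — candidates but never nodules;
* 1–3 bright blobs outside the lungs (rib/sternum mimics), excluded
  from every mask so the stage-1 gate is genuinely load-bearing;
* additive Gaussian noise (σ = 0.03), then clipping to [0, 1].

Masks satisfy `nodule ⊆ candidate ⊆ parenchyma` pixel-wise by
construction, nodules never overlap (connected components equal the
annotation count), and generation is bit-reproducible from `(params,
seed)`.  Negative slices (no nodules) make up a configurable fraction
of a dataset, 0.3 by default, so the empty-mask dice branch is
exercised during training.

**What the phantoms do not model:** CT texture and scanner physics, 3D
anatomy, partial-volume effects, and — importantly — truly ambiguous
lesions: phantom vessels differ from nodules in intensity and shape, so
a network that separates them here may still confuse real vessels with
real nodules.  Passing the phantom study demonstrates that the
pipeline's mechanics (gating, joint loss, end-to-end optimisation,
lesion scoring) work; it is not evidence of clinical performance.

## Evaluation

Pixel-level metrics tally per-pixel confusion counts; accuracy,
sensitivity and specificity are the usual ratios, raising on undefined
(zero-denominator) cases rather than silently returning 0.
Lesion-level scoring extracts 8-connected components of the binarised
map; a component hits an annotation when its centroid lies within the
annotation's radius (an IoU criterion is available), each annotation
claiming at most one component, greedily nearest-first.  Both levels
are reported, lesion-level as the headline.

The precision-recall curve sweeps thresholds from high to low.  Its
area uses the interpolated upper-envelope convention (best precision at
recall ≥ r): at near-zero thresholds all detections merge into one
component whose centroid misses every annotation, so the raw sweep's
tail is degenerate and the envelope is the meaningful summary.  A
(recall 0, precision 1) anchor closes the curve so a perfect detector
integrates to exactly 1.0.

## Training defaults and the desk-scale study

Full-scale defaults: learning rate 0.001, batch 40, 100 epochs,
μ = (0.9, 0.9, 0.999), weight decay 1e-4, Adam.  The validation split
is 80/20 by sample, seeded.  Gradients are clipped to a global L2 norm
of 5 before each step: a single spiking batch can otherwise contaminate
the shared Adam state and stall the remainder of a short training
budget.

The desk-scale study (`nodulecascade.study.run_phantom_study`) trains
the smallest cascade configuration — stage widths (8, 12, 16, 24) for
stages 1–2 and multi-resolution base 4 for stage 3 — on 200 phantoms of
64×64 px for 20 epochs at batch 10, with auxiliary per-stage losses
(stage 1 vs parenchyma mask, stage 2 vs candidate mask, weight 0.5)
enabled and the `small` perceptual extractor; 50 held-out phantoms are
scored at threshold 0.5.  These sizes were chosen as the smallest
population on which the cascade reliably converges to a clean detector
on one CPU core in a few minutes; auxiliary supervision is what makes
the 20-epoch budget sufficient, since without it stages 1–2 must be
learned implicitly through the gates.

## Numerical and design notes

* Output size follows the standard convention o = ⌊(i + 2p − n)/s⌋ + 1
  (padding *adds* to the input extent).
* Table'd architectures list four stride-2 decoder stages against three
  encoder reductions; the fourth decoder stage is implemented at full
  resolution (stride 1) so input and output sizes match.
* Inception branch widths: out/4 per branch (three branches, depths
  0/1/2 of factorized pairs) in the segmentation stem; out/2 (two
  branches, depths 0/1) in the candidate form.  No pooling branch.
* Multi-scale pooling pads each branch by ⌊(k−1)/2⌋ so all four
  branches emit ⌈i/2⌉ and concatenate exactly; all four branches use
  stride 2.
* ReLU + batch normalisation follow every convolution (configurable at
  the layer level); output heads are 1×1 convolutions with sigmoid.
* The three output heads start with bias −2 (initial probability
  ≈ 0.12): lesions cover a tiny fraction of a slice, and a background
  prior removes the early all-speckle phase, making convergence within
  a small epoch budget robust across seeds.
* Stage-3 input defaults to the 2-channel concat (gated image +
  candidate probability); multiply-only gating is available.
* Batch-norm running statistics make a training run's *forward* history
  non-repeatable across different batch sizes; with identical config
  and seed, trajectories are bit-reproducible on CPU.

## Known limitations

* No 3D context: a vessel seen end-on in a single slice is genuinely
  ambiguous; the real discriminator is often the adjacent slice.
* The NumPy core is single-threaded BLAS-bound; full-width (64–512
  channel) configurations are buildable and correct but impractical to
  train here — they exist for architecture fidelity and shape checks.
* The perceptual extractor's random weights are a fixed-feature stand-in
  chosen for offline reproducibility; pretrained features would likely
  weight lesion-like structure differently.
* Lesion matching is centroid-based; elongated false positives whose
  centroid happens to fall inside a nodule's radius count as hits.
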