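"""The joint training loss and its three components.

L_j = mu1*L_pix + mu2*L_perc + mu3*L_d with the default weights
(0.9, 0.9, 0.999).  The modified dice loss falls back to the prediction's
L1 magnitude when the ground truth is empty, so negative slices still
produce a gradient.
"""

import numpy as np

from nodulecascade import LossWeights, PerceptualExtractor, dice_loss, joint_loss, pixel_loss

rng = np.random.default_rng(0)
gt = np.zeros((32, 32), np.float32)
gt[10:14, 10:14] = 1  # a 4x4 "nodule"
pred = np.clip(gt + rng.normal(0, 0.1, gt.shape), 0, 1).astype(np.float32)

extractor = PerceptualExtractor(topology="small", seed=0)
print(f"pixel MSE:          {pixel_loss(pred, gt):.4f}")
print(f"dice loss:          {dice_loss(pred, gt):.4f}")
print(f"joint loss:         {joint_loss(pred, gt, LossWeights(), extractor):.4f}")

empty = np.zeros_like(gt)
print(f"dice on empty GT (L1 branch): {dice_loss(pred, empty):.4f}")
# The joint loss is 0 exactly when prediction equals ground truth:
print(f"joint at equality:  {joint_loss(gt, gt, LossWeights(), extractor):.4f}")
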