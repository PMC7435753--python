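"""Joint training loss: pixel-wise MSE + perceptual + modified dice.

``L_j = mu1 * L_pix + mu2 * L_perc + mu3 * L_d`` with

* ``L_pix``: mean squared error, ``(1/WH) ||F(y) - x||^2``;
* ``L_perc``: Euclidean distance between fixed deep features of the
  prediction and the ground truth, normalised by the feature map's
  spatial size ``W_i H_i``;
* ``L_d``: soft dice ``1 - 2|F(y) ∩ x| / (|F(y)| + |x|)`` for samples
  containing nodules, and the (pixel-normalised) L1 magnitude of the
  prediction for empty (negative) ground truth, so all-negative slices
  still carry a training signal.

Every loss accepts either plain NumPy arrays (returning a float) or
autograd tensors (returning a differentiable scalar tensor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Conv2d, Module, Tensor, max_pool2x2, relu

__all__ = [
    "LossWeights",
    "PerceptualExtractor",
    "pixel_loss",
    "perceptual_loss",
    "dice_loss",
    "combine_losses",
    "joint_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Loss normalisation coefficients (mu1, mu2, mu3); defaults 0.9, 0.9, 0.999."""

    mu1: float = 0.9
    mu2: float = 0.9
    mu3: float = 0.999

    def __post_init__(self):
        if min(self.mu1, self.mu2, self.mu3) < 0:
            raise ValueError("loss weights must be non-negative")


def _pair(pred, gt):
    """Promote to tensors; remember whether a plain float is wanted back."""
    plain = not (isinstance(pred, Tensor) or isinstance(gt, Tensor))
    p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=np.float32))
    g = gt if isinstance(gt, Tensor) else Tensor(np.asarray(gt, dtype=np.float32))
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g, plain


def _ret(t: Tensor, plain: bool):
    return float(t.data) if plain else t


def pixel_loss(pred, gt):
    """Mean squared error over all pixels."""
    p, g, plain = _pair(pred, gt)
    return _ret(((p - g) ** 2).mean(), plain)


def dice_loss(pred, gt):
    """Modified soft dice with an L1 branch for empty ground truth.

    Positive ground truth: ``1 - 2 sum(pred*gt) / (sum(pred) + sum(gt))``.
    Empty ground truth: mean absolute value of the prediction.
    """
    p, g, plain = _pair(pred, gt)
    gd = g.data
    if not np.isin(np.unique(gd), (0.0, 1.0)).all():
        raise ValueError("ground truth mask must be binary")
    if gd.sum() == 0:
        return _ret(p.abs().mean(), plain)
    inter = (p * g).sum()
    return _ret(1.0 - (2.0 * inter) / (p.sum() + g.sum()), plain)


class PerceptualExtractor(Module):
    """A fixed (non-trained) convolutional feature extractor.

    ``topology='small'`` (default): three 3x3 convolution layers
    (widths 8, 16, 16) with one 2x2 max-pool, operating on single-channel
    input — cheap enough to sit inside every CPU training step.

    ``topology='vgg19'``: the VGG-19 convolutional trunk tapped at its
    12th convolution layer (conv-only counting by default; set
    ``count_pooling=True`` to count pooling layers as well), with the
    grayscale input replicated to three channels.  Weights are seeded
    random and *fixed*: identical inputs always give identical features,
    which is all the perceptual distance needs.
    """

    _VGG = [64, 64, "P", 128, 128, "P", 256, 256, 256, 256, "P",
            512, 512, 512, 512, "P", 512, 512, 512, 512]

    def __init__(self, topology: str = "small", layer_index: int = 12,
                 count_pooling: bool = False, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.topology = topology
        self.layer_index = layer_index
        if topology == "small":
            self.in_channels = 1
            self.plan = [("conv", 1, 8), ("conv", 8, 16), ("pool",), ("conv", 16, 16)]
        elif topology == "vgg19":
            self.in_channels = 3
            plan, in_ch, n_layers = [], 3, 0
            for item in self._VGG:
                if item == "P":
                    plan.append(("pool",))
                    if count_pooling:
                        n_layers += 1
                else:
                    plan.append(("conv", in_ch, item))
                    in_ch = item
                    n_layers += 1
                if n_layers >= layer_index:
                    break
            self.plan = plan
        else:
            raise ValueError(f"unknown extractor topology {topology!r}")
        self.convs = [Conv2d(a, b, 3, padding=1, rng=rng)
                      for step in self.plan if step[0] == "conv"
                      for a, b in [step[1:]]]
        for p in self.parameters():
            p.requires_grad = False  # fixed features, never trained

    def features(self, x) -> Tensor:
        """Deep features of a (H, W), (C, H, W) or (N, C, H, W) image."""
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if t.ndim == 2:
            t = t.reshape(1, 1, *t.shape)
        elif t.ndim == 3:
            t = t.reshape(1, *t.shape)
        if t.shape[1] == 1 and self.in_channels > 1:
            from .autograd import concat
            t = concat([t] * self.in_channels, axis=1)
        elif t.shape[1] != self.in_channels:
            raise ValueError(
                f"extractor expects {self.in_channels} channels, got {t.shape[1]}")
        ci = 0
        for step in self.plan:
            if step[0] == "pool":
                t = max_pool2x2(t)
            else:
                t = relu(self.convs[ci](t))
                ci += 1
        return t

    forward = features


def perceptual_loss(pred, gt, extractor: PerceptualExtractor):
    """Normalised squared feature distance ``(1/W_i H_i) ||phi(pred) - phi(gt)||^2``."""
    p, g, plain = _pair(pred, gt)
    fp = extractor.features(p)
    fg = extractor.features(g)
    # normalised by the feature map's spatial size (and batch size, so
    # the per-slice scale is batch-independent)
    denom = fp.shape[0] * fp.shape[2] * fp.shape[3]
    return _ret(((fp - fg) ** 2).sum() * (1.0 / denom), plain)


def combine_losses(l_pix, l_perc, l_d, weights: LossWeights = LossWeights()):
    """The joint combination ``mu1*L_pix + mu2*L_perc + mu3*L_d``."""
    return weights.mu1 * l_pix + weights.mu2 * l_perc + weights.mu3 * l_d


def joint_loss(pred, gt, weights: LossWeights = LossWeights(),
               extractor: PerceptualExtractor | None = None):
    """Weighted sum of pixel, perceptual and dice losses.

    With ``extractor=None`` the perceptual term is dropped (equivalent to
    ``mu2 = 0``).
    """
    p, g, plain = _pair(pred, gt)
    l_perc = (perceptual_loss(p, g, extractor)
              if extractor is not None and weights.mu2 > 0 else 0.0)
    total = combine_losses(pixel_loss(p, g), l_perc, dice_loss(p, g), weights)
    return _ret(total, plain)
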