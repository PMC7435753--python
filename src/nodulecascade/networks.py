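"""The three cascaded sub-networks and their stage-to-stage gating.

Stage 1 (:class:`ParenchymaNet`) segments the lung parenchyma from the
raw slice: an inception stem at full resolution, three stride-2 encoder
stages with dense multi-rate skip concatenation, a mirrored decoder and
a sigmoid head.

Stage 2 (:class:`CandidateNet`) detects nodule candidates on the
parenchyma-gated image: a U-Net whose every encoder stage is an
inception + dilation-2 convolution block and whose decoder stages append
two dilation-2 convolutions after each transposed convolution.

Stage 3 (:class:`DeterminationNet`) separates true nodules from the
candidates: encoder alternating multi-resolution convolution blocks and
multi-scale pooling, a transposed-convolution decoder, sigmoid head.

The cascade feeds each stage the previous stage's output as a gate —
softly (multiplying by the probability map) during training so the joint
loss stays differentiable end to end, and hard (thresholded) at
inference.  By default stage 3 receives a 2-channel input: the
candidate-gated image stacked with the candidate probability map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Conv2d, ConvTranspose2d, BatchNorm2d, Module, Tensor, concat, relu, sigmoid
from .blocks import (
    ConvBNReLU,
    DilatedConvBlock,
    DilatedDeconvBlock,
    InceptionBlock,
    MultiResBlock,
    MultiScalePool,
    dense_resample_concat,
)

__all__ = [
    "CascadeConfig",
    "CascadeOutput",
    "ParenchymaNet",
    "CandidateNet",
    "DeterminationNet",
    "NoduleCascade",
    "build_parenchyma_net",
    "build_candidate_net",
    "build_determination_net",
    "apply_stage_gate",
    "tiny_cascade_config",
]


@dataclass
class CascadeConfig:
    """Architecture and gating hyper-parameters of the whole cascade.

    Default stage widths are 64/128/256/512 for stages 1-2;
    ``determination_base`` is the width ``c`` of the first
    multi-resolution block.
    """

    parenchyma_widths: tuple[int, ...] = (64, 128, 256, 512)
    candidate_widths: tuple[int, ...] = (64, 128, 256, 512)
    determination_base: int = 16
    gating_mode: str = "concat"  # stage-3 input: 'concat' (2-channel) | 'multiply'
    binarize_threshold: float = 0.5
    soft_gating: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.gating_mode not in ("concat", "multiply"):
            raise ValueError("gating_mode must be 'concat' or 'multiply'")


def tiny_cascade_config(seed: int = 0) -> CascadeConfig:
    """The smallest cascade configuration, used for desk-scale CPU studies."""
    return CascadeConfig(parenchyma_widths=(8, 12, 16, 24),
                         candidate_widths=(8, 12, 16, 24),
                         determination_base=4, seed=seed)


@dataclass
class CascadeOutput:
    """Per-stage probability maps, each at the input's spatial size."""

    parenchyma_prob: np.ndarray | Tensor
    candidate_prob: np.ndarray | Tensor
    nodule_prob: np.ndarray | Tensor

    def numpy(self) -> "CascadeOutput":
        def to_np(v):
            return v.data if isinstance(v, Tensor) else v
        return CascadeOutput(*(to_np(m) for m in
                               (self.parenchyma_prob, self.candidate_prob, self.nodule_prob)))


def _as_batch(image) -> Tensor:
    t = image if isinstance(image, Tensor) else Tensor(np.asarray(image, dtype=np.float32))
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(1, *t.shape)
    return t


def _init_detection_prior(head: Conv2d, bias: float = -2.0) -> None:
    """Bias the sigmoid head towards background.

    Lesions cover a tiny fraction of any slice, so starting the output
    probability near sigmoid(-2) ~ 0.12 instead of 0.5 removes the early
    all-speckle phase and lets the dice term lock onto lesions quickly.
    """
    if head.bias is not None:
        head.bias.data[:] = bias


def _check_divisible(t: Tensor, by: int = 8) -> None:
    if t.shape[2] % by or t.shape[3] % by:
        raise ValueError(f"input spatial dims must be divisible by {by}, got {t.shape[2:]}")


class ParenchymaNet(Module):
    """Inception-stem U-Net with dense multi-rate skip connections."""

    def __init__(self, widths=(64, 128, 256, 512), in_ch: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.widths = tuple(widths)
        w0, w1, w2, w3 = self.widths
        self.stem = InceptionBlock(in_ch, w0, "segmentation", rng=rng)
        # encoder: stride-2 convs on the dense concatenation of all
        # shallower features, resampled to the current resolution
        self.enc = [
            ConvBNReLU(w0, w1, 3, stride=2, padding=1, rng=rng),
            ConvBNReLU(w0 + w1, w2, 3, stride=2, padding=1, rng=rng),
            ConvBNReLU(w0 + w1 + w2, w3, 3, stride=2, padding=1, rng=rng),
        ]
        enc_sum = w0 + w1 + w2 + w3
        # decoder: three stride-2 transposed convs (densely fed by all
        # encoder and decoder features) plus one full-resolution
        # refinement stage, closing the resolution bookkeeping
        self.dec = [
            ConvTranspose2d(enc_sum, w3, 3, stride=2, padding=1, output_padding=1, rng=rng),
            ConvTranspose2d(enc_sum + w3, w2, 3, stride=2, padding=1, output_padding=1, rng=rng),
            ConvTranspose2d(enc_sum + w3 + w2, w1, 3, stride=2, padding=1, output_padding=1, rng=rng),
        ]
        self.dec_bn = [BatchNorm2d(w3), BatchNorm2d(w2), BatchNorm2d(w1)]
        self.refine = ConvBNReLU(enc_sum + w3 + w2 + w1, w0, 3, padding=1, rng=rng)
        self.head = Conv2d(w0, 1, 1, rng=rng)
        _init_detection_prior(self.head)

    def forward(self, x) -> Tensor:
        x = _as_batch(x)
        _check_divisible(x)
        feats = [self.stem(x)]
        for stage in self.enc:
            feats.append(stage(dense_resample_concat(feats, len(feats) - 1)))
        allf = list(feats)
        h = feats[-1]
        for up, bn in zip(self.dec, self.dec_bn):
            h = relu(bn(up(dense_resample_concat(allf, len(allf) - 1))))
            allf.append(h)
        h = self.refine(dense_resample_concat(allf, len(allf) - 1))
        return sigmoid(self.head(h))


class CandidateNet(Module):
    """U-Net with inception + dilated-convolution blocks throughout."""

    def __init__(self, widths=(64, 128, 256, 512), in_ch: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.widths = tuple(widths)
        w0, w1, w2, w3 = self.widths
        self.enc = [
            DilatedConvBlock(in_ch, w0, stride=1, rng=rng),
            DilatedConvBlock(w0, w1, stride=2, rng=rng),
            DilatedConvBlock(w1, w2, stride=2, rng=rng),
            DilatedConvBlock(w2, w3, stride=2, rng=rng),
        ]
        self.dec = [
            DilatedDeconvBlock(w3, w2, w2, rng=rng),
            DilatedDeconvBlock(w2, w1, w1, rng=rng),
            DilatedDeconvBlock(w1, w0, w0, rng=rng),
        ]
        # fourth decoder stage at full resolution (stride-1 refinement)
        self.refine = ConvBNReLU(w0, w0, 3, padding=2, dilation=2, rng=rng)
        self.head = Conv2d(w0, 1, 1, rng=rng)
        _init_detection_prior(self.head)

    def forward(self, x) -> Tensor:
        x = _as_batch(x)
        _check_divisible(x)
        skips = []
        h = x
        for stage in self.enc:
            h = stage(h)
            skips.append(h)
        for block, skip in zip(self.dec, reversed(skips[:-1])):
            h = block(h, skip)
        return sigmoid(self.head(self.refine(h)))


class DeterminationNet(Module):
    """Multi-resolution convolution + multi-scale pooling classifier network."""

    def __init__(self, base: int = 16, in_ch: int = 2, depth: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if (3 * base) % 4:
            raise ValueError("3*base must be divisible by 4 for multi-scale pooling")
        self.base = base
        self.stem = ConvBNReLU(in_ch, base, 3, padding=1, rng=rng)
        self.blocks = []
        c = base
        chans = []
        for _ in range(depth):
            mr = MultiResBlock(c, rng=rng)
            pool = MultiScalePool(3 * c, rng=rng)
            self.blocks.append((mr, pool))
            c = 3 * c
            chans.append(c)
        self.bottleneck = ConvBNReLU(c, c, 3, padding=1, rng=rng)
        self.ups = []
        for i in range(depth):
            out_c = chans[-i - 2] if i < depth - 1 else base
            self.ups.append((ConvTranspose2d(c, out_c, 3, stride=2, padding=1,
                                             output_padding=1, rng=rng),
                             BatchNorm2d(out_c)))
            c = out_c
        self.head = Conv2d(base, 1, 1, rng=rng)
        _init_detection_prior(self.head)

    def forward(self, x) -> Tensor:
        x = _as_batch(x)
        _check_divisible(x, by=2 ** len(self.blocks))
        h = self.stem(x)
        for mr, pool in self.blocks:
            h = pool(mr(h))
        h = self.bottleneck(h)
        for up, bn in self.ups:
            h = relu(bn(up(h)))
        return sigmoid(self.head(h))


def build_parenchyma_net(config: CascadeConfig) -> ParenchymaNet:
    rng = np.random.default_rng(config.seed)
    return ParenchymaNet(config.parenchyma_widths, rng=rng)


def build_candidate_net(config: CascadeConfig) -> CandidateNet:
    rng = np.random.default_rng(config.seed + 1)
    return CandidateNet(config.candidate_widths, rng=rng)


def build_determination_net(config: CascadeConfig) -> DeterminationNet:
    rng = np.random.default_rng(config.seed + 2)
    in_ch = 2 if config.gating_mode == "concat" else 1
    return DeterminationNet(config.determination_base, in_ch=in_ch, rng=rng)


def apply_stage_gate(image, prob, mode: str = "multiply", soft: bool = True,
                     threshold: float = 0.5):
    """Gate an image with the previous stage's probability map.

    ``multiply``: element-wise product of the image with the (soft or
    thresholded) map.  ``concat``: 2-channel stack of the gated image and
    the probability map.
    """
    img = _as_batch(image)
    prb = _as_batch(prob)
    if img.shape[2:] != prb.shape[2:]:
        raise ValueError(f"image/prob spatial mismatch: {img.shape[2:]} vs {prb.shape[2:]}")
    gate = prb if soft else Tensor((prb.data >= threshold).astype(np.float32))
    gated = img * gate
    if mode == "multiply":
        return gated
    if mode == "concat":
        return concat([gated, prb], axis=1)
    raise ValueError(f"unknown gating mode {mode!r}")


class NoduleCascade(Module):
    """The full three-stage detector trained as one end-to-end network."""

    def __init__(self, config: CascadeConfig | None = None):
        super().__init__()
        self.config = config if config is not None else CascadeConfig()
        self.parenchyma_net = build_parenchyma_net(self.config)
        self.candidate_net = build_candidate_net(self.config)
        self.determination_net = build_determination_net(self.config)

    def forward(self, image, soft: bool | None = None) -> CascadeOutput:
        """Run all three stages; soft gating defaults to the training mode."""
        x = _as_batch(image)
        _check_divisible(x)
        soft = self.training if soft is None else soft
        cfg = self.config
        p1 = self.parenchyma_net(x)
        g1 = apply_stage_gate(x, p1, "multiply", soft and cfg.soft_gating,
                              cfg.binarize_threshold)
        p2 = self.candidate_net(g1)
        stage3_in = apply_stage_gate(g1, p2, cfg.gating_mode,
                                     soft and cfg.soft_gating, cfg.binarize_threshold)
        p3 = self.determination_net(stage3_in)
        return CascadeOutput(p1, p2, p3)

    def predict(self, image) -> CascadeOutput:
        """Inference with hard gating; returns plain NumPy maps (H, W)."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(image, soft=False)
        finally:
            self.train(was_training)
        def squeeze(t):
            return t.data[0, 0]
        return CascadeOutput(squeeze(out.parenchyma_prob),
                             squeeze(out.candidate_prob),
                             squeeze(out.nodule_prob))


def cascade_forward(image, cascade: NoduleCascade) -> CascadeOutput:
    """Functional alias for :meth:`NoduleCascade.forward`."""
    return cascade(image)
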