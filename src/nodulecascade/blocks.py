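"""Building blocks of the cascaded nodule-detection networks.

Five bespoke blocks are implemented here, together with the dilated
convolution size algebra:

* :class:`InceptionBlock` — parallel factorized-kernel branches with 1x1
  bottlenecks and a trailing 1x1 projection; two variants (the parenchyma
  segmentation stem and the candidate-detection form).
* :func:`dense_resample_concat` — the dense skip connection: every earlier
  feature map is resampled by its power-of-two resolution ratio to the
  target and channel-concatenated.
* :class:`DilatedConvBlock` / :class:`DilatedDeconvBlock` — inception +
  dilation-2 convolution encoder blocks, and transposed-conv + skip-concat
  + two dilation-2 convolutions decoder blocks.
* :class:`MultiResBlock` — three parallel routes at full and axis-wise
  half resolution, restored by axis-wise transposed convolution and
  concatenated (channel tripling).
* :class:`MultiScalePool` — four parallel stride-2 convolutions with
  kernels 2/3/4/5, each projected to m/4 channels, concatenated back to m
  channels at half resolution.

The dilated kernel grows as ``n = k + (k-1)(d-1)`` and a convolution maps
a length-``i`` axis to ``o = floor((i + 2p - n)/s) + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Module,
    Tensor,
    avg_pool2d,
    concat,
    relu,
    upsample_nearest,
)

__all__ = [
    "BlockSpec",
    "effective_kernel_size",
    "conv_output_size",
    "InceptionBlock",
    "inception_forward",
    "dense_resample_concat",
    "DilatedConvBlock",
    "DilatedDeconvBlock",
    "MultiResBlock",
    "MultiScalePool",
    "ConvBNReLU",
]


@dataclass(frozen=True)
class BlockSpec:
    """Declarative description of a single convolution block.

    Fractional (0.5) strides are expressed as ``transposed=True`` with the
    corresponding integer stride.
    """

    kernel_rows: int = 3
    kernel_cols: int = 3
    in_channels: int = 1
    out_channels: int = 1
    stride: tuple[int, int] = (1, 1)
    dilation: int = 1
    padding: tuple[int, int] = (0, 0)
    transposed: bool = False

    def __post_init__(self):
        if self.kernel_rows < 1 or self.kernel_cols < 1:
            raise ValueError("kernel size must be >= 1")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.stride[0] < 1 or self.stride[1] < 1:
            raise ValueError("stride must be >= 1 per axis")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")


def effective_kernel_size(k: int, d: int) -> int:
    """Size of a kernel after dilation: ``n = k + (k-1)(d-1)``."""
    if k < 1 or d < 1:
        raise ValueError("kernel size and dilation must be positive")
    return k + (k - 1) * (d - 1)


def conv_output_size(i: int, spec: BlockSpec, axis: int = 0) -> int:
    """Spatial output size of a convolution along one axis.

    ``o = floor((i + 2p - n)/s) + 1`` with ``n`` the dilated kernel size.
    For a transposed spec the inverse relation
    ``o = (i - 1)s - 2p + n`` is used.
    """
    k = spec.kernel_rows if axis == 0 else spec.kernel_cols
    s = spec.stride[axis]
    p = spec.padding[axis]
    n = effective_kernel_size(k, spec.dilation)
    if spec.transposed:
        o = (i - 1) * s - 2 * p + n
        if o < 1:
            raise ValueError("padding exceeds transposed-convolution extent")
        return o
    if i + 2 * p < n:
        raise ValueError(
            f"effective kernel {n} exceeds padded input {i + 2 * p}"
        )
    return (i + 2 * p - n) // s + 1


class ConvBNReLU(Module):
    """Convolution followed by (optional) batch norm and ReLU."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, dilation=1,
                 rng=None, norm: bool = True, act: bool = True):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, padding, dilation, rng=rng)
        self.bn = BatchNorm2d(out_ch) if norm else None
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return relu(x) if self.act else x


class InceptionBlock(Module):
    """Parallel multi-receptive-field convolution with factorized kernels.

    ``variant='segmentation'``: three branches (1x1 bottleneck; bottleneck
    followed by one 1x3 -> 3x1 pair; bottleneck followed by two stacked
    pairs), each ``out_ch // 4`` wide, concatenated and projected by a
    trailing 1x1 convolution to ``out_ch`` channels.

    ``variant='candidate'``: two branches (1x1 bottleneck; bottleneck plus
    one factorized pair), each ``out_ch // 2`` wide, trailing 1x1 to
    ``out_ch``.

    Spatial size is preserved (all strides 1, "same" padding).
    """

    _DEPTHS = {"segmentation": (0, 1, 2), "candidate": (0, 1)}

    def __init__(self, in_ch: int, out_ch: int, variant: str = "segmentation",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if variant not in self._DEPTHS:
            raise ValueError(f"unknown inception variant {variant!r}")
        depths = self._DEPTHS[variant]
        bw = max(out_ch // 4, 1) if variant == "segmentation" else max(out_ch // 2, 1)
        self.variant = variant
        self.in_ch, self.out_ch = in_ch, out_ch
        self.branches = []
        for depth in depths:
            layers = [ConvBNReLU(in_ch, bw, 1, rng=rng)]
            for _ in range(depth):
                layers.append(ConvBNReLU(bw, bw, (1, 3), padding=(0, 1), rng=rng))
                layers.append(ConvBNReLU(bw, bw, (3, 1), padding=(1, 0), rng=rng))
            self.branches.append(layers)
        self.project = ConvBNReLU(bw * len(depths), out_ch, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"inception expects {self.in_ch} input channels, got {x.shape[1]}"
            )
        outs = []
        for layers in self.branches:
            h = x
            for layer in layers:
                h = layer(h)
            outs.append(h)
        return self.project(concat(outs, axis=1))


def inception_forward(x: Tensor, block: InceptionBlock) -> Tensor:
    """Functional alias for :meth:`InceptionBlock.forward`."""
    return block(x)


def _resample_to(x: Tensor, target_h: int, target_w: int) -> Tensor:
    """Average-pool down or nearest-neighbour up to the target size.

    Resolution ratios must be (axis-wise) integer powers of two.
    """
    h, w = x.shape[2], x.shape[3]
    if (h, w) == (target_h, target_w):
        return x

    def factor(a: int, b: int) -> int:
        big, small = max(a, b), min(a, b)
        if small == 0 or big % small:
            raise ValueError(f"resolution ratio {a}/{b} is not integer")
        f = big // small
        if f & (f - 1):
            raise ValueError(f"resolution ratio {f} is not a power of two")
        return f

    fh, fw = factor(h, target_h), factor(w, target_w)
    if h > target_h:
        return avg_pool2d(x, (fh, fw))
    return upsample_nearest(x, (fh, fw))


def dense_resample_concat(features: list[Tensor], target_index: int) -> Tensor:
    """Dense skip connection with multi-rate resampling.

    Every feature before ``target_index`` is resampled by the power-of-two
    ratio between its resolution and the target's, then all are
    channel-concatenated (output channels = sum of input channels).
    Features after the target index are ignored.  The same rule serves the
    decoder path, where earlier features are *up*-sampled.
    """
    if not features:
        raise ValueError("need at least one feature map")
    if not 0 <= target_index < len(features):
        raise IndexError("target_index out of range")
    target = features[target_index]
    th, tw = target.shape[2], target.shape[3]
    resampled = [_resample_to(f, th, tw) for f in features[: target_index]]
    resampled.append(target)
    if len(resampled) == 1:
        return target
    return concat(resampled, axis=1)


class DilatedConvBlock(Module):
    """Inception (candidate variant) followed by one 3x3 dilation-2 conv.

    With stride 1 and "same" padding the spatial size is preserved and the
    receptive field grows by 4 (effective kernel 5).  A stride of 2 in the
    trailing dilated convolution halves the resolution.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.inception = InceptionBlock(in_ch, out_ch, "candidate", rng=rng)
        self.dilated = ConvBNReLU(out_ch, out_ch, 3, stride=stride, padding=2,
                                  dilation=2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.dilated(self.inception(x))


class DilatedDeconvBlock(Module):
    """Stride-2 transposed conv, skip concatenation, two dilation-2 convs."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.up = ConvTranspose2d(in_ch, out_ch, 3, stride=2, padding=1,
                                  output_padding=1, rng=rng)
        self.bn_up = BatchNorm2d(out_ch)
        self.conv1 = ConvBNReLU(out_ch + skip_ch, out_ch, 3, padding=2, dilation=2, rng=rng)
        self.conv2 = ConvBNReLU(out_ch, out_ch, 3, padding=2, dilation=2, rng=rng)

    def forward(self, decoder_x: Tensor, skip_x: Tensor) -> Tensor:
        up = relu(self.bn_up(self.up(decoder_x)))
        if up.shape[2:] != skip_x.shape[2:]:
            raise ValueError(
                f"skip/decoder spatial mismatch: {skip_x.shape[2:]} vs {up.shape[2:]}"
            )
        return self.conv2(self.conv1(concat([up, skip_x], axis=1)))


class MultiResBlock(Module):
    """Multi-resolution feature concatenation (channel tripling).

    Three routes: stride (1,1) at c channels; stride (2,1) at 2c channels
    restored by a (2,1)-stride transposed convolution back to c channels;
    stride (1,2) likewise along columns.  Outputs concatenate to 3c
    channels at the input resolution.  Requires even spatial dims.
    """

    def __init__(self, in_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        c = in_ch
        self.in_ch = in_ch
        self.full = ConvBNReLU(c, c, 3, padding=1, rng=rng)
        self.half_rows = ConvBNReLU(c, 2 * c, 3, stride=(2, 1), padding=1, rng=rng)
        self.up_rows = ConvTranspose2d(2 * c, c, 3, stride=(2, 1), padding=1,
                                       output_padding=(1, 0), rng=rng)
        self.half_cols = ConvBNReLU(c, 2 * c, 3, stride=(1, 2), padding=1, rng=rng)
        self.up_cols = ConvTranspose2d(2 * c, c, 3, stride=(1, 2), padding=1,
                                       output_padding=(0, 1), rng=rng)
        self.bn_rows = BatchNorm2d(c)
        self.bn_cols = BatchNorm2d(c)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError("multi-resolution block needs even spatial dims")
        r1 = self.full(x)
        r2 = relu(self.bn_rows(self.up_rows(self.half_rows(x))))
        r3 = relu(self.bn_cols(self.up_cols(self.half_cols(x))))
        return concat([r1, r2, r3], axis=1)


class MultiScalePool(Module):
    """Four parallel stride-2 convolutions (kernels 2,3,4,5) as pooling.

    Each branch is projected by a 1x1 convolution to ``m/4`` channels so
    the concatenated output keeps ``m`` channels at half the spatial size.
    Per-branch padding floor((k-1)/2) makes all branches emit ceil(i/2).
    """

    KERNELS = (2, 3, 4, 5)

    def __init__(self, in_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        if in_ch % 4:
            raise ValueError("multi-scale pooling needs channels divisible by 4")
        self.in_ch = in_ch
        quarter = in_ch // 4
        self.scales = []
        self.reduces = []
        for k in self.KERNELS:
            pad = (k - 1) // 2
            self.scales.append(ConvBNReLU(in_ch, in_ch, k, stride=2, padding=pad, rng=rng))
            self.reduces.append(ConvBNReLU(in_ch, quarter, 1, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError("multi-scale pooling needs even spatial dims")
        outs = [red(sc(x)) for sc, red in zip(self.scales, self.reduces)]
        sizes = {o.shape[2:] for o in outs}
        assert len(sizes) == 1, "branch spatial sizes diverged"
        return concat(outs, axis=1)
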