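"""Block contracts: size algebra, dilated-kernel equivalence, channel bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodulecascade import autograd as ag
from nodulecascade.blocks import (
    BlockSpec,
    DilatedConvBlock,
    DilatedDeconvBlock,
    InceptionBlock,
    MultiResBlock,
    MultiScalePool,
    conv_output_size,
    dense_resample_concat,
    effective_kernel_size,
)


# -- dilated-convolution size algebra --------------------------------------

@pytest.mark.parametrize("k,d,n", [(3, 1, 3), (3, 2, 5), (5, 3, 13), (1, 7, 1)])
def test_effective_kernel_size(k, d, n):
    assert effective_kernel_size(k, d) == n


@pytest.mark.parametrize("bad", [(0, 1), (3, 0), (-1, 2)])
def test_effective_kernel_size_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        effective_kernel_size(*bad)


@pytest.mark.parametrize("i,k,d,p,s,o", [
    (8, 3, 2, 0, 1, 4),   # width-5 effective kernel has 4 placements on 8
    (8, 3, 2, 2, 1, 8),   # "same"-style padding
    (8, 1, 1, 0, 1, 8),   # identity kernel preserves size
])
def test_conv_output_size_examples(i, k, d, p, s, o):
    spec = BlockSpec(kernel_rows=k, kernel_cols=k, stride=(s, s),
                     dilation=d, padding=(p, p))
    assert conv_output_size(i, spec) == o


def test_conv_output_size_rejects_oversized_kernel():
    spec = BlockSpec(kernel_rows=5, kernel_cols=5, dilation=2, padding=(0, 0))
    with pytest.raises(ValueError):
        conv_output_size(6, spec)  # effective kernel 9 > 6


def test_conv_output_size_matches_executed_convolutions(rng):
    """The size formula agrees with real convolutions over a parameter grid."""
    for i in range(5, 17):
        for k in (1, 3, 5):
            for d in (1, 2, 3):
                for s in (1, 2):
                    for p in (0, 1, 2):
                        n = effective_kernel_size(k, d)
                        if i + 2 * p < n:
                            continue
                        spec = BlockSpec(kernel_rows=k, kernel_cols=k,
                                         stride=(s, s), dilation=d, padding=(p, p))
                        x = ag.Tensor(rng.random((1, 1, i, i), dtype=np.float32))
                        w = ag.Parameter(rng.random((1, 1, k, k), dtype=np.float32))
                        out = ag.conv2d(x, w, None, stride=s, padding=p, dilation=d)
                        assert out.shape[2] == conv_output_size(i, spec), (i, k, d, s, p)


def test_dilated_conv_equals_zero_inflated_standard_conv(rng):
    """A dilation-d convolution equals a standard conv with a zero-stuffed kernel."""
    for i in (7, 10, 12):
        for k, d in [(3, 2), (3, 3), (2, 2)]:
            n = effective_kernel_size(k, d)
            if n > i:
                continue
            x = ag.Tensor(rng.normal(size=(1, 1, i, i)).astype(np.float32))
            w = rng.normal(size=(1, 1, k, k)).astype(np.float32)
            inflated = np.zeros((1, 1, n, n), dtype=np.float32)
            inflated[:, :, ::d, ::d] = w
            out_dilated = ag.conv2d(x, ag.Tensor(w), None, dilation=d)
            out_standard = ag.conv2d(x, ag.Tensor(inflated), None)
            assert out_dilated.shape == out_standard.shape
            assert np.abs(out_dilated.data - out_standard.data).max() < 1e-5


# -- inception ---------------------------------------------------------------

def test_inception_segmentation_variant_projects_to_width(rng):
    block = InceptionBlock(1, 64, "segmentation", rng=rng)
    out = block(ag.Tensor(rng.random((1, 1, 16, 16), dtype=np.float32)))
    assert out.shape == (1, 64, 16, 16)


def test_inception_candidate_variant_preserves_channels(rng):
    block = InceptionBlock(16, 16, "candidate", rng=rng)
    out = block(ag.Tensor(rng.random((1, 16, 12, 12), dtype=np.float32)))
    assert out.shape == (1, 16, 12, 12)


def test_inception_rejects_channel_mismatch(rng):
    block = InceptionBlock(4, 8, "segmentation", rng=rng)
    with pytest.raises(ValueError):
        block(ag.Tensor(np.zeros((1, 5, 8, 8), np.float32)))


# -- dense resample concat ---------------------------------------------------

def test_dense_concat_downsamples_earlier_features_by_power_of_two(rng):
    """Channels add up and ratios are x8/x4/x2 for a four-level encoder."""
    base = 32
    feats = [ag.Tensor(rng.random((1, c, base // 2**j, base // 2**j),
                                  dtype=np.float32))
             for j, c in enumerate((64, 128, 256, 512))]
    out = dense_resample_concat(feats, target_index=3)
    assert out.shape == (1, 64 + 128 + 256 + 512, 4, 4)


def test_dense_concat_single_feature_is_identity(rng):
    f = ag.Tensor(rng.random((1, 3, 8, 8), dtype=np.float32))
    assert dense_resample_concat([f], 0) is f


def test_dense_concat_preserves_constants_under_downsampling():
    const = ag.Tensor(np.full((1, 2, 16, 16), 0.7, dtype=np.float32))
    target = ag.Tensor(np.zeros((1, 1, 4, 4), np.float32))
    out = dense_resample_concat([const, target], 1)
    assert np.allclose(out.data[:, :2], 0.7, atol=1e-6)


def test_dense_concat_upsamples_in_decoder_direction():
    low = ag.Tensor(np.full((1, 1, 4, 4), 2.0, dtype=np.float32))
    high = ag.Tensor(np.zeros((1, 1, 16, 16), np.float32))
    out = dense_resample_concat([low, high], 1)
    assert out.shape == (1, 2, 16, 16)
    assert np.allclose(out.data[:, 0], 2.0)


def test_dense_concat_rejects_non_power_of_two_ratio():
    a = ag.Tensor(np.zeros((1, 1, 12, 12), np.float32))
    b = ag.Tensor(np.zeros((1, 1, 4, 4), np.float32))
    with pytest.raises(ValueError):
        dense_resample_concat([a, b], 1)


# -- dilated conv/deconv blocks ----------------------------------------------

def test_dilated_conv_block_preserves_spatial_size(rng):
    block = DilatedConvBlock(8, 8, stride=1, rng=rng)
    out = block(ag.Tensor(rng.random((1, 8, 16, 16), dtype=np.float32)))
    assert out.shape == (1, 8, 16, 16)


def test_dilated_conv_block_stride2_halves(rng):
    block = DilatedConvBlock(4, 8, stride=2, rng=rng)
    out = block(ag.Tensor(rng.random((1, 4, 16, 16), dtype=np.float32)))
    assert out.shape == (1, 8, 8, 8)


def test_dilated_deconv_block_doubles_decoder_resolution(rng):
    block = DilatedDeconvBlock(16, 8, 8, rng=rng)
    dec = ag.Tensor(rng.random((1, 16, 8, 8), dtype=np.float32))
    skip = ag.Tensor(rng.random((1, 8, 16, 16), dtype=np.float32))
    out = block(dec, skip)
    assert out.shape == (1, 8, 16, 16)


def test_dilated_deconv_block_rejects_spatial_mismatch(rng):
    block = DilatedDeconvBlock(16, 8, 8, rng=rng)
    dec = ag.Tensor(rng.random((1, 16, 8, 8), dtype=np.float32))
    bad_skip = ag.Tensor(rng.random((1, 8, 12, 12), dtype=np.float32))
    with pytest.raises(ValueError):
        block(dec, bad_skip)


# -- multi-resolution and multi-scale blocks ----------------------------------

@settings(max_examples=10, deadline=None, derandomize=True)
@given(c=st.sampled_from([2, 4, 8]), size=st.sampled_from([8, 12, 16]))
def test_multires_block_triples_channels_at_input_resolution(c, size):
    rng = np.random.default_rng(1)
    block = MultiResBlock(c, rng=rng)
    out = block(ag.Tensor(rng.random((1, c, size, size), dtype=np.float32)))
    assert out.shape == (1, 3 * c, size, size)


def test_multires_block_rejects_odd_spatial_dims(rng):
    block = MultiResBlock(4, rng=rng)
    with pytest.raises(ValueError):
        block(ag.Tensor(np.zeros((1, 4, 15, 16), np.float32)))


def test_multires_half_resolution_route_shape(rng):
    """The stride-(2,1) route halves rows only before its restoration."""
    block = MultiResBlock(4, rng=rng)
    x = ag.Tensor(rng.random((1, 4, 16, 16), dtype=np.float32))
    inter = block.half_rows(x)
    assert inter.shape == (1, 8, 8, 16)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(m=st.sampled_from([8, 16, 64]), size=st.sampled_from([8, 16, 32]))
def test_multiscale_pool_conserves_channels_and_halves_size(m, size):
    rng = np.random.default_rng(2)
    block = MultiScalePool(m, rng=rng)
    out = block(ag.Tensor(rng.random((1, m, size, size), dtype=np.float32)))
    assert out.shape == (1, m, size // 2, size // 2)


def test_multiscale_pool_branch_contributes_quarter_channels(rng):
    block = MultiScalePool(64, rng=rng)
    x = ag.Tensor(rng.random((1, 64, 32, 32), dtype=np.float32))
    branch = block.reduces[0](block.scales[0](x))
    assert branch.shape == (1, 16, 16, 16)


def test_multiscale_pool_rejects_channels_not_divisible_by_four(rng):
    with pytest.raises(ValueError):
        MultiScalePool(10, rng=rng)


def test_blocks_are_deterministic_given_fixed_weights(rng):
    block = DilatedConvBlock(4, 8, rng=rng)
    block.eval()
    x = ag.Tensor(rng.random((1, 4, 16, 16), dtype=np.float32))
    assert np.array_equal(block(x).data, block(x).data)
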