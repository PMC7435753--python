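"""Cascade contracts: resolution closure, gating semantics, gradient flow."""

import numpy as np
import pytest

from nodulecascade.autograd import Tensor
from nodulecascade.losses import LossWeights, joint_loss
from nodulecascade.networks import (
    CascadeConfig,
    NoduleCascade,
    apply_stage_gate,
    build_candidate_net,
    build_determination_net,
    build_parenchyma_net,
    tiny_cascade_config,
)

TINY = tiny_cascade_config(seed=0)


@pytest.fixture(scope="module")
def cascade():
    return NoduleCascade(tiny_cascade_config(seed=0))


@pytest.fixture(scope="module")
def image():
    return np.random.default_rng(0).random((64, 64), dtype=np.float32)


# -- sub-network contracts ---------------------------------------------------

@pytest.mark.parametrize("builder,in_ch", [
    (build_parenchyma_net, 1),
    (build_candidate_net, 1),
    (build_determination_net, 2),
])
def test_subnetworks_map_to_unit_interval_at_input_resolution(builder, in_ch, rng):
    net = builder(TINY)
    x = Tensor(rng.random((1, in_ch, 32, 32), dtype=np.float32))
    out = net(x)
    assert out.shape == (1, 1, 32, 32)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0


def test_parenchyma_net_rejects_indivisible_input(rng):
    net = build_parenchyma_net(TINY)
    with pytest.raises(ValueError):
        net(Tensor(rng.random((1, 1, 30, 30), dtype=np.float32)))


def test_parenchyma_encoder_reaches_one_eighth_resolution():
    """Three stride-2 encoder stages: 64 -> 8; deepest width per config."""
    net = build_parenchyma_net(CascadeConfig())
    assert net.enc[-1].conv.out_ch == 512
    assert net.enc[-1].conv.stride == 2
    tiny_net = build_parenchyma_net(TINY)
    feats = [tiny_net.stem(Tensor(np.zeros((1, 1, 64, 64), np.float32)))]
    from nodulecascade.blocks import dense_resample_concat
    for stage in tiny_net.enc:
        feats.append(stage(dense_resample_concat(feats, len(feats) - 1)))
    assert feats[-1].shape[2:] == (8, 8)


def test_candidate_net_first_stage_full_resolution_dilation2():
    net = build_candidate_net(CascadeConfig())
    assert net.enc[0].dilated.conv.stride == 1
    assert all(stage.dilated.conv.dilation == 2 for stage in net.enc)
    assert [stage.dilated.conv.out_ch for stage in net.enc] == [64, 128, 256, 512]


def test_determination_net_halves_after_multires_pool_pair(rng):
    net = build_determination_net(TINY)
    x = Tensor(rng.random((1, 2, 64, 64), dtype=np.float32))
    mr, pool = net.blocks[0]
    h = pool(mr(net.stem(x)))
    assert h.shape[2:] == (32, 32)
    assert h.shape[1] == 3 * net.base  # channel tripling then conservation


# -- gating ------------------------------------------------------------------

def test_all_ones_gate_is_identity(image):
    gated = apply_stage_gate(image, np.ones_like(image), "multiply")
    assert np.allclose(gated.data[0, 0], image)


def test_all_zeros_gate_annihilates(image):
    gated = apply_stage_gate(image, np.zeros_like(image), "multiply")
    assert np.all(gated.data == 0)


def test_hard_gate_zeroes_subthreshold_pixels(image):
    prob = np.full_like(image, 0.4)
    prob[:10] = 0.9
    gated = apply_stage_gate(image, prob, "multiply", soft=False, threshold=0.5)
    assert np.all(gated.data[0, 0, 10:] == 0)
    assert np.allclose(gated.data[0, 0, :10], image[:10])


def test_concat_gate_stacks_two_channels(image):
    prob = np.full_like(image, 0.7)
    out = apply_stage_gate(image, prob, "concat")
    assert out.shape == (1, 2, 64, 64)
    assert np.allclose(out.data[0, 1], 0.7, atol=1e-6)


def test_gate_monotonicity(image, rng):
    """A pixel-wise smaller parenchyma gate never increases stage-2 input."""
    big = rng.random(image.shape, dtype=np.float32)
    small = big * rng.random(image.shape, dtype=np.float32)
    g_big = apply_stage_gate(image, big, "multiply").data
    g_small = apply_stage_gate(image, small, "multiply").data
    assert np.all(g_small <= g_big + 1e-7)


def test_gate_rejects_dimension_mismatch(image):
    with pytest.raises(ValueError):
        apply_stage_gate(image, np.ones((32, 32), np.float32), "multiply")


# -- cascade -----------------------------------------------------------------

def test_cascade_emits_three_input_sized_maps(cascade, image):
    out = cascade.predict(image)
    for m in (out.parenchyma_prob, out.candidate_prob, out.nodule_prob):
        assert m.shape == image.shape
        assert m.min() >= 0.0 and m.max() <= 1.0


def test_zero_parenchyma_gate_blanks_stage2_input(cascade, image):
    gated = apply_stage_gate(image, np.zeros_like(image), "multiply", soft=False)
    assert np.all(gated.data == 0)
    out = cascade.candidate_net(gated)
    assert out.shape == (1, 1, 64, 64)


def test_forced_ones_stage1_passes_raw_image(image):
    gated = apply_stage_gate(image, np.ones_like(image), "multiply", soft=False)
    assert np.array_equal(gated.data[0, 0], image)


def test_cascade_gradients_reach_all_three_subnetworks(cascade, image):
    """One end-to-end step populates a gradient for every parameter."""
    cascade.train()
    cascade.zero_grad()
    gt = Tensor(np.zeros((1, 1, 64, 64), np.float32))
    out = cascade(Tensor(image))
    loss = joint_loss(out.nodule_prob, gt, LossWeights(0.9, 0.0, 0.999))
    loss.backward()
    params = cascade.parameters()
    assert params and all(p.grad is not None for p in params)
    for net in (cascade.parenchyma_net, cascade.candidate_net,
                cascade.determination_net):
        assert all(p.grad is not None for p in net.parameters())


def test_soft_gating_keeps_finite_gradients(cascade, image):
    cascade.train()
    cascade.zero_grad()
    out = cascade(Tensor(image))
    loss = joint_loss(out.nodule_prob, Tensor(np.zeros((1, 1, 64, 64), np.float32)),
                      LossWeights(0.9, 0.0, 0.999))
    loss.backward()
    assert all(np.isfinite(p.grad).all() for p in cascade.parameters())


def test_config_validation():
    with pytest.raises(ValueError):
        CascadeConfig(binarize_threshold=1.5)
    with pytest.raises(ValueError):
        CascadeConfig(gating_mode="sum")
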