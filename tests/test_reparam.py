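"""Reparameterization: every fusion step checked against the direct
multibranch forward pass."""

import numpy as np
import pytest

from cattlepose.nn import Sequential, Tensor, no_grad, seed_init
from cattlepose.nn import autograd as ag
from cattlepose.reparam import (BNParams, ConvKernel, FusionStateError,
                                InvalidBNError, RepBlock, RepVGGBlock,
                                embed_1x1_in_3x3, fuse_conv_bn,
                                identity_as_3x3, reparameterize_network)


def _conv(x, kernel: ConvKernel, bias=None):
    y = ag.conv2d(Tensor(x.astype(np.float32)),
                  Tensor(kernel.weights.astype(np.float32)),
                  None if bias is None else Tensor(bias.astype(np.float32)),
                  stride=kernel.stride, padding=kernel.padding,
                  groups=kernel.groups)
    return y.data


def _bn_apply(y, bn: BNParams):
    std = np.sqrt(bn.running_var + bn.eps)
    return (bn.gamma[:, None, None] * (y - bn.running_mean[:, None, None])
            / std[:, None, None] + bn.beta[:, None, None])


class TestFuseConvBN:
    def test_identity_normalization(self, rng):
        k = ConvKernel(rng.normal(size=(4, 3, 3, 3)), padding=1)
        bn = BNParams(np.ones(4), np.zeros(4), np.zeros(4), np.ones(4), eps=0.0)
        fused, bias = fuse_conv_bn(k, bn)
        assert np.allclose(fused.weights, k.weights)
        assert np.allclose(bias, 0.0)

    def test_pure_affine_scale(self, rng):
        k = ConvKernel(rng.normal(size=(4, 3, 3, 3)), padding=1)
        bn = BNParams(2 * np.ones(4), 3 * np.ones(4), np.zeros(4), np.ones(4),
                      eps=0.0)
        fused, bias = fuse_conv_bn(k, bn)
        assert np.allclose(fused.weights, 2 * k.weights)
        assert np.allclose(bias, 3.0)

    def test_forward_equivalence_random(self, rng):
        k = ConvKernel(rng.normal(size=(4, 4, 3, 3)), padding=1)
        bn = BNParams(rng.uniform(0.5, 2, 4), rng.normal(size=4),
                      rng.normal(size=4), rng.uniform(0.1, 2, 4))
        x = rng.normal(size=(1, 4, 8, 8))
        ref = _bn_apply(_conv(x, k)[0], bn)
        fused, bias = fuse_conv_bn(k, bn)
        out = _conv(x, fused, bias)[0]
        assert np.abs(out - ref).max() < 1e-5

    def test_negative_variance_rejected(self):
        with pytest.raises(InvalidBNError):
            BNParams(np.ones(2), np.zeros(2), np.zeros(2), np.array([1.0, -0.1]))

    def test_length_mismatch_rejected(self, rng):
        k = ConvKernel(rng.normal(size=(4, 3, 3, 3)))
        with pytest.raises(InvalidBNError):
            fuse_conv_bn(k, BNParams(np.ones(3), np.zeros(3), np.zeros(3),
                                     np.ones(3)))


class TestEmbedAndIdentity:
    def test_embed_structure(self, rng):
        k1 = ConvKernel(rng.normal(size=(2, 3, 1, 1)))
        k3 = embed_1x1_in_3x3(k1)
        assert k3.weights.shape == (2, 3, 3, 3)
        assert np.allclose(k3.weights[:, :, 1, 1], k1.weights[:, :, 0, 0])
        center = k3.weights.copy()
        center[:, :, 1, 1] = 0
        assert np.allclose(center, 0.0)

    def test_embed_zero_kernel_and_bad_size(self, rng):
        assert np.allclose(embed_1x1_in_3x3(
            ConvKernel(np.zeros((2, 2, 1, 1)))).weights, 0.0)
        with pytest.raises(ValueError):
            embed_1x1_in_3x3(ConvKernel(np.zeros((2, 2, 3, 3))))

    def test_embed_forward_equivalence(self, rng):
        k1 = ConvKernel(rng.normal(size=(3, 2, 1, 1)), padding=0)
        x = rng.normal(size=(1, 2, 6, 6))
        assert np.abs(_conv(x, embed_1x1_in_3x3(k1)) - _conv(x, k1)).max() < 1e-6

    @pytest.mark.parametrize("channels,groups", [(2, 1), (4, 4), (4, 2)])
    def test_identity_kernel_is_identity(self, rng, channels, groups):
        kid = identity_as_3x3(channels, groups)
        x = rng.normal(size=(1, channels, 5, 5))
        assert np.abs(_conv(x, kid) - x).max() < 1e-6

    def test_identity_structure_and_errors(self):
        kid = identity_as_3x3(2, 1)
        assert kid.weights.shape == (2, 2, 3, 3)
        assert kid.weights.sum() == 2.0
        with pytest.raises(ValueError):
            identity_as_3x3(3, 2)


def _warm_bn(module, rng, channels, steps=3):
    """Run training-mode forwards so running statistics are realistic."""
    module.train()
    for _ in range(steps):
        module(Tensor(rng.normal(size=(4, channels, 8, 8)).astype(np.float32)))
    module.eval()


class TestUnitFusion:
    def test_full_unit_forward_equivalence(self, rng):
        seed_init(7)
        blk = RepVGGBlock(4, 4)
        _warm_bn(blk, rng, 4)
        xs = [rng.normal(size=(2, 4, 8, 8)).astype(np.float32) for _ in range(100)]
        with no_grad():
            refs = [blk(Tensor(x)).data for x in xs]
            blk.fuse()
            outs = [blk(Tensor(x)).data for x in xs]
        dev = max(np.abs(r - o).max() for r, o in zip(refs, outs))
        assert dev < 1e-5

    def test_zero_pointwise_no_identity_equals_dense_fusion(self, rng):
        seed_init(8)
        blk = RepVGGBlock(3, 5)  # in != out: no identity branch
        assert not blk.has_identity
        blk.pointwise.weight.data[:] = 0.0
        _warm_bn(blk, rng, 3)
        # pointwise BN of a zero conv output contributes only its bias shift
        weights, bias = blk.fused_kernel()
        from cattlepose.reparam import fuse_conv_bn as fcb
        k, b = fcb(ConvKernel(blk.dense.weight.data, 1, 1),
                   BNParams(blk.dense_bn.weight.data, blk.dense_bn.bias.data,
                            blk.dense_bn.running_mean, blk.dense_bn.running_var,
                            blk.dense_bn.eps))
        assert np.allclose(weights, k.weights, atol=1e-6)

    def test_parameter_count_decreases_and_matches_formula(self, rng):
        blk = RepVGGBlock(6, 6)
        before = blk.num_parameters()
        _warm_bn(blk, rng, 6)
        blk.fuse()
        after = blk.num_parameters()
        assert after < before
        assert after == 6 * 6 * 9 + 6  # out*in*9 + bias

    def test_fusion_state_errors(self, rng):
        blk = RepVGGBlock(2, 2)
        with pytest.raises(FusionStateError):
            blk.fuse()  # training mode
        blk.eval()
        blk.fuse()
        with pytest.raises(FusionStateError):
            blk.fuse()


class TestNetworkFusion:
    def test_stacked_units_equivalence(self, rng):
        seed_init(9)
        net = Sequential(RepVGGBlock(3, 8, stride=2), RepVGGBlock(8, 8))
        net.train()
        for _ in range(3):
            net(Tensor(rng.normal(size=(2, 3, 16, 16)).astype(np.float32)))
        net.eval()
        x = Tensor(rng.normal(size=(1, 3, 16, 16)).astype(np.float32))
        with no_grad():
            ref = net(x).data
            reparameterize_network(net)
            out = net(x).data
        assert np.abs(ref - out).max() < 1e-4

    def test_no_units_is_noop_and_double_fusion_rejected(self, rng):
        from cattlepose.nn import Conv2d
        plain = Sequential(Conv2d(3, 4, 3, padding=1))
        plain.eval()
        reparameterize_network(plain)  # no-op, no error
        net = Sequential(RepVGGBlock(2, 2))
        net.eval()
        reparameterize_network(net)
        with pytest.raises(FusionStateError):
            reparameterize_network(net)

    def test_training_mode_rejected(self):
        net = Sequential(RepVGGBlock(2, 2))
        with pytest.raises(FusionStateError):
            reparameterize_network(net)

    def test_repblock_shapes_and_depth(self, rng):
        rb = RepBlock(4, 8, n=3)
        assert len(rb.units.layers) == 3
        rb.eval()
        with no_grad():
            y = rb(Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32)))
        assert y.shape == (1, 8, 8, 8)
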