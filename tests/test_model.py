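"""ECA operations, shape contracts and gradient-flow of the network."""

import numpy as np
import pytest
from scipy.special import expit

from tideseg import harness
from tideseg.errors import ConfigError, InputError, ShapeError
from tideseg.model import (
    EcaConfig,
    ModelConfig,
    SegmentationModel,
    adaptive_kernel_size,
    channel_descriptor,
    channel_weights,
    fuse_shallow,
    normalize_composite,
    recalibrate,
)
from tideseg.nn import functional as F
from tideseg.nn.tensor import Tensor


class TestAdaptiveKernel:
    @pytest.mark.parametrize("channels,expected", [
        (64, 5),    # shallow stage C1
        (128, 5),   # shallow stage C2
        (2, 3),     # nearest odd to 1.5 is 1, floored at 3
        (32, 3),
        (320, 5),
        (512, 5),
    ])
    def test_values(self, channels, expected):
        assert adaptive_kernel_size(channels, gamma=2, b=1) == expected

    def test_tie_rounds_upward(self):
        # C=64: log2/2+1 = 4.0 is equidistant from 3 and 5 -> 5
        assert adaptive_kernel_size(64) == 5

    def test_monotone_in_channels(self):
        ks = [adaptive_kernel_size(c) for c in range(1, 2049)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))
        assert all(k % 2 == 1 and k >= 3 for k in ks)

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            adaptive_kernel_size(0)
        with pytest.raises(ConfigError):
            adaptive_kernel_size(8, gamma=0)


class TestEcaFunctional:
    def test_descriptor_is_spatial_mean(self, rng):
        f = rng.standard_normal((4, 6, 3))
        np.testing.assert_allclose(channel_descriptor(f), f.mean(axis=(0, 1)))
        np.testing.assert_allclose(
            channel_descriptor(np.full((2, 2, 1), 7.0)), [7.0])
        np.testing.assert_allclose(
            channel_descriptor(np.array([[[0.], [0.]], [[2.], [2.]]])), [1.0])
        one_pixel = rng.standard_normal((1, 1, 5))
        np.testing.assert_allclose(channel_descriptor(one_pixel), one_pixel[0, 0])

    def test_descriptor_rejects_empty(self):
        with pytest.raises(InputError):
            channel_descriptor(np.empty((0, 0, 3)))

    def test_weights_zero_kernel_and_zero_input(self, rng):
        z = rng.standard_normal(8)
        np.testing.assert_allclose(channel_weights(z, 3, np.zeros(3)), 0.5)
        np.testing.assert_allclose(
            channel_weights(np.zeros(8), 5, rng.standard_normal(5)), 0.5)

    def test_weights_identity_kernel(self):
        z = np.array([1.0, 2.0, 3.0])
        s = channel_weights(z, 3, np.array([0.0, 1.0, 0.0]))
        np.testing.assert_allclose(s, expit(z))

    def test_weights_bounded_and_odd_only(self, rng):
        s = channel_weights(rng.standard_normal(16) * 3, 5, rng.standard_normal(5))
        assert ((s > 0) & (s < 1)).all()
        extreme = channel_weights(rng.standard_normal(16) * 1e4, 5, rng.standard_normal(5))
        assert ((extreme >= 0) & (extreme <= 1)).all()
        with pytest.raises(ConfigError):
            channel_weights(np.zeros(4), 4, np.zeros(4))

    def test_recalibrate(self, rng):
        f = rng.standard_normal((4, 4, 2))
        out = recalibrate(f, np.array([0.5, 2.0]))
        np.testing.assert_allclose(out[..., 0], f[..., 0] * 0.5)
        np.testing.assert_allclose(out[..., 1], f[..., 1] * 2.0)
        np.testing.assert_allclose(recalibrate(f, np.ones(2)), f)
        assert (recalibrate(f, np.zeros(2)) == 0).all()
        with pytest.raises(ShapeError):
            recalibrate(f, np.ones(3))

    def test_recalibrate_shrinks_for_sigmoid_weights(self, rng):
        f = rng.standard_normal((5, 5, 4))
        s = expit(rng.standard_normal(4))
        assert (np.abs(recalibrate(f, s)) <= np.abs(f) + 1e-12).all()

    def test_eca_layer_matches_functional_composition(self, rng):
        """The trained layer equals descriptor -> conv -> sigmoid -> rescale."""
        from tideseg.model import EcaLayer
        layer = EcaLayer(8, EcaConfig(), rng=np.random.default_rng(0))
        x = rng.standard_normal((1, 8, 4, 4)).astype(np.float32)
        out = layer(Tensor(x)).data[0].transpose(1, 2, 0)
        f_hwc = x[0].transpose(1, 2, 0)
        z = channel_descriptor(f_hwc)
        s = channel_weights(z, layer.kernel_size, layer.conv.weight.data)
        np.testing.assert_allclose(out, recalibrate(f_hwc, s), rtol=1e-5, atol=1e-6)


@pytest.fixture(scope="module")
def micro_model():
    return SegmentationModel(ModelConfig.from_variant("micro"), seed=0)


class TestShapes:
    def test_pyramid_contract(self, micro_model, rng):
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        pyr = micro_model.encode(x)
        chans = micro_model.config.stage_channels
        for feat, stride, c in zip(pyr, (4, 8, 16, 32), chans):
            assert feat.shape == (1, c, 64 // stride, 64 // stride)

    def test_forward_pair_shapes(self, micro_model, rng):
        x = Tensor(rng.standard_normal((2, 3, 64, 64)).astype(np.float32))
        pair = micro_model(x)
        assert pair.seg_logits.shape == (2, 2, 64, 64)
        assert pair.boundary_logits.shape == (2, 1, 64, 64)

    def test_non_divisible_or_bad_channels_rejected(self, micro_model, rng):
        with pytest.raises(InputError):
            micro_model(Tensor(rng.standard_normal((1, 3, 60, 60))))
        with pytest.raises(InputError):
            micro_model(Tensor(rng.standard_normal((1, 2, 64, 64))))

    def test_fuse_shallow_shapes(self, rng):
        c1 = Tensor(rng.standard_normal((1, 64, 16, 16)))
        c2 = Tensor(rng.standard_normal((1, 128, 8, 8)))
        fused = fuse_shallow(c1, c2)
        assert fused.shape == (1, 192, 16, 16)
        with pytest.raises(ShapeError):
            fuse_shallow(c1, Tensor(rng.standard_normal((1, 128, 16, 16))))

    def test_boundary_head_shapes_and_relu(self, rng):
        from tideseg.model import BoundaryBranch
        branch = BoundaryBranch(192, 64, np.random.default_rng(0))
        fused = Tensor(rng.standard_normal((1, 192, 8, 8)).astype(np.float32))
        out = branch(fused, 64)
        assert out.shape == (1, 1, 64, 64)
        hidden = branch.bn(branch.conv3(fused)).relu()
        assert (hidden.data >= 0).all()
        with pytest.raises(ConfigError):
            branch(fused, 4)

    def test_inference_deterministic(self, micro_model, rng):
        img = rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
        seg1, bnd1 = micro_model.predict(img)
        seg2, bnd2 = micro_model.predict(img)
        np.testing.assert_array_equal(seg1, seg2)
        np.testing.assert_array_equal(bnd1, bnd2)

    def test_zero_classifier_gives_zero_logits(self, rng):
        model = SegmentationModel(ModelConfig.from_variant("micro"), seed=1)
        model.decoder.classifier.weight.data[:] = 0.0
        model.decoder.classifier.bias.data[:] = 0.0
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        pair = model(x)
        np.testing.assert_allclose(pair.seg_logits.data, 0.0)


class TestGradientFlow:
    def test_boundary_loss_reaches_eca_weights(self, rng):
        """With L_seg zeroed, ECA kernels still receive boundary-loss gradient."""
        model = SegmentationModel(ModelConfig.from_variant("micro"), seed=2)
        x = Tensor(rng.standard_normal((2, 3, 64, 64)).astype(np.float32))
        pair = model(x)
        target = rng.integers(0, 2, size=(2, 1, 64, 64)).astype(float)
        loss = F.bce_with_logits(pair.boundary_logits, target)
        loss.backward()
        for stage in (1, 2):
            g = model.eca_layer(stage).conv.weight.grad
            assert g is not None and np.abs(g).sum() > 0

    def test_parameter_delta_of_eca(self):
        """ECA on stages {1,2} with k=5 kernels adds exactly 10 parameters."""
        base = ModelConfig.from_variant("b2", eca=None, boundary_branch=False)
        with_eca = ModelConfig.from_variant("b2", boundary_branch=False)
        n0 = SegmentationModel(base, seed=0).num_parameters()
        model = SegmentationModel(with_eca, seed=0)
        assert model.eca_layer(1).kernel_size == 5
        assert model.eca_layer(2).kernel_size == 5
        assert model.num_parameters() - n0 == 10

    def test_boundary_branch_parameter_count(self):
        """3x3 conv(192->64, no bias) + BN(64) + biased 1x1 conv = 110,785."""
        cfg = ModelConfig.from_variant("b2")
        model = SegmentationModel(cfg, seed=0)
        table = harness.count_parameters(model)
        row = table.set_index("module").loc["boundary_branch", "parameters"]
        assert row == 110_785


class TestConfig:
    def test_variant_roundtrip(self):
        cfg = ModelConfig.from_variant("tiny", boundary_branch=False)
        cfg2 = ModelConfig.from_dict(cfg.to_dict())
        assert cfg == cfg2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            EcaConfig(active_stages=())
        with pytest.raises(ConfigError):
            EcaConfig(active_stages=(5,))
        with pytest.raises(ConfigError):
            ModelConfig.from_variant("b2", stage_channels=(64, 64, 320, 512))
        with pytest.raises(ConfigError):
            ModelConfig.from_variant("nope")

    def test_normalize_composite_range(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        x = normalize_composite(img)
        assert x.shape == (3, 32, 32)
        assert x.min() >= -1.0 and x.max() <= 1.0
        with pytest.raises(InputError):
            normalize_composite(img[..., :2])
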