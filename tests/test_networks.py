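import numpy as np
import pytest

from roigan import networks as nw
from roigan import nn


class TestSpecs:
    def test_rfb_layer_census(self):
        spec = nw.build_rfb_spec(64, 8)
        census = spec.layer_census()
        assert census["mirror_pad"] == 2
        assert census["conv"] == 3
        assert census["deconv"] == 1

    def test_discriminator_layer_census(self):
        spec = nw.build_discriminator_spec(64)
        census = spec.layer_census()
        assert census["conv"] == 4
        assert census["flatten"] == 1
        assert census["dense"] == 1
        sigmoids = [l for l in spec.layers
                    if l.kind == "activation" and l.activation_name == "sigmoid"]
        assert len(sigmoids) == 1

    def test_generator_shape_anchors_at_256(self):
        spec = nw.build_generator_spec(256, 9)
        trace = nw.shape_trace(spec)
        assert trace[0][1:] == (262, 262)          # 3-pixel mirror pad
        assert trace[9] == (128, 64, 64)           # bottleneck after conv3
        assert trace[-1] == (1, 256, 256)          # restored to input size

    def test_generator_size_must_divide_by_four(self):
        with pytest.raises(ValueError, match="divisible"):
            nw.build_generator_spec(66, 1)

    def test_spec_json_round_trip(self):
        spec = nw.build_generator_spec(64, 9)
        back = nw.NetworkSpec.from_json(spec.to_json())
        assert back == spec

    def test_shape_trace_matches_hand_computed_table_at_64(self):
        # independently worked-out arithmetic for the generator at 64x64
        spec = nw.build_generator_spec(64, 9)
        trace = nw.shape_trace(spec)
        expected = [
            (9, 70, 70),                       # mirror pad 3
            (32, 64, 64), (32, 64, 64), (32, 64, 64),   # conv1 7x7 + IN + relu
            (64, 32, 32), (64, 32, 32), (64, 32, 32),   # conv2 3x3 s2
            (128, 16, 16), (128, 16, 16), (128, 16, 16),  # conv3 3x3 s2
            (128, 16, 16), (128, 16, 16), (128, 16, 16),  # conv4 3x3 s1
            (64, 32, 32), (64, 32, 32), (64, 32, 32),     # deconv1
            (64, 32, 32), (64, 32, 32), (64, 32, 32),     # fusion1
            (32, 64, 64), (32, 64, 64), (32, 64, 64),     # deconv2
            (32, 64, 64), (32, 64, 64), (32, 64, 64),     # fusion2
            (1, 64, 64), (1, 64, 64),                     # out conv + sigmoid
        ]
        assert trace == expected


class TestForward:
    def test_rfb_restores_spatial_dims_and_channel_count(self, rng):
        spec = nw.build_rfb_spec(64, feature_channels=8)
        net = nw.Network(spec)
        p = net.init_params(np.random.default_rng(0))
        region = rng.random((1, 64, 64)).astype(nn.DTYPE)
        y, _ = net.forward(p, region)
        assert y.shape == (8, 64, 64)

    @pytest.mark.parametrize("size", [32, 64])
    def test_generator_output_matches_input_dims_in_unit_range(self, size, rng):
        spec = nw.build_generator_spec(size, 2)
        net = nw.Network(spec)
        p = net.init_params(np.random.default_rng(1))
        x = rng.random((2, size, size)).astype(nn.DTYPE)
        y, _ = net.forward(p, x)
        assert y.shape == (1, size, size)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_zero_weight_discriminator_outputs_half(self):
        spec = nw.build_discriminator_spec(32)
        net = nw.Network(spec)
        p = net.init_params(np.random.default_rng(0), zero=True)
        y, _ = net.forward(p, np.ones((1, 32, 32), dtype=nn.DTYPE))
        assert y.shape == (1,)
        assert y[0] == 0.5

    def test_discriminator_batch_scores_strictly_inside_unit_interval(self, rng):
        spec = nw.build_discriminator_spec(32)
        p = nw.Network(spec).init_params(np.random.default_rng(2))
        batch = (10 * rng.standard_normal((5, 1, 32, 32))).astype(nn.DTYPE)
        out = nw.forward(spec, p, batch)
        assert out.shape == (5, 1)
        assert np.all(out > 0) and np.all(out < 1)

    def test_forward_is_deterministic(self, rng):
        spec = nw.build_generator_spec(32, 1)
        net = nw.Network(spec)
        p = net.init_params(np.random.default_rng(3))
        x = rng.random((1, 32, 32)).astype(nn.DTYPE)
        a, _ = net.forward(p, x)
        b, _ = net.forward(p, x)
        np.testing.assert_array_equal(a, b)

    def test_input_shape_mismatch_names_the_network(self):
        spec = nw.build_generator_spec(32, 1)
        net = nw.Network(spec)
        p = net.init_params(np.random.default_rng(0))
        with pytest.raises(ValueError, match="generator_G"):
            net.forward(p, np.zeros((1, 16, 16), dtype=nn.DTYPE))

    def test_instance_norm_standardizes_each_channel(self, rng):
        x = (rng.random((3, 12, 12)) * 5 + 2).astype(np.float64)
        y, _ = nn.instance_norm_forward(x)
        np.testing.assert_allclose(y.mean(axis=(1, 2)), 0, atol=1e-10)
        np.testing.assert_allclose(y.var(axis=(1, 2)), 1, atol=1e-4)


class TestFusion:
    def test_channel_concatenation_image_first(self, rng):
        img = rng.random((64, 64))
        feats = rng.random((8, 64, 64))
        fused = nw.fuse_regional_features(img, feats)
        assert fused.shape == (9, 64, 64)
        np.testing.assert_array_equal(fused[0], img)

    def test_spatial_mismatch_rejected(self):
        with pytest.raises(ValueError, match="spatial"):
            nw.fuse_regional_features(np.zeros((32, 32)),
                                      np.zeros((4, 64, 64)))

    def test_zero_feature_maps_reduce_to_image_only_behavior(self, rng):
        # a generator fed (image, zero features) must match the same
        # generator fed (image, zero features) built independently — and the
        # extra channels must contribute nothing at the first conv
        spec = nw.build_generator_spec(32, 3)
        net = nw.Network(spec)
        p = net.init_params(np.random.default_rng(4))
        img = rng.random((1, 32, 32)).astype(nn.DTYPE)
        fused = nw.fuse_regional_features(img, np.zeros((2, 32, 32),
                                                        dtype=nn.DTYPE))
        y1, _ = net.forward(p, fused)
        # zero out the weights that read the feature channels: same output
        p2 = {k: v.copy() for k, v in p.items()}
        p2["1.w"][:, 1:, :, :] = 0.0
        y2, _ = net.forward(p2, fused)
        np.testing.assert_allclose(y1, y2, atol=1e-6)


class TestGradients:
    """Finite-difference checks of the assembled networks (float64)."""

    @staticmethod
    def _check(net, p, x, keys, rng, tol=1e-5):
        y, tape = net.forward(p, x)
        gy = rng.standard_normal(np.shape(y))
        gx, grads = net.backward(p, tape, gy)

        def loss():
            return float((net.forward(p, x)[0] * gy).sum())

        eps = 1e-6
        for key in keys:
            w = p[key]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in w.shape)
                orig = w[idx]
                w[idx] = orig + eps
                lp = loss()
                w[idx] = orig - eps
                lm = loss()
                w[idx] = orig
                assert np.isclose(grads[key][idx], (lp - lm) / (2 * eps),
                                  atol=tol), key
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            orig = x[idx]
            x[idx] = orig + eps
            lp = loss()
            x[idx] = orig - eps
            lm = loss()
            x[idx] = orig
            assert np.isclose(gx[idx], (lp - lm) / (2 * eps), atol=tol)

    def test_generator_backward_matches_finite_differences(self):
        rng = np.random.default_rng(10)
        spec = nw.build_generator_spec(16, 2)
        net = nw.Network(spec)
        p = net.init_params(rng, dtype=np.float64)
        x = rng.random((2, 16, 16))
        self._check(net, p, x, ["1.w", "13.w", "16.w", "22.w", "25.w"], rng)

    def test_discriminator_backward_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        spec = nw.build_discriminator_spec(16)
        net = nw.Network(spec)
        p = net.init_params(rng, dtype=np.float64)
        x = rng.random((1, 16, 16))
        self._check(net, p, x, ["0.w", "6.w", "9.w"], rng)

    def test_rfb_backward_matches_finite_differences(self):
        rng = np.random.default_rng(12)
        spec = nw.build_rfb_spec(16, 4)
        net = nw.Network(spec)
        p = net.init_params(rng, dtype=np.float64)
        x = rng.random((1, 16, 16))
        self._check(net, p, x, ["1.w", "8.w", "11.w"], rng)
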