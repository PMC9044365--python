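"""Architecture construction, shape contracts and parameter accounting."""

import numpy as np
import pytest

from mlped import autodiff as ad
from mlped.autodiff import Tensor
from mlped.network import (
    MLPED,
    MLPModule,
    Module,
    NetworkConfig,
    RMP,
    ZoomInOut,
    build_decoder_block,
    build_encoder_block,
    build_mlped,
    count_trainable_parameters,
    load_model,
    save_model,
)


def conv_params(cin, cout, k=3):
    return k * k * cin * cout + cout


class TestNetworkConfig:
    def test_default_schedule(self):
        cfg = NetworkConfig()
        assert cfg.channel_schedule == (32, 64, 128, 256, 384)

    def test_level_consistency_enforced(self):
        with pytest.raises(ValueError):
            NetworkConfig(encoder_levels=5, mlp_levels=3)
        with pytest.raises(ValueError):
            NetworkConfig(channel_schedule=(16, 32, 64, 128, 256))  # first != 32
        with pytest.raises(ValueError):
            NetworkConfig(rmp_kernels=(2, 2, 5, 6))

    def test_round_trips_through_dict(self):
        cfg = NetworkConfig(first_channels=8, dropout_rate=0.1)
        assert NetworkConfig.from_dict(cfg.to_dict()) == cfg


class TestEncoderBlock:
    def test_output_shape(self, rng):
        block = build_encoder_block(1, 32)
        out = block(Tensor(rng.standard_normal((1, 1, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 32, 16, 16)

    def test_parameter_count_closed_form(self):
        block = build_encoder_block(1, 32)
        expected = conv_params(1, 32) + conv_params(32, 32) + 2 * (2 * 32)
        assert count_trainable_parameters(block) == expected == 9696

    def test_no_dropout_means_train_eval_agree(self, rng):
        block = build_encoder_block(2, 8, NetworkConfig(dropout_rate=0.0))
        x = Tensor(rng.standard_normal((1, 2, 12, 12)).astype(np.float32))
        block.train()
        a = block(x).data
        block.eval()
        b = block(x).data
        assert np.array_equal(a, b)


class TestRMP:
    def test_channel_arithmetic(self, rng):
        rmp = RMP(32, (2, 3, 5, 6), np.random.default_rng(0))
        out = rmp(Tensor(rng.standard_normal((1, 32, 32, 32)).astype(np.float32)))
        assert out.shape == (1, 36, 32, 32)

    def test_residual_passthrough(self, rng):
        rmp = RMP(4, (2, 3), np.random.default_rng(0))
        x = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        out = rmp(x)
        assert np.array_equal(out.data[:, :4], x.data)

    def test_zero_weight_branches_are_bias_broadcasts(self, rng):
        rmp = RMP(3, (2, 3), np.random.default_rng(0))
        for i, reducer in enumerate(rmp.reducers):
            reducer.weight.data[:] = 0
            reducer.bias.data[:] = 0.5 + i
        x = Tensor(rng.standard_normal((1, 3, 6, 6)).astype(np.float32))
        out = rmp(x)
        assert np.allclose(out.data[:, 3], 0.5)
        assert np.allclose(out.data[:, 4], 1.5)

    def test_matches_hand_rolled_pooling_oracle(self, rng):
        rmp = RMP(1, (2,), np.random.default_rng(3))
        x = rng.standard_normal((1, 1, 4, 4)).astype(np.float32)
        out = rmp(Tensor(x))
        # oracle: 2x2 max pool, 1x1 conv, bilinear upsample back to 4x4
        w = float(rmp.reducers[0].weight.data[0, 0, 0, 0])
        b = float(rmp.reducers[0].bias.data[0])
        pooled = x[0, 0].reshape(2, 2, 2, 2).max(axis=(1, 3))
        reduced = w * pooled + b
        m = np.array([[1.0, 0.0], [0.75, 0.25], [0.25, 0.75], [0.0, 1.0]])
        expected = m @ reduced @ m.T
        assert np.max(np.abs(out.data[0, 1] - expected)) < 1e-5

    def test_kernel_larger_than_feature_rejected(self, rng):
        rmp = RMP(2, (2, 3, 5, 6), np.random.default_rng(0))
        with pytest.raises(ValueError):
            rmp(Tensor(rng.standard_normal((1, 2, 4, 4)).astype(np.float32)))


class TestZoomInOut:
    def test_shape_round_trip(self, rng):
        zoom = ZoomInOut(64, 2, np.random.default_rng(0))
        out = zoom(Tensor(rng.standard_normal((1, 64, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 64, 16, 16)

    def test_zoom_factor_four_spans_two_levels(self, rng):
        zoom = ZoomInOut(64, 4, np.random.default_rng(0))
        x = Tensor(rng.standard_normal((1, 64, 16, 16)).astype(np.float32))
        hid = zoom.conv_down(zoom.conv_pre(x))
        assert hid.shape[2:] == (4, 4)
        assert zoom(x).shape == (1, 64, 16, 16)

    def test_indivisible_spatial_dims_rejected(self, rng):
        zoom = ZoomInOut(64, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            zoom(Tensor(rng.standard_normal((1, 64, 15, 15)).astype(np.float32)))


class TestMLPModule:
    def test_shape_preservation(self, rng):
        mod = MLPModule(128, NetworkConfig(), np.random.default_rng(0))
        out = mod(Tensor(rng.standard_normal((1, 128, 8, 8)).astype(np.float32)))
        assert out.shape == (1, 128, 8, 8)

    def test_zero_weights_reduce_to_residual_identity(self, rng):
        mod = MLPModule(8, NetworkConfig(first_channels=8), np.random.default_rng(0))
        for p in mod.project.parameters():
            p.data[:] = 0
        x = Tensor(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
        assert np.array_equal(mod(x).data, x.data)

    def test_level_one_parameter_count_closed_form(self):
        mod = MLPModule(32, NetworkConfig(), np.random.default_rng(0))
        rmp = 4 * (32 + 1)
        zoom = conv_params(36, 18) + conv_params(18, 18) + conv_params(18, 36)
        proj = conv_params(36, 32)
        assert count_trainable_parameters(mod) == rmp + zoom + proj == 25184


class TestPixelShuffle:
    def test_unit_factor_is_identity(self, rng):
        x = Tensor(rng.standard_normal((1, 3, 4, 4)))
        assert np.array_equal(ad.pixel_shuffle(x, 1).data, x.data)

    def test_index_formula_enumeration(self):
        x = Tensor(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 4, 1, 1))
        out = ad.pixel_shuffle(x, 2)
        assert np.array_equal(out.data[0, 0], [[1.0, 2.0], [3.0, 4.0]])

    def test_value_multiset_preserved(self, rng):
        x = Tensor(rng.standard_normal((1, 8, 4, 4)))
        out = ad.pixel_shuffle(x, 2)
        assert np.array_equal(np.sort(out.data.ravel()), np.sort(x.data.ravel()))

    def test_inverse_rearrangement_is_identity(self, rng):
        x = rng.standard_normal((2, 8, 4, 4))
        shuffled = ad.pixel_shuffle(Tensor(x), 2).data
        n, co, hr, wr = shuffled.shape
        unshuffled = (
            shuffled.reshape(n, co, hr // 2, 2, wr // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, 8, 4, 4)
        )
        assert np.array_equal(unshuffled, x)

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            ad.pixel_shuffle(Tensor(rng.standard_normal((1, 6, 4, 4))), 2)


class TestDecoderBlock:
    def test_level_four_shape_contract(self, rng):
        block = build_decoder_block(512, 256, 256)
        below = Tensor(rng.standard_normal((1, 512, 8, 8)).astype(np.float32))
        skip = Tensor(rng.standard_normal((1, 256, 16, 16)).astype(np.float32))
        assert block(below, skip).shape == (1, 256, 16, 16)

    def test_parameter_count_closed_form_toy(self):
        block = build_decoder_block(16, 8, 8, NetworkConfig(first_channels=8))
        adjust = conv_params(4, 8)
        enc = conv_params(16, 8) + conv_params(8, 8) + 2 * (2 * 8)
        assert count_trainable_parameters(block) == adjust + enc

    def test_mismatched_skip_shape_rejected(self, rng):
        block = build_decoder_block(16, 8, 8, NetworkConfig(first_channels=8))
        below = Tensor(rng.standard_normal((1, 16, 4, 4)).astype(np.float32))
        skip = Tensor(rng.standard_normal((1, 8, 12, 12)).astype(np.float32))
        with pytest.raises(ValueError):
            block(below, skip)


class TestMLPEDModel:
    def test_default_config_full_resolution_forward(self):
        model = build_mlped(NetworkConfig(), seed=0).eval()
        x = Tensor(np.zeros((1, 1, 320, 320), dtype=np.float32))
        assert model(x).shape == (1, 1, 320, 320)

    @pytest.mark.parametrize("size", [64, 128])
    def test_forward_preserves_spatial_shape(self, size, rng):
        model = build_mlped(NetworkConfig(first_channels=8), seed=0).eval()
        x = Tensor(rng.standard_normal((1, 1, size, size)).astype(np.float32))
        assert model(x).shape == (1, 1, size, size)

    def test_indivisible_input_rejected(self):
        model = build_mlped(NetworkConfig(first_channels=8), seed=0)
        with pytest.raises(ValueError):
            model(Tensor(np.zeros((1, 1, 100, 100), dtype=np.float32)))

    def test_eval_forward_is_deterministic(self, rng):
        model = build_mlped(NetworkConfig(first_channels=8, dropout_rate=0.2),
                            seed=0).eval()
        x = Tensor(rng.standard_normal((1, 1, 64, 64)).astype(np.float32))
        assert np.array_equal(model(x).data, model(x).data)

    def test_every_parameter_receives_gradient(self, rng):
        model = build_mlped(NetworkConfig(first_channels=8), seed=0).train()
        x = Tensor(rng.standard_normal((1, 1, 48, 48)).astype(np.float32))
        t = Tensor(rng.standard_normal((1, 1, 48, 48)).astype(np.float32))
        loss = ad.mean_abs_error(model(x), t)
        model.zero_grad()
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, name
            assert np.any(p.grad != 0), name

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_mlped(NetworkConfig(first_channels=8), seed=1).eval()
        x = Tensor(rng.standard_normal((1, 1, 48, 48)).astype(np.float32))
        before = model(x).data
        path = tmp_path / "ckpt.npz"
        save_model(model, path)
        restored = load_model(path).eval()
        assert restored.config == model.config
        assert np.array_equal(restored(x).data, before)


class TestParameterCounting:
    def test_empty_module_counts_zero(self):
        assert count_trainable_parameters(Module()) == 0

    def test_single_conv_closed_form(self):
        from mlped.network import Conv2d

        conv = Conv2d(1, 32, 3, padding=1)
        assert count_trainable_parameters(conv) == 9 * 1 * 32 + 32 == 320

    def test_default_model_rounds_to_eight_million(self):
        model = build_mlped(NetworkConfig(), seed=0)
        n = count_trainable_parameters(model)
        assert round(n / 1e6) == 8

    def test_count_matches_closed_form_audit(self):
        # independent closed-form audit of the documented architecture
        sched = (32, 64, 128, 256, 384)

        def enc(i, o):
            return conv_params(i, o) + conv_params(o, o) + 4 * o

        total = enc(1, sched[0])
        total += sum(enc(a, b) for a, b in zip(sched, sched[1:]))
        for c in sched[:-1]:
            cp = c + 4
            h = cp // 2
            total += 4 * (c + 1)
            total += conv_params(cp, h) + conv_params(h, h) + conv_params(h, cp)
            total += conv_params(cp, c)
        for l in range(4):
            total += conv_params(sched[l + 1] // 4, sched[l])
            total += enc(2 * sched[l], sched[l])
        total += conv_params(sched[0], 1)
        model = build_mlped(NetworkConfig(), seed=0)
        assert count_trainable_parameters(model) == total == 7886593
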