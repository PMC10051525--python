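"""EvoNorm, SE gate, residual block, and network construction."""

import math

import numpy as np
import pytest

import ecgkit as ek
from ecgkit.autodiff import Tensor
from ecgkit.model import (EvoNorm1d, ResidualBlock1d, SEBlock1d,
                          se_reduced_width, _stride_pad)


def evo_s0_scalar_loop(x, groups, gamma, beta, v, eps=1e-5):
    """Brute-force elementwise evaluation of the S0 formula."""
    B, T, C = x.shape
    gs = C // groups
    y = np.empty_like(x)
    for b in range(B):
        for g in range(groups):
            vals = [x[b, t, c] for t in range(T)
                    for c in range(g * gs, (g + 1) * gs)]
            mu = sum(vals) / len(vals)
            var = sum((u - mu) ** 2 for u in vals) / len(vals)
            den = math.sqrt(var + eps)
            for t in range(T):
                for c in range(g * gs, (g + 1) * gs):
                    sig = 1.0 / (1.0 + math.exp(-v[c] * x[b, t, c]))
                    y[b, t, c] = x[b, t, c] * sig / den * gamma[c] + beta[c]
    return y


class TestEvoNorm:
    def test_zero_input_returns_beta(self):
        beta = np.array([0.3, -0.7, 1.1, 0.0])
        y = ek.evo_norm(np.zeros((2, 6, 4)), "S0", groups=2,
                        gamma=np.ones(4), beta=beta, v=np.ones(4))
        np.testing.assert_array_equal(y, np.broadcast_to(beta, (2, 6, 4)))

    def test_s0_output_bounded_by_normalized_input(self, rng):
        x = rng.normal(size=(2, 8, 4))
        y = ek.evo_norm(x, "S0", groups=2, gamma=1.0, beta=0.0, v=1.0)
        var = x.reshape(2, 8, 2, 2).var(axis=(1, 3), keepdims=True)
        bound = np.abs(x.reshape(2, 8, 2, 2) / np.sqrt(var + 1e-5)).reshape(2, 8, 4)
        assert np.all(np.abs(y) <= bound + 1e-12)

    def test_s0_matches_scalar_loop_oracle(self, rng):
        x = rng.normal(size=(2, 8, 4))
        gamma, beta, v = rng.normal(size=(3, 4))
        y = ek.evo_norm(x, "S0", groups=2, gamma=gamma, beta=beta, v=v)
        expected = evo_s0_scalar_loop(x, 2, gamma, beta, v)
        np.testing.assert_allclose(y, expected, atol=1e-10)

    def test_indivisible_groups_rejected(self):
        with pytest.raises(ValueError):
            ek.evo_norm(np.zeros((1, 4, 6)), "S0", groups=4,
                        gamma=1.0, beta=0.0, v=1.0)
        with pytest.raises(ValueError):
            EvoNorm1d(6, "S0", groups=4)

    def test_layer_matches_functional_s0(self, rng):
        x = rng.normal(size=(3, 10, 8))
        layer = EvoNorm1d(8, "S0", groups=4)
        layer.gamma.data = rng.normal(size=(1, 1, 8))
        layer.beta.data = rng.normal(size=(1, 1, 8))
        layer.v.data = rng.normal(size=(1, 1, 8))
        y = layer(Tensor(x)).data
        expected = ek.evo_norm(x, "S0", 4, layer.gamma.data[0, 0],
                               layer.beta.data[0, 0], layer.v.data[0, 0])
        np.testing.assert_allclose(y, expected, atol=1e-10)

    def test_b0_uses_running_stats_at_inference(self, rng):
        x = rng.normal(size=(4, 10, 4)) * 3.0
        layer = EvoNorm1d(4, "B0")
        y_train = layer(Tensor(x), training=True).data
        assert not np.allclose(layer.running_var, 1.0)  # stats updated
        y_eval = layer(Tensor(x), training=False).data
        assert y_train.shape == y_eval.shape == x.shape
        # functional form agrees with the layer at inference
        expected = ek.evo_norm(x, "B0", 0, np.ones(4), np.zeros(4), np.ones(4),
                               training=False, running_var=layer.running_var)
        np.testing.assert_allclose(y_eval, expected, atol=1e-10)


class TestSEBlock:
    def test_zero_excitation_scales_by_half(self, rng):
        x = rng.normal(size=(2, 9, 8))
        C, r = 8, 2
        y = ek.se_block(x, np.zeros((C, r)), np.zeros(r), np.zeros((r, C)),
                        np.zeros(C))
        np.testing.assert_allclose(y, 0.5 * x)

    @pytest.mark.parametrize("C,expected", [(4, 1), (8, 2), (16, 4), (32, 8)])
    def test_reduced_width(self, C, expected):
        assert se_reduced_width(C, 0.25) == expected
        assert SEBlock1d(np.random.default_rng(0), C, 0.25).reduced_width \
            == expected

    def test_gate_strictly_shrinks_nonzero_activations(self, rng):
        x = rng.normal(size=(2, 7, 8))
        layer = SEBlock1d(rng, 8, 0.25)
        y = layer(Tensor(x)).data
        nz = x != 0
        assert np.all(np.abs(y[nz]) < np.abs(x[nz]))

    def test_identity_forcing_bias_returns_input(self, rng):
        x = rng.normal(size=(2, 7, 8))
        layer = SEBlock1d(rng, 8, 0.25)
        layer.fc2.w.data[:] = 0.0
        layer.fc2.b.data[:] = 20.0  # sigmoid(20) ~ 1
        y = layer(Tensor(x)).data
        np.testing.assert_allclose(y, x, atol=1e-6)


class TestResidualBlock:
    def test_output_shape_halves_time_and_projects_channels(self, rng):
        cfg = ek.ModelConfig()
        blk = ResidualBlock1d(rng, cfg, t_in=187, in_ch=32, out_ch=64)
        y = blk(Tensor(rng.normal(size=(3, 187, 32))))
        assert y.shape == (3, 93, 64)

    def test_zero_input_zero_biases_gives_zero_output(self, rng):
        cfg = ek.ModelConfig()
        blk = ResidualBlock1d(rng, cfg, t_in=20, in_ch=8, out_ch=16)
        blk.conv_a.b.data[:] = 0.0
        blk.conv_b.b.data[:] = 0.0
        y = blk(Tensor(np.zeros((2, 20, 8))))
        np.testing.assert_allclose(y.data, 0.0, atol=1e-12)

    def test_ablated_block_builds_and_runs(self, rng):
        cfg = ek.ModelConfig(use_se=False, use_evo=False)
        blk = ResidualBlock1d(rng, cfg, t_in=20, in_ch=8, out_ch=16)
        assert blk.se is None
        y = blk(Tensor(rng.normal(size=(2, 20, 8))))
        assert y.shape == (2, 10, 16)

    @pytest.mark.parametrize("t", [11, 20, 93, 187, 3000])
    def test_stride_padding_matches_pool_arithmetic(self, t):
        p = _stride_pad(t, kernel=5, stride=2)
        assert (t + 2 * p - 5) // 2 + 1 == t // 2


class TestModelConfig:
    @pytest.mark.parametrize("kw", [
        dict(se_ratio=0.0), dict(se_ratio=1.5), dict(dropout=1.0),
        dict(block_filters=(64, 128)), dict(evo_variant="C1"),
        dict(evo_groups=7),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            ek.ModelConfig(**kw)

    def test_json_round_trip(self, tmp_path):
        cfg = ek.ModelConfig(n_classes=2, use_se=False)
        cfg.to_json(tmp_path / "cfg.json")
        assert ek.ModelConfig.from_json(tmp_path / "cfg.json") == cfg


class TestBuildModel:
    def test_softmax_rows_sum_to_one(self, rng):
        m = ek.build_model(ek.ModelConfig(), seed=0)
        p = m.predict_proba(rng.random((4, 187)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_sigmoid_head_in_unit_interval(self, rng):
        m = ek.build_model(ek.ModelConfig(n_classes=1), seed=0)
        p = m.predict_proba(rng.random((4, 187)))
        assert np.all((p > 0) & (p < 1))

    def test_inference_is_deterministic(self, rng):
        m = ek.build_model(ek.ModelConfig(), seed=0)
        x = rng.random((3, 187))
        np.testing.assert_array_equal(m.forward(x).data, m.forward(x).data)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            ek.build_model(ek.ModelConfig(input_len=8))

    def test_ablation_switches_reduce_parameter_count(self):
        full = ek.build_model(ek.ModelConfig(), seed=0).num_params()
        no_se = ek.build_model(ek.ModelConfig(use_se=False), seed=0).num_params()
        no_evo = ek.build_model(ek.ModelConfig(use_evo=False), seed=0).num_params()
        assert no_se < full and no_evo < full

    def test_rhythm_configuration_builds(self, rng):
        cfg = ek.ModelConfig(input_len=3000, in_channels=4, n_classes=1)
        m = ek.build_model(cfg, seed=0)
        z = m.forward(rng.random((2, 3000, 4)))
        assert z.shape == (2, 1)

    def test_end_to_end_gradients_finite(self, rng):
        cfg = ek.ModelConfig(stem_filters=8, block_filters=(8, 8, 8, 8),
                             head_hidden=8, input_len=64)
        m = ek.build_model(cfg, seed=0)
        z = m.forward(rng.random((4, 64)), training=True, rng=rng)
        loss = ek.softmax_ce_from_logits(z, np.array([0, 1, 2, 3]))
        loss.backward()
        for p in m.parameters():
            assert p.grad is not None and np.all(np.isfinite(p.grad))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = ek.ModelConfig(stem_filters=8, block_filters=(8, 8, 8, 8),
                             head_hidden=8, input_len=64)
        m = ek.build_model(cfg, seed=1)
        m.save(tmp_path / "w.npz")
        m2 = ek.EcgNet.load(tmp_path / "w.npz")
        x = rng.random((2, 64))
        np.testing.assert_array_equal(m.forward(x).data, m2.forward(x).data)
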