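"""Branch forward contracts, pooling arithmetic, complexity accounting."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import correlate2d

from rmetnet import nn
from rmetnet.autodiff import Tensor
from rmetnet.network import (
    ModelConfig,
    RMETNet,
    RiemannianBranch,
    SpatioTemporalBranch,
    conv2d_macs,
    count_flops,
    count_parameters,
    linear_macs,
    preset,
    reconcile_complexity,
)


class TestPooling:
    def test_printed_pool_arithmetic(self):
        assert ModelConfig(C=22, T=1000, K=4, pool_stride=15).l_pool == 62
        assert ModelConfig(C=22, T=1000, K=4, pool_stride=75).l_pool == 13

    def test_l_pool_matches_sliding_window_oracle(self):
        for t in range(10, 201, 13):
            for kernel in (3, 7, 10):
                for stride in (1, 2, 5, kernel):
                    if kernel > t:
                        continue
                    windows = [s for s in range(0, t - kernel + 1, stride)]
                    cfg = ModelConfig(C=4, T=t, K=2, K_E=min(5, t), pool_kernel=kernel,
                                      pool_stride=stride, riemannian_kernels=(1, 2))
                    assert cfg.l_pool == len(windows)

    def test_pool_kernel_longer_than_t_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(C=4, T=50, K=2, pool_kernel=75, K_E=10, riemannian_kernels=(1, 2))


class TestSpatioTemporalBranch:
    def test_delta_kernels_constant_input_give_log_square(self):
        """Identity convolutions on a constant input e land at log(e^2) = 2."""
        cfg = ModelConfig(C=4, T=100, K=2, F1=3, F2=6, K_E=5, pool_kernel=10,
                          pool_stride=10, riemannian_kernels=(1, 2))
        branch = SpatioTemporalBranch(cfg).eval()
        for conv in (branch.conv_t1, branch.conv_t2, branch.conv_s):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        branch.conv_t1.weight.data[:, 0, 0, 2] = 1.0  # centre tap of k=5
        branch.conv_t2.weight.data[:, 0, 0, 2] = 1.0  # read map 0 only
        branch.conv_s.weight.data[:, 0, 0, 0] = 1.0  # one-hot spatial row
        x = Tensor(np.full((2, 4, 100), np.e))
        out = branch(x).data
        assert np.abs(out - 2.0).max() < 1e-4  # eval-mode BN with unit stats

    def test_log_clamp_keeps_zero_input_finite(self):
        cfg = ModelConfig(C=4, T=100, K=2, F1=3, F2=6, K_E=5, pool_kernel=10,
                          pool_stride=10, riemannian_kernels=(1, 2))
        branch = SpatioTemporalBranch(cfg).eval()
        out = branch(Tensor(np.zeros((1, 4, 100)))).data
        assert np.isfinite(out).all()


class TestRiemannianBranch:
    def _cfg(self, mode="pooled"):
        return ModelConfig(C=8, T=100, K=2, F3=4, K_E=5, pool_kernel=10, pool_stride=10,
                           riemannian_kernels=(1, 3, 5), riem_feature_mode=mode)

    def test_zero_input_zero_biases_give_projection_bias(self, rng):
        branch = RiemannianBranch(self._cfg())
        for conv in branch.convs:
            conv.bias.data[:] = 0.0
        out = branch(Tensor(np.zeros((3, 8, 8)))).data
        assert np.allclose(out, branch.proj.bias.data[None, :])

    @pytest.mark.parametrize("mode", ["pooled", "full_flatten"])
    def test_matches_scipy_straight_line_oracle(self, mode, rng):
        cfg = self._cfg(mode)
        branch = RiemannianBranch(cfg, rng=np.random.default_rng(4))
        x = rng.normal(size=(2, 8, 8))
        feats = []
        for i, (conv, k) in enumerate(zip(branch.convs, cfg.riemannian_kernels)):
            maps = []
            for f in range(cfg.F3):
                kernel = conv.weight.data[f, 0]
                ms = []
                for b in range(2):
                    mode_s = "same" if i < 2 else "valid"
                    m = correlate2d(x[b], kernel, mode=mode_s) + conv.bias.data[f]
                    ms.append(m)
                maps.append(np.stack(ms))
            maps = np.stack(maps, axis=1)  # (B, F3, h, w)
            if mode == "pooled":
                feats.append(maps.mean(axis=(2, 3)))
            else:
                feats.append(maps.reshape(2, -1))
        flat = np.concatenate(feats, axis=1)
        expected = flat @ branch.proj.weight.data.T + branch.proj.bias.data
        got = branch(Tensor(x)).data
        assert np.abs(got - expected).max() < 1e-6

    def test_pinned_width_is_three_f3(self):
        assert preset("bciciv2a").riem_width == 12
        assert preset("bciciv2b").riem_width == 8

    def test_kernel_larger_than_channels_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(C=3, T=100, K=2, K_E=5, pool_kernel=10, riemannian_kernels=(1, 5))


class TestFullModel:
    @pytest.fixture()
    def model(self, tiny_model_cfg):
        return RMETNet(tiny_model_cfg, seed=0).eval()

    def test_probabilities_on_simplex(self, model, tiny_model_cfg, rng):
        c, t = tiny_model_cfg.C, tiny_model_cfg.T
        out = model(rng.normal(size=(5, c, t)), rng.normal(size=(5, c, c)), mode="full")
        p = out.probs.data
        assert (p >= 0).all()
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-6
        assert p.shape[1] == tiny_model_cfg.K

    def test_preset_class_counts(self):
        assert preset("bciciv2a").K == 4
        assert preset("bciciv2b").K == 2

    def test_base_mode_ignores_covariances_and_full_requires_them(self, model, tiny_model_cfg, rng):
        c, t = tiny_model_cfg.C, tiny_model_cfg.T
        x = rng.normal(size=(2, c, t))
        out = model(x, None, mode="base")
        assert out.riem_features is None
        with pytest.raises(ValueError):
            model(x, None, mode="full")

    def test_eval_forward_is_bitwise_repeatable(self, model, tiny_model_cfg, rng):
        c, t = tiny_model_cfg.C, tiny_model_cfg.T
        x = rng.normal(size=(2, c, t))
        r = rng.normal(size=(2, c, c))
        a = model(x, r, mode="full").probs.data
        b = model(x, r, mode="full").probs.data
        assert np.array_equal(a, b)


class TestComplexity:
    def test_parameter_count_closed_forms(self):
        lin = nn.Linear(10, 5)
        assert sum(p.data.size for p in lin.parameters()) == 55
        conv = nn.Conv2d(1, 12, (1, 30))
        assert sum(p.data.size for p in conv.parameters()) == 372

    def test_mac_closed_forms(self):
        assert linear_macs(10, 5) == 50
        assert conv2d_macs(24, 12, 1, 30, 22, 1000) == 190_080_000

    def test_count_parameters_matches_instantiated_model(self, tiny_model_cfg):
        model = RMETNet(tiny_model_cfg)
        manual = sum(p.data.size for p in model.trainable_parameters("full"))
        assert count_parameters(tiny_model_cfg) == manual

    def test_maxnorm_constrains_all_kernels_after_step(self, tiny_model_cfg, rng):
        model = RMETNet(tiny_model_cfg, seed=1)
        for p in model.parameters():
            p.grad = rng.normal(size=p.data.shape) * 10
        nn.Adam(model.parameters(), lr=1.0).step()
        nn.apply_maxnorm(model, 2.0)
        for p in model.parameters():
            if getattr(p, "constrain", False):
                norms = np.linalg.norm(p.data.reshape(p.data.shape[0], -1), axis=1)
                assert (norms <= 2.0 + 1e-12).all()

    def test_reconciliation_sweep_terminates_and_pins_defaults(self):
        report = reconcile_complexity()
        assert len(report["grid"]) == 16
        default = ModelConfig()
        sel = report["selected_dials"]
        assert sel["pool_stride"] == default.pool_stride
        assert sel["asb_filter_scope"] == default.asb_filter_scope
        assert sel["icb_conv_type"] == default.icb_conv_type
        assert sel["riem_feature_mode"] == default.riem_feature_mode
        conv = report["selected_flop_convention"]
        assert conv == {"convention": "mac_is_2", "include_fft": False}

    def test_fft_inclusion_and_convention_scale_flops(self):
        cfg = preset("bciciv2b")
        base = count_flops(cfg, "mac_is_1", include_fft=False)
        assert count_flops(cfg, "mac_is_2", include_fft=False) == 2 * base
        assert count_flops(cfg, "mac_is_1", include_fft=True) > base
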