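"""Closed-form, oracle and property tests for the three-branch attention."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import array_shapes, arrays

from shrimpdet import nn
from shrimpdet.ensimam import (EnSimAM, EnSimAMConfig, SOBEL_X, SOBEL_Y,
                               apply_ensimam, channel_stats, edge_attention,
                               fusion_weights, global_attention, local_attention)
from shrimpdet.nn import autograd as ag


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


CFG = EnSimAMConfig()


class TestChannelStats:
    @pytest.mark.parametrize("channel,correction,mean,var", [
        (np.full((3, 3), 3.0), "M_minus_1", 3.0, 0.0),
        ([[1, 2], [3, 4]], "M_minus_1", 2.5, 5 / 3),
        ([[1, 2], [3, 4]], "M", 2.5, 1.25),
    ])
    def test_hand_cases(self, channel, correction, mean, var):
        m, v = channel_stats(np.asarray(channel, dtype=float), correction)
        assert m == pytest.approx(mean)
        assert v == pytest.approx(var)

    def test_single_element_sample_variance_degenerates_to_zero(self):
        m, v = channel_stats(np.array([[7.0]]), "M_minus_1")
        assert (m, v) == (7.0, 0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            channel_stats(np.array([[np.nan, 1.0]]))


class TestGlobalBranch:
    def test_constant_channel_weight_is_sigmoid_half(self):
        a = global_attention(np.full((2, 4, 4), 3.0), CFG)
        assert np.allclose(a, sigmoid(0.5))

    def test_closed_form_on_2x2(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        a = global_attention(x, CFG)
        expected = sigmoid(2.25 / (4 * (5 / 3 + 1e-4)) + 0.5)
        assert a[0, 1, 1] == pytest.approx(expected, rel=1e-6)

    def test_weight_increases_with_distance_from_mean(self):
        x = np.linspace(-3, 3, 25).reshape(1, 5, 5)
        a = global_attention(x, CFG)
        d = np.abs(x - x.mean())
        order = np.argsort(d.ravel())
        assert np.all(np.diff(a.ravel()[order]) >= -1e-12)

    def test_nonfinite_rejected(self):
        bad = np.ones((1, 3, 3))
        bad[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            global_attention(bad, CFG)


class TestLocalBranch:
    def test_constant_map_gives_half(self):
        a = local_attention(np.full((1, 5, 5), 2.0), EnSimAMConfig(padding_mode="replicate"))
        assert np.allclose(a, 0.5)

    def test_center_spike_window_variance(self):
        x = np.zeros((1, 3, 3))
        x[0, 1, 1] = 9.0
        a = local_attention(x, CFG)
        # window mean 1, variance (64 + 8)/9 = 8
        assert a[0, 1, 1] == pytest.approx(sigmoid(8.0), rel=1e-6)

    def test_alpha_monotone(self):
        x = np.random.default_rng(0).normal(size=(2, 6, 6))
        a1 = local_attention(x, EnSimAMConfig(alpha_local=1.0))
        a2 = local_attention(x, EnSimAMConfig(alpha_local=2.0))
        assert np.all(a2 >= a1 - 1e-12)


class TestEdgeBranch:
    def test_constant_map_gives_half(self):
        a = edge_attention(np.full((1, 5, 5), 4.0), EnSimAMConfig(padding_mode="replicate"))
        assert np.allclose(a, 0.5)

    def test_vertical_step_gradient_magnitude(self):
        x = np.zeros((1, 4, 4))
        x[0, :, 2:] = 1.0
        a = edge_attention(x, CFG)
        # interior position adjacent to the step: Gx = 4, Gy = 0
        assert a[0, 1, 1] == pytest.approx(sigmoid(4.0), rel=1e-6)

    def test_rotation_swaps_gradients_but_not_magnitude(self, rng):
        x = rng.normal(size=(1, 6, 6))
        a = edge_attention(x, CFG)
        a_rot = edge_attention(np.rot90(x, axes=(1, 2)).copy(), CFG)
        assert np.allclose(np.rot90(a, axes=(1, 2)), a_rot, atol=1e-10)

    def test_sobel_kernels_are_transposes(self):
        assert np.array_equal(SOBEL_X.T, SOBEL_Y)


class TestFusion:
    def test_zero_channel_splits_evenly(self):
        wg, wl, we = fusion_weights(np.zeros((1, 4, 4)), CFG)
        assert wg[0] == pytest.approx(0.0)
        assert wl[0] == we[0] == pytest.approx(0.5)

    def test_unit_channel_value(self):
        wg, _, _ = fusion_weights(np.ones((1, 4, 4)), CFG)
        assert wg[0] == pytest.approx(4 / (4 + 1e-4), rel=1e-9)

    @given(arrays(np.float64, array_shapes(min_dims=3, max_dims=3, min_side=1, max_side=6),
                  elements=st.floats(-50, 50)))
    def test_weights_sum_to_one(self, x):
        wg, wl, we = fusion_weights(x, CFG)
        assert np.allclose(wg + wl + we, 1.0, atol=1e-12)
        assert np.all((wg >= 0) & (wg <= 1))

    def test_scaling_up_increases_global_weight(self, rng):
        x = rng.normal(size=(2, 5, 5))
        wg1, _, _ = fusion_weights(x, CFG)
        wg2, _, _ = fusion_weights(3.0 * x, CFG)
        assert np.all(wg2 > wg1)


def _naive_ensimam(x, cfg):
    """Per-pixel loop implementation of all branches — the independent oracle."""
    c, h, w = x.shape
    m = h * w
    out = np.zeros_like(x)
    for ci in range(c):
        ch = x[ci]
        mu = ch.mean()
        var = ch.var(ddof=1) if m > 1 else 0.0
        a_g = sigmoid((ch - mu) ** 2 / (4 * (var + cfg.lambda_reg)) + 0.5)
        a_l = np.zeros_like(ch)
        a_e = np.zeros_like(ch)
        for i in range(h):
            for j in range(w):
                vals = []
                gx = gy = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        v = ch[ii, jj] if 0 <= ii < h and 0 <= jj < w else 0.0
                        vals.append(v)
                        gx += SOBEL_X[di + 1, dj + 1] * v
                        gy += SOBEL_Y[di + 1, dj + 1] * v
                mu_l = np.mean(vals)
                var_l = np.mean([(v - mu_l) ** 2 for v in vals])
                a_l[i, j] = sigmoid(cfg.alpha_local * var_l)
                a_e[i, j] = sigmoid(cfg.beta_edge * np.hypot(gx, gy))
        norm = np.sqrt((ch ** 2).sum())
        wg = norm / (norm + cfg.eps_fusion)
        wl = (1 - wg) / 2
        out[ci] = ch * (wg * a_g + wl * a_l + wl * a_e)
    return out


class TestApply:
    @pytest.mark.parametrize("shape", [(1, 1, 1), (3, 5, 7), (2, 2, 4, 4)])
    def test_shape_preserved(self, rng, shape):
        x = rng.normal(size=shape)
        assert apply_ensimam(x, CFG).shape == shape

    def test_layer_has_zero_learnable_parameters(self):
        assert EnSimAM(CFG).num_params() == 0

    def test_constant_map_composes_branch_closed_forms(self):
        # replicate padding keeps a constant map constant at the borders too
        cfg = EnSimAMConfig(padding_mode="replicate")
        c = 2.0
        x = np.full((1, 4, 4), c)
        out = apply_ensimam(x, cfg)
        norm = np.sqrt(16 * c * c)
        wg = norm / (norm + cfg.eps_fusion)
        a = wg * sigmoid(0.5) + (1 - wg) * 0.5
        assert np.allclose(out, c * a, rtol=1e-6)

    def test_vectorized_matches_naive_loop_oracle(self, rng):
        x = rng.normal(size=(2, 5, 5))
        assert np.abs(apply_ensimam(x, CFG) - _naive_ensimam(x, CFG)).max() <= 1e-6

    def test_simam_limit_reproduces_reference_modulation(self, rng):
        """w_global -> 1 must recover plain SimAM: sigmoid(1/e*) * X."""
        x = rng.normal(size=(3, 6, 6))
        a_g = global_attention(x, CFG)
        ref = np.zeros_like(x)
        for ci in range(3):
            mu = x[ci].mean()
            var = x[ci].var(ddof=1)
            ref[ci] = x[ci] * sigmoid((x[ci] - mu) ** 2 / (4 * (var + CFG.lambda_reg)) + 0.5)
        assert np.allclose(x * a_g, ref, atol=1e-10)

    def test_autograd_layer_matches_reference_api(self, rng):
        x = rng.normal(size=(2, 3, 7, 7))
        t = ag.Tensor(x.copy(), requires_grad=True)
        y = EnSimAM(CFG)(t)
        assert np.abs(y.data - apply_ensimam(x, CFG)).max() <= 1e-9
        y.sum().backward()
        assert np.all(np.isfinite(t.grad))

    def test_deterministic(self, rng):
        x = rng.normal(size=(2, 4, 4))
        assert np.array_equal(apply_ensimam(x, CFG), apply_ensimam(x, CFG))

    @given(arrays(np.float64, (2, 4, 4), elements=st.floats(-4, 4)))
    def test_all_weights_in_unit_interval(self, x):
        # moderate activations keep the sigmoids away from float saturation
        for branch in (global_attention, local_attention, edge_attention):
            a = branch(x, CFG)
            assert np.all((a > 0) & (a < 1))


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"lambda_reg": 0.0}, {"alpha_local": -1.0}, {"eps_fusion": 0.0},
        {"variance_correction": "bogus"}, {"padding_mode": "wrap"},
        {"fusion_norm": "max"},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            EnSimAMConfig(**kw)

    def test_rms_norm_desaturates_global_weight(self, rng):
        x = rng.normal(size=(1, 32, 32))
        wg_l2, _, _ = fusion_weights(x, EnSimAMConfig(fusion_norm="l2"))
        wg_rms, _, _ = fusion_weights(x, EnSimAMConfig(fusion_norm="rms"))
        assert wg_rms[0] < wg_l2[0]
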