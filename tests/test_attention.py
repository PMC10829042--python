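"""D-scSE attention: hand-computed examples, a nested-loop oracle, and
the block's algebraic invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dsca.attention import (DscSE, DscseParams, FusionWeights, channel_excite,
                            dscse_forward, dscse_param_count, fuse,
                            init_fusion_weights, spatial_excite)
from dsca.nn import AdamW, Tensor
from dsca.nn import functional as F


def _sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def oracle_dscse(u, params):
    """Triple-loop scalar reference for the whole block."""
    c, h, w = u.shape
    out = np.zeros((c, h, w))
    # channel descriptor
    x = []
    for ch in range(c):
        vals = [u[ch, i, j] for i in range(h) for j in range(w)]
        x.append(sum(vals) / len(vals))
    for ch in range(c):
        x.append(max(u[ch, i, j] for i in range(h) for j in range(w)))
    gates_c = []
    for ch in range(c):
        acc = params.channel_bias[ch] if np.ndim(params.channel_bias) else params.channel_bias
        for k in range(2 * c):
            acc += params.channel_weight[ch, k] * max(x[k], 0.0)
        gates_c.append(_sigmoid(acc))
    for i in range(h):
        for j in range(w):
            k = params.spatial_bias
            for ch in range(c):
                k += params.spatial_kernel[ch] * u[ch, i, j]
            gate_s = _sigmoid(k)
            for ch in range(c):
                out[ch, i, j] = (params.fusion.alpha * gate_s * u[ch, i, j]
                                 + params.fusion.beta * gates_c[ch] * u[ch, i, j])
    return out


def random_params(rng, c):
    return DscseParams(
        spatial_kernel=rng.normal(size=c),
        spatial_bias=float(rng.normal()),
        channel_weight=rng.normal(size=(c, 2 * c)),
        channel_bias=rng.normal(size=c),
        fusion=FusionWeights(float(rng.normal()), float(rng.normal())),
    )


class TestSpatialExcite:
    def test_hand_example_uniform_gate(self):
        u = np.array([[[1, 2], [3, 4]], [[5, 6], [7, 8]]], dtype=float)
        out = spatial_excite(u, np.array([1.0, -1.0]), bias=0.0)
        gate = _sigmoid(-4.0)
        assert gate == pytest.approx(0.017986, abs=1e-6)
        np.testing.assert_allclose(out, gate * u, rtol=1e-9)

    def test_zero_kernel_gives_half_gate(self, rng):
        u = rng.normal(size=(3, 4, 5))
        np.testing.assert_allclose(spatial_excite(u, np.zeros(3)), 0.5 * u, rtol=1e-12)

    def test_zero_input_stays_zero(self, rng):
        out = spatial_excite(np.zeros((2, 3, 3)), rng.normal(size=2))
        np.testing.assert_array_equal(out, 0)

    def test_kernel_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="kernel length"):
            spatial_excite(rng.normal(size=(3, 2, 2)), np.zeros(4))


class TestChannelExcite:
    def test_hand_example_avg_max_descriptor(self):
        u = np.stack([np.ones((1, 2)), np.array([[0.0, 2.0]])])
        w = np.array([[1.0, 0, 0, 0], [0, 0, 0, 1.0]])
        out = channel_excite(u, w, bias=0.0)
        s = (_sigmoid(1.0), _sigmoid(2.0))
        assert s[0] == pytest.approx(0.731059, abs=1e-6)
        assert s[1] == pytest.approx(0.880797, abs=1e-6)
        np.testing.assert_allclose(out[0], s[0] * u[0], rtol=1e-9)
        np.testing.assert_allclose(out[1], s[1] * u[1], rtol=1e-9)

    def test_zero_weight_gives_half_gate(self, rng):
        u = rng.normal(size=(2, 3, 3))
        np.testing.assert_allclose(channel_excite(u, np.zeros((2, 4))), 0.5 * u, rtol=1e-12)

    def test_relu_kills_negative_descriptor(self, rng):
        u = -np.abs(rng.normal(size=(2, 3, 3))) - 1.0  # all-negative pools
        w = rng.normal(size=(2, 4))
        np.testing.assert_allclose(channel_excite(u, w), 0.5 * u, rtol=1e-12)

    def test_weight_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="channel weight"):
            channel_excite(rng.normal(size=(2, 3, 3)), np.zeros((2, 5)))


class TestFuse:
    def test_pure_branches_and_zero(self, rng):
        a = rng.normal(size=(2, 3, 3))
        b = rng.normal(size=(2, 3, 3))
        np.testing.assert_array_equal(fuse(a, b, FusionWeights(1.0, 0.0)), a)
        np.testing.assert_array_equal(fuse(a, b, FusionWeights(0.0, 0.0)), 0 * a)

    def test_weighted_scalar_example(self):
        out = fuse(np.full((1, 2, 2), 2.0), np.full((1, 2, 2), 10.0),
                   FusionWeights(0.3, 0.7))
        np.testing.assert_allclose(out, 7.6, rtol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shapes differ"):
            fuse(np.zeros((1, 2, 2)), np.zeros((1, 3, 2)), FusionWeights(1, 1))

    @given(st.floats(-3, 3), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_fusion_is_homogeneous(self, a, sub_seed):
        rng = np.random.default_rng(sub_seed)
        u1 = rng.normal(size=(2, 2, 2))
        u2 = rng.normal(size=(2, 2, 2))
        w = FusionWeights(float(rng.normal()), float(rng.normal()))
        np.testing.assert_allclose(fuse(a * u1, a * u2, w), a * fuse(u1, u2, w),
                                   rtol=1e-9, atol=1e-9)


class TestFusionInit:
    def test_bounds_for_n6(self):
        for seed in range(20):
            w = init_fusion_weights(n=6, seed=seed)
            assert -1.0 <= w.alpha <= 1.0 and -1.0 <= w.beta <= 1.0

    def test_reproducible_under_seed(self):
        assert init_fusion_weights(seed=42) == init_fusion_weights(seed=42)

    def test_distribution_moments(self):
        draws = np.array([[w.alpha, w.beta] for w in
                          (init_fusion_weights(n=6, seed=s) for s in range(5000))]).ravel()
        assert abs(draws.mean()) < 0.03
        assert draws.min() >= -1.0 and draws.max() <= 1.0

    def test_invalid_n_raises(self):
        with pytest.raises(ValueError):
            init_fusion_weights(n=0)


class TestDscseForward:
    def test_all_zero_params_unit_fusion_is_identity(self, rng):
        u = rng.normal(size=(3, 4, 4))
        params = DscseParams(np.zeros(3), 0.0, np.zeros((3, 6)), np.zeros(3),
                             FusionWeights(1.0, 1.0))
        np.testing.assert_allclose(dscse_forward(u, params), u, rtol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c, h, w = rng.integers(1, 5), rng.integers(1, 5), rng.integers(1, 5)
        u = rng.normal(size=(c, h, w))
        params = random_params(rng, c)
        np.testing.assert_allclose(dscse_forward(u, params), oracle_dscse(u, params),
                                   atol=1e-6)

    def test_closed_form_parameter_count(self):
        assert dscse_param_count(64) == 2 * 64 ** 2 + 2 * 64 + 3 == 8323
        for c in (1, 16, 64, 1024):
            assert DscSE(c).num_parameters() == dscse_param_count(c)

    @given(st.integers(1, 8), st.integers(1, 8), st.integers(1, 8),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_shape_preserved_and_gates_open(self, c, h, w, sub_seed):
        rng = np.random.default_rng(sub_seed)
        u = rng.normal(size=(c, h, w))
        kern = rng.normal(size=c)
        cw = rng.normal(size=(c, 2 * c))
        assert spatial_excite(u, kern).shape == u.shape
        assert channel_excite(u, cw).shape == u.shape
        params = random_params(rng, c)
        assert dscse_forward(u, params).shape == u.shape
        # gate ranges, via the layer's intermediate values
        from scipy.special import expit
        k = np.tensordot(kern, u, axes=1)
        gate_s = expit(k)
        assert np.all(gate_s > 0) and np.all(gate_s < 1)


class TestDscseLayer:
    def test_layer_matches_reference_forward(self, rng):
        blk = DscSE(5, rng=np.random.default_rng(3))
        u = rng.normal(size=(2, 5, 6, 7)).astype(np.float32)
        out = blk(Tensor(u)).data
        ref = np.stack([dscse_forward(u[i], blk.reference_params()) for i in range(2)])
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_fusion_weights_receive_gradient(self, rng):
        blk = DscSE(4, rng=np.random.default_rng(5))
        a0, b0 = float(blk.alpha.data), float(blk.beta.data)
        opt = AdamW(blk.parameters(), lr=1e-2)
        x = Tensor(rng.normal(size=(2, 4, 6, 6)).astype(np.float32))
        out = blk(x)
        loss = F.tensor_mean(F.mul(out - 1.0, out - 1.0))
        opt.zero_grad()
        loss.backward()
        assert blk.alpha.grad is not None and blk.beta.grad is not None
        opt.step()
        assert float(blk.alpha.data) != a0
        assert float(blk.beta.data) != b0

    def test_channel_mismatch_raises(self, rng):
        blk = DscSE(4)
        with pytest.raises(ValueError, match="channels"):
            blk(Tensor(rng.normal(size=(1, 3, 4, 4)).astype(np.float32)))
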