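"""Numerical correctness of the autodiff core.

Every backward implementation is checked against central finite
differences through a random linear projection of the op's output
(keeping the loss linear in the op avoids float32 curvature noise),
and the convolution forward is checked against scipy's correlate2d.
"""

import numpy as np
import pytest
from scipy.signal import correlate2d

from dsca.nn import AdamW, Tensor
from dsca.nn import functional as F

RNG = np.random.default_rng(7)


def _fd_check(make_loss, params, eps=0.02, tol=5e-3):
    for p in params:
        p.grad = None
    make_loss().backward()
    for p in params:
        grad = p.grad.copy()
        flat = p.data.reshape(-1)
        for i in RNG.choice(flat.size, size=min(6, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = make_loss().item()
            flat[i] = orig - eps
            lm = make_loss().item()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = grad.reshape(-1)[i]
            assert abs(num - ana) <= tol * max(1.0, abs(num), abs(ana))


def _proj_loss(op, *params):
    out = op()
    proj = Tensor(np.random.default_rng(0).normal(size=out.shape).astype(np.float32))
    return F.tensor_sum(F.mul(out, proj))


@pytest.fixture()
def x():
    return Tensor(RNG.normal(size=(2, 3, 9, 9)).astype(np.float32), requires_grad=True)


def test_conv2d_forward_matches_scipy(x):
    w = Tensor(RNG.normal(size=(4, 3, 3, 3)).astype(np.float32))
    out = F.conv2d(x, w, stride=1, padding=1).data
    for n in range(2):
        for co in range(4):
            ref = sum(correlate2d(x.data[n, ci], w.data[co, ci], mode="same")
                      for ci in range(3))
            np.testing.assert_allclose(out[n, co], ref, rtol=1e-4, atol=1e-4)


def test_conv2d_strided_dilated_matches_loop_oracle(x):
    w = Tensor(RNG.normal(size=(2, 3, 3, 3)).astype(np.float32))
    stride, pad, dil = 2, 2, 2
    out = F.conv2d(x, w, stride=stride, padding=pad, dilation=dil).data
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, hp, wp = xp.shape
    ho, wo = out.shape[2:]
    ref = np.zeros_like(out)
    for b in range(n):
        for co in range(2):
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for ci in range(c):
                        for ki in range(3):
                            for kj in range(3):
                                acc += (w.data[co, ci, ki, kj]
                                        * xp[b, ci, i * stride + ki * dil, j * stride + kj * dil])
                    ref[b, co, i, j] = acc
    np.testing.assert_allclose(out, ref, rtol=1e-4, atol=1e-4)


@pytest.mark.parametrize("op_name", [
    "conv", "conv_bias", "maxpool", "adaptive_pool", "bilinear", "relu",
    "sigmoid", "concat", "mean_spatial", "amax_spatial", "linear", "matmul",
])
def test_backward_matches_finite_differences(op_name, x):
    w = Tensor(RNG.normal(size=(4, 3, 3, 3)).astype(np.float32) * 0.3, requires_grad=True)
    b = Tensor(RNG.normal(size=4).astype(np.float32), requires_grad=True)
    lw = Tensor(RNG.normal(size=(5, 9)).astype(np.float32) * 0.3, requires_grad=True)
    ops = {
        "conv": (lambda: _proj_loss(lambda: F.conv2d(x, w, stride=2, padding=2, dilation=2)), [x, w]),
        "conv_bias": (lambda: _proj_loss(lambda: F.conv2d(x, w, b, padding=1)), [x, w, b]),
        "maxpool": (lambda: _proj_loss(lambda: F.max_pool2d(x, 3, 2, 1)), [x]),
        "adaptive_pool": (lambda: _proj_loss(lambda: F.adaptive_avg_pool2d(x, (2, 3))), [x]),
        "bilinear": (lambda: _proj_loss(lambda: F.bilinear_resize(x, (13, 7))), [x]),
        "relu": (lambda: _proj_loss(lambda: F.relu(x)), [x]),
        "sigmoid": (lambda: _proj_loss(lambda: F.sigmoid(x)), [x]),
        "concat": (lambda: _proj_loss(lambda: F.concat([x, x], axis=1)), [x]),
        "mean_spatial": (lambda: _proj_loss(lambda: F.mean_spatial(x)), [x]),
        "amax_spatial": (lambda: _proj_loss(lambda: F.amax_spatial(x)), [x]),
        "linear": (lambda: _proj_loss(lambda: F.linear(F.reshape(x, (2 * 3 * 9, 9)), lw)), [x, lw]),
        "matmul": (lambda: _proj_loss(lambda: F.matmul(F.reshape(x, (54, 9)), F.reshape(x, (54, 9)).reshape(9, 54))), [x]),
    }
    make_loss, params = ops[op_name]
    _fd_check(make_loss, params)


def test_batchnorm_backward_and_running_stats(x):
    gamma = Tensor(RNG.normal(size=3).astype(np.float32), requires_grad=True)
    beta = Tensor(RNG.normal(size=3).astype(np.float32), requires_grad=True)

    def bn_loss():
        rm = np.zeros(3, dtype=np.float32)
        rv = np.ones(3, dtype=np.float32)
        out = F.batch_norm(x, gamma, beta, rm, rv, training=True)
        proj = Tensor(np.random.default_rng(1).normal(size=out.shape).astype(np.float32))
        return F.tensor_sum(F.mul(out, proj))

    _fd_check(bn_loss, [x, gamma, beta])
    # training mode normalises the batch: unit-scale stats after affine removal
    rm = np.zeros(3, dtype=np.float32)
    rv = np.ones(3, dtype=np.float32)
    one = Tensor(np.ones(3, dtype=np.float32), requires_grad=True)
    zero = Tensor(np.zeros(3, dtype=np.float32), requires_grad=True)
    out = F.batch_norm(x, one, zero, rm, rv, training=True).data
    assert np.allclose(out.mean(axis=(0, 2, 3)), 0, atol=1e-5)
    assert np.allclose(out.var(axis=(0, 2, 3)), 1, atol=1e-3)
    assert not np.allclose(rm, 0)  # running stats were updated
    # eval mode uses the running stats and leaves them untouched
    rm2, rv2 = rm.copy(), rv.copy()
    F.batch_norm(x, one, zero, rm, rv, training=False)
    np.testing.assert_array_equal(rm, rm2)
    np.testing.assert_array_equal(rv, rv2)


def test_softmax_cross_entropy_gradient_and_value():
    logits = Tensor(RNG.normal(size=(2, 2, 4, 4)).astype(np.float32), requires_grad=True)
    target = RNG.integers(0, 2, size=(2, 4, 4))
    _fd_check(lambda: F.softmax_cross_entropy(logits, target), [logits], eps=0.01)
    zero = Tensor(np.zeros((1, 2, 3, 3), dtype=np.float32))
    assert F.softmax_cross_entropy(zero, np.zeros((1, 3, 3), dtype=int)).item() == pytest.approx(np.log(2), rel=1e-6)


def test_bilinear_resize_identity_and_constant(x):
    same = F.bilinear_resize(x, (9, 9)).data
    np.testing.assert_array_equal(same, x.data)
    const = Tensor(np.full((1, 1, 4, 4), 3.5, dtype=np.float32))
    up = F.bilinear_resize(const, (11, 13)).data
    np.testing.assert_allclose(up, 3.5, rtol=1e-6)


def test_adamw_minimises_simple_objective():
    p = Tensor(np.array([4.0], dtype=np.float32), requires_grad=True)
    opt = AdamW([p], lr=0.1, weight_decay=0.0)
    for _ in range(200):
        loss = F.tensor_sum(F.mul(p - 3.0, p - 3.0))
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert abs(p.data[0] - 3.0) < 1e-2


def test_adamw_weight_decay_is_decoupled():
    # with zero gradient signal the decay shrinks weights geometrically
    p = Tensor(np.array([1.0], dtype=np.float32), requires_grad=True)
    opt = AdamW([p], lr=0.1, weight_decay=0.5)
    p.grad = np.zeros(1, dtype=np.float32)
    opt.step()
    assert p.data[0] == pytest.approx(1.0 - 0.1 * 0.5 * 1.0)
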