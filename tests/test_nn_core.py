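"""Autograd primitives against independent references and finite differences."""

import numpy as np
import pytest
from scipy import ndimage

from frogeye import nn
from frogeye.nn import autograd as F


def numgrad(fn, param, eps=1e-3, limit=None):
    """Central-difference gradient of scalar fn w.r.t. a Tensor's entries."""
    flat = param.data.reshape(-1)
    n = len(flat) if limit is None else min(limit, len(flat))
    out = np.zeros(n)
    for i in range(n):
        old = flat[i]
        flat[i] = old + eps
        lp = fn()
        flat[i] = old - eps
        lm = fn()
        flat[i] = old
        out[i] = (lp - lm) / (2 * eps)
    return out


class TestConv2d:
    def test_matches_scipy_correlate(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 1, 9, 9)).astype(np.float32)
        w = rng.normal(size=(1, 1, 3, 3)).astype(np.float32)
        y = F.conv2d(nn.Tensor(x), nn.Tensor(w), None, pad=1)
        ref = ndimage.correlate(x[0, 0].astype(np.float64),
                                w[0, 0].astype(np.float64), mode="constant")
        assert np.allclose(y.data[0, 0], ref, atol=1e-5)

    def test_identity_kernel(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 3, 6, 6)).astype(np.float32)
        w = np.zeros((3, 3, 1, 1), np.float32)
        for c in range(3):
            w[c, c, 0, 0] = 1.0
        y = F.conv2d(nn.Tensor(x), nn.Tensor(w), None)
        assert np.array_equal(y.data, x)

    def test_strided_and_dilated_shapes(self):
        x = nn.Tensor(np.zeros((1, 2, 16, 16), np.float32))
        w = nn.Tensor(np.zeros((4, 2, 3, 3), np.float32))
        assert F.conv2d(x, w, None, stride=2, pad=1).data.shape == (1, 4, 8, 8)
        assert F.conv2d(x, w, None, dilation=2, pad=2).data.shape == (1, 4, 16, 16)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(2)
        x = nn.Tensor(rng.normal(size=(1, 2, 6, 6)).astype(np.float32),
                      requires_grad=True)
        w = nn.Tensor(rng.normal(size=(3, 2, 3, 3)).astype(np.float32),
                      requires_grad=True)
        gy = rng.normal(size=(1, 3, 6, 6)).astype(np.float32)

        def loss():
            return float((F.conv2d(x, w, None, pad=1).data * gy).sum())

        y = F.conv2d(x, w, None, pad=1)
        y.grad = gy.copy()
        y._backward()
        for p in (x, w):
            num = numgrad(loss, p, limit=20)
            assert np.allclose(p.grad.reshape(-1)[:20], num, atol=2e-2)


class TestPoolingAndUpsampling:
    def test_max_pool_selects_maxima(self):
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        y = F.max_pool2d(nn.Tensor(x), 2)
        assert np.array_equal(y.data[0, 0], [[5, 7], [13, 15]])

    def test_max_pool_odd_size_uses_ceil(self):
        x = nn.Tensor(np.zeros((1, 1, 5, 5), np.float32))
        assert F.max_pool2d(x, 2).data.shape == (1, 1, 3, 3)

    def test_adaptive_avg_pool_global_is_mean(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 3, 7, 5)).astype(np.float32)
        y = F.adaptive_avg_pool2d(nn.Tensor(x), (1, 1))
        assert np.allclose(y.data[..., 0, 0], x.mean(axis=(2, 3)), atol=1e-6)

    def test_adaptive_avg_pool_partitions_input(self):
        # 6x6 pooled from 12x12 averages disjoint 2x2 blocks
        x = np.arange(144, dtype=np.float32).reshape(1, 1, 12, 12)
        y = F.adaptive_avg_pool2d(nn.Tensor(x), (6, 6))
        assert y.data[0, 0, 0, 0] == x[0, 0, :2, :2].mean()
        assert y.data[0, 0, 5, 5] == x[0, 0, 10:, 10:].mean()

    def test_bilinear_upsample_preserves_constants(self):
        x = nn.Tensor(np.full((1, 2, 4, 4), 3.5, np.float32))
        y = F.upsample_bilinear(x, (9, 9))
        assert np.allclose(y.data, 3.5, atol=1e-6)

    def test_bilinear_upsample_is_linear(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        b = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        up = lambda z: F.upsample_bilinear(nn.Tensor(z), (7, 7)).data
        assert np.allclose(up(a + 2 * b), up(a) + 2 * up(b), atol=1e-5)


class TestBatchNorm:
    def test_training_mode_normalizes_batch(self):
        rng = np.random.default_rng(5)
        x = rng.normal(3.0, 2.0, size=(4, 2, 8, 8)).astype(np.float32)
        bn = nn.BatchNorm2d(2)
        y = bn(nn.Tensor(x))
        assert np.allclose(y.data.mean(axis=(0, 2, 3)), 0, atol=1e-5)
        assert np.allclose(y.data.std(axis=(0, 2, 3)), 1, atol=1e-3)

    def test_eval_mode_uses_running_stats(self):
        bn = nn.BatchNorm2d(1)
        bn.running_mean[:] = 2.0
        bn.running_var[:] = 4.0
        bn.eval()
        y = bn(nn.Tensor(np.full((1, 1, 2, 2), 4.0, np.float32)))
        assert np.allclose(y.data, 1.0, atol=1e-3)


class TestConvTranspose:
    def test_block_upsampling_doubles_size(self):
        x = nn.Tensor(np.ones((1, 2, 5, 5), np.float32))
        layer = nn.ConvTranspose2d(2, 3, 2, rng=np.random.default_rng(0))
        assert layer(x).data.shape == (1, 3, 10, 10)

    def test_single_pixel_expands_to_kernel(self):
        x = np.zeros((1, 1, 2, 2), np.float32)
        x[0, 0, 0, 0] = 1.0
        layer = nn.ConvTranspose2d(1, 1, 2, rng=np.random.default_rng(1))
        layer.bias.data[:] = 0
        y = layer(nn.Tensor(x))
        assert np.allclose(y.data[0, 0, :2, :2], layer.weight.data[0, 0])
        assert np.allclose(y.data[0, 0, 2:, :], 0)


class TestLossAndOptim:
    def test_focal_gamma_zero_is_cross_entropy(self):
        rng = np.random.default_rng(6)
        logits = nn.Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))
        t = rng.integers(0, 2, (1, 4, 4))
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        pt = np.take_along_axis(p, t[:, None], axis=1)[:, 0]
        assert F.focal_softmax_loss(logits, t, gamma=0.0).item() == pytest.approx(
            float(-np.log(pt).mean()), rel=1e-5)

    def test_valid_mask_excludes_pixels(self):
        rng = np.random.default_rng(7)
        logits = nn.Tensor(rng.normal(size=(1, 2, 2, 2)).astype(np.float32))
        t = np.zeros((1, 2, 2), np.int64)
        valid = np.zeros((1, 2, 2), bool)
        valid[0, 0, 0] = True
        full = F.focal_softmax_loss(logits, t, gamma=0.0).item()
        masked = F.focal_softmax_loss(logits, t, gamma=0.0, valid=valid).item()
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        assert masked == pytest.approx(float(-np.log(p[0, 0, 0, 0])), rel=1e-5)
        assert masked != pytest.approx(full)

    def test_adam_minimizes_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0], np.float32))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(300):
            p.grad = 2 * p.data
            opt.step()
        assert np.allclose(p.data, 0, atol=1e-3)

    def test_lr_schedules(self):
        assert nn.step_decay(1.0, 5, [10, 20], 0.1) == 1.0
        assert nn.step_decay(1.0, 15, [10, 20], 0.1) == pytest.approx(0.1)
        assert nn.step_decay(1.0, 25, [10, 20], 0.1) == pytest.approx(0.01)
        assert nn.exp_decay(1.0, 3, 0.96) == pytest.approx(0.96 ** 3)


class TestModuleContainers:
    def test_state_dict_roundtrip(self, tmp_path):
        m = nn.Sequential(nn.Conv2d(3, 4, 3, rng=np.random.default_rng(0)),
                          nn.BatchNorm2d(4), nn.ReLU())
        m.layers[1].running_mean[:] = 1.5
        p = tmp_path / "ckpt.npz"
        m.save(p)
        m2 = nn.Sequential(nn.Conv2d(3, 4, 3, rng=np.random.default_rng(9)),
                           nn.BatchNorm2d(4), nn.ReLU())
        m2.load(p)
        for (k1, a), (k2, b) in zip(m.named_parameters(), m2.named_parameters()):
            assert k1 == k2 and np.array_equal(a.data, b.data)
        assert np.array_equal(m2.layers[1].running_mean, m.layers[1].running_mean)

    def test_train_eval_flag_propagates(self):
        m = nn.Sequential(nn.BatchNorm2d(2), nn.Sequential(nn.BatchNorm2d(2)))
        m.eval()
        assert all(not mod.training for mod in m.modules())
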