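"""D-UNet: encoder/decoder structure, focal loss, checkerboard-free decoding."""

import math

import numpy as np
import pytest

from frogeye import metrics, nn
from frogeye.dunet import (DecoderConfig, DUNet, DUNetConfig, EncoderConfig,
                           FocalLossConfig, focal_loss)


class TestEncoderDecoderStructure:
    def test_full_width_encoder_has_13_convolutions(self):
        enc = EncoderConfig()
        assert sum(enc.conv_blocks) == 13
        assert enc.channels == (64, 128, 256, 512, 512)

    def test_skip_levels_halve_down_to_stride_16(self):
        # thin-width encoder, published input size: five skip maps at
        # 512, 256, 128, 64, 32
        model = DUNet(DUNetConfig.tiny((512, 512)), seed=0)
        model.eval()
        sizes = []
        x = nn.Tensor(np.zeros((1, 3, 512, 512), np.float32))
        for i, block in enumerate(model.enc_blocks):
            x = block(x)
            sizes.append(x.data.shape[2])
            if i < 4:
                x = model.pools[i](x)
        assert sizes == [512, 256, 128, 64, 32]

    def test_tiny_shape_contract(self):
        model = DUNet(DUNetConfig.tiny((64, 64)), seed=0)
        x = np.zeros((2, 3, 64, 64), np.float32)
        assert model(nn.Tensor(x)).data.shape == (2, 2, 64, 64)

    def test_indivisible_input_error_states_padding(self):
        model = DUNet(DUNetConfig.tiny((64, 64)), seed=0)
        with pytest.raises(ValueError, match="pad by 12 rows and 4 cols"):
            model(nn.Tensor(np.zeros((1, 3, 52, 60), np.float32)))

    @pytest.mark.parametrize("bn,mode", [
        (False, "transposed"),   # original U-Net layout
        (False, "bilinear"),
        (True, "transposed"),
        (True, "bilinear"),      # the improved variant
    ])
    def test_ablation_variants_construct_and_run(self, bn, mode):
        model = DUNet(DUNetConfig.tiny((64, 64), bn=bn, mode=mode), seed=0)
        x = np.zeros((1, 3, 64, 64), np.float32)
        assert model(nn.Tensor(x)).data.shape == (1, 2, 64, 64)

    def test_unknown_decoder_mode_rejected(self):
        with pytest.raises(ValueError):
            DecoderConfig(upsample_mode="nearest")

    def test_ablation_flag_constructor(self):
        cfg = DUNetConfig.from_ablation_flags(normalized_layer=False,
                                              bilinear_interpolation=False,
                                              tiny=True)
        assert not cfg.encoder.bn_before_relu
        assert cfg.decoder.upsample_mode == "transposed"
        full = DUNetConfig.from_ablation_flags(True, True)
        assert full.input_size == (512, 512)
        assert full.encoder.channels == (64, 128, 256, 512, 512)


class TestFocalLoss:
    def test_certain_predictions_give_zero_loss(self):
        p = np.zeros((4, 4, 2))
        t = np.zeros((4, 4), int)
        p[..., 0] = 1.0
        assert focal_loss(p, t) == 0.0

    def test_gamma_zero_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0.05, 0.95, size=(5, 5))
        p = np.stack([raw, 1 - raw], axis=-1)
        t = rng.integers(0, 2, (5, 5))
        pt = np.where(t == 0, raw, 1 - raw)
        ce = -np.log(pt).mean()
        assert focal_loss(p, t, FocalLossConfig(gamma=0)) == pytest.approx(ce)

    def test_half_confidence_gamma_two_closed_form(self):
        # single pixel at p_t = 0.5: (1-0.5)^2 * ln 2 = 0.25 ln 2
        p = np.array([[[0.5, 0.5]]])
        t = np.array([[0]])
        expected = 0.25 * math.log(2)
        assert focal_loss(p, t) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.173287, abs=1e-6)

    def test_strictly_decreasing_in_pt(self):
        pts = np.linspace(0.01, 0.99, 99)
        losses = [focal_loss(np.array([[[q, 1 - q]]]), np.array([[0]]))
                  for q in pts]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_modulating_factor_bounded_by_one(self):
        # (1-p_t)^gamma <= 1 with equality only at p_t = 0
        pts = np.linspace(0.0, 1.0, 101)
        factor = (1 - pts) ** 2
        assert (factor <= 1.0).all()
        assert factor[0] == 1.0 and (factor[1:] < 1.0).all()

    def test_zero_probability_clamped_not_infinite(self):
        p = np.array([[[0.0, 1.0]]])
        t = np.array([[0]])
        val = focal_loss(p, t)
        assert np.isfinite(val) and val > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.zeros((2, 2, 2)), np.zeros((3, 3), int))

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            FocalLossConfig(gamma=-1)


class TestCheckerboard:
    @staticmethod
    def nyquist_fraction(mode):
        model = DUNet(DUNetConfig.tiny((64, 64), mode=mode), seed=0)
        model.eval()
        x = np.full((1, 3, 64, 64), 0.25, np.float32)
        y = model(nn.Tensor(x)).data[0, 0]
        inner = y[8:-8, 8:-8]  # drop padding-affected borders
        spec = np.abs(np.fft.fft2(inner - inner.mean())) ** 2
        h, w = inner.shape
        nyq = spec[h // 2, w // 2] + spec[0, w // 2] + spec[h // 2, 0]
        return nyq / spec.sum()

    def test_bilinear_decoder_injects_no_checkerboard(self):
        assert self.nyquist_fraction("bilinear") < 1e-3

    def test_transposed_decoder_does_inject_checkerboard(self):
        # the artifact the bilinear decoder exists to avoid: orders of
        # magnitude more Nyquist power than the bilinear decoder's ~1e-4
        assert self.nyquist_fraction("transposed") > 0.05


class TestDUNetTraining:
    def test_overfits_eight_synthetic_scenes(self, lesion_overfit):
        model, log, scenes = lesion_overfit
        preds = [model.predict(s.image * s.leaf_mask[..., None])
                 for s in scenes]
        trues = [s.lesion_mask for s in scenes]
        rep = metrics.segmentation_report(trues, preds)
        assert rep["miou_percent"] >= 90.0
        assert log.losses[-1][-1] < log.losses[0][-1]
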