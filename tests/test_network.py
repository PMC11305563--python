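"""Architecture assembly: shapes, complexity accounting, decoding."""

import numpy as np
import pytest

from cattlepose.network import (REG_MAX, BiFusion, CattlePoseModel,
                                InvalidInputError, ModelConfig,
                                baseline_config, build_model, count_flops,
                                count_parameters, decode, improved_config)
from cattlepose.nn import Conv2d, Tensor, no_grad
from cattlepose.nn.modules import _Profiler
from cattlepose.reparam import reparameterize_network


def _forward(model, size, batch=1):
    x = Tensor(np.random.default_rng(0).random((batch, 3, size, size),
                                               ).astype(np.float32))
    with no_grad():
        return model(x)


class TestBackbone:
    def test_pyramid_strides(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        model.eval()
        with no_grad():
            c2, p3, p4, p5 = model.backbone(
                Tensor(np.zeros((1, 3, 128, 128), dtype=np.float32)))
        assert c2.shape[2:] == (32, 32)
        assert p3.shape[2:] == (16, 16)
        assert p4.shape[2:] == (8, 8)
        assert p5.shape[2:] == (4, 4)

    def test_indivisible_input_rejected(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        with pytest.raises(InvalidInputError):
            _forward(model.eval(), 96 + 1)

    def test_simam_insertion_preserves_parameter_count(self):
        plain = build_model(baseline_config(), seed=0)
        attn = build_model(baseline_config(simam_stages=("P3", "P4", "P5")),
                           seed=0)
        assert count_parameters(plain) == count_parameters(attn)


class TestBiFusion:
    def test_output_stride_and_channels(self, rng):
        bf = BiFusion(8, 6, 4, out_channels=10)
        deep = Tensor(rng.random((1, 8, 4, 4)).astype(np.float32))
        cur = Tensor(rng.random((1, 6, 8, 8)).astype(np.float32))
        shal = Tensor(rng.random((1, 4, 16, 16)).astype(np.float32))
        bf.eval()
        with no_grad():
            out = bf(deep, cur, shal)
        assert out.shape == (1, 10, 8, 8)

    def test_stride_relationship_enforced(self, rng):
        bf = BiFusion(8, 6, 4, out_channels=10)
        bad = Tensor(rng.random((1, 8, 8, 8)).astype(np.float32))
        cur = Tensor(rng.random((1, 6, 8, 8)).astype(np.float32))
        shal = Tensor(rng.random((1, 4, 16, 16)).astype(np.float32))
        with pytest.raises(InvalidInputError):
            bf(bad, cur, shal)

    def test_concat_channel_bookkeeping(self, rng):
        # three projected streams of out_channels each enter the final 1x1
        bf = BiFusion(8, 6, 4, out_channels=10)
        assert bf.cv_out.conv.in_channels == 3 * 10


class TestHeadAndModel:
    def test_prediction_cell_count_640_grid(self, tiny_config):
        model = build_model(tiny_config, seed=0).eval()
        pred = _forward(model, 320)
        assert pred.cells() == 40 ** 2 + 20 ** 2 + 10 ** 2
        # at 640 the grid would be 80^2+40^2+20^2 = 8400 (same arithmetic)
        assert (640 // 8) ** 2 + (640 // 16) ** 2 + (640 // 32) ** 2 == 8400

    def test_keypoint_field_width(self, tiny_config):
        model = build_model(tiny_config, seed=0).eval()
        pred = _forward(model, 64)
        for _, _, kpt in pred.levels:
            assert kpt.shape[1] == 16 * 3

    def test_head_shapes_invariant_under_neck_reparam(self, tiny_config):
        model = build_model(tiny_config, seed=0).eval()
        before = [(tuple(b.shape), tuple(c.shape), tuple(k.shape))
                  for b, c, k in _forward(model, 64).levels]
        reparameterize_network(model)
        after = [(tuple(b.shape), tuple(c.shape), tuple(k.shape))
                 for b, c, k in _forward(model, 64).levels]
        assert before == after

    def test_neck_outputs_three_strides(self, tiny_config):
        model = build_model(tiny_config, seed=0).eval()
        pred = _forward(model, 96)
        sizes = [b.shape[2] for b, _, _ in pred.levels]
        assert sizes == [12, 6, 3]


class TestComplexityCounts:
    def test_single_conv_parameter_count(self):
        conv = Conv2d(3, 16, 3, padding=1, bias=True)
        assert sum(p.size for p in conv.parameters()) == 16 * 3 * 9 + 16

    def test_single_conv_flops_closed_form(self):
        conv = Conv2d(3, 16, 3, stride=1, padding=1, bias=True)
        x = Tensor(np.zeros((1, 3, 640, 640), dtype=np.float32))
        with no_grad(), _Profiler() as prof:
            conv(x)
        gflops = 2 * prof.macs / 1e9
        assert gflops == pytest.approx(2 * 16 * 3 * 9 * 640 * 640 / 1e9)
        assert gflops == pytest.approx(0.354, abs=0.001)

    def test_reference_model_statistics(self):
        base = build_model(baseline_config(), seed=0)
        imp = build_model(improved_config(), seed=0)
        p_base, p_imp = count_parameters(base), count_parameters(imp)
        assert round(p_base / 1e6, 2) == 3.27
        assert round(p_imp / 1e6, 2) == 3.11
        assert round((p_base - p_imp) / 1e6, 2) == 0.16
        f_base, f_imp = count_flops(base, 640), count_flops(imp, 640)
        assert round(f_base, 1) == 9.1
        assert round(f_imp, 1) == 8.1
        assert round(f_base - f_imp, 1) == 1.0

    def test_flop_scaling_is_exact(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        a = count_flops(model, 128, profile_size=64)
        b = count_flops(model, 128, profile_size=128)
        assert a == pytest.approx(b, rel=1e-6)


class TestDecode:
    def test_conf_threshold_one_empty(self, tiny_config):
        model = build_model(tiny_config, seed=0).eval()
        pred = _forward(model, 64)
        assert decode(pred, conf_threshold=1.0) == []

    def test_invalid_thresholds(self, tiny_config):
        model = build_model(tiny_config, seed=0).eval()
        pred = _forward(model, 64)
        with pytest.raises(ValueError):
            decode(pred, conf_threshold=-0.1)

    def test_duplicate_cells_suppressed(self):
        # two identical synthetic cells -> one instance after NMS
        box = np.zeros((1, 4 * REG_MAX, 2, 2), dtype=np.float32)
        box[0, 0::REG_MAX] = 5.0  # peak at bin 0 on every side
        cls = np.full((1, 1, 2, 2), -10.0, dtype=np.float32)
        cls[0, 0, 0, 0] = 3.0
        cls[0, 0, 0, 1] = 3.0
        kpt = np.zeros((1, 48, 2, 2), dtype=np.float32)
        from cattlepose.network import DensePrediction
        pred = DensePrediction([(box, cls, kpt)], strides=(8,))
        dets = decode(pred, conf_threshold=0.5, iou_threshold=0.5)
        # both cells predict near-identical boxes around their centers; with
        # mostly-bin-0 distributions the boxes are tiny and disjoint -> 2 kept
        assert 1 <= len(dets) <= 2
        assert all(d.score > 0.9 for d in dets)
        assert dets == sorted(dets, key=lambda d: -d.score)

    def test_decode_encode_round_trip_center(self, tiny_config):
        """A target painted at a known cell decodes back to that cell."""
        from cattlepose.network import DensePrediction
        stride, h = 8, 8
        gx, gy = 3, 4
        box = np.zeros((1, 4 * REG_MAX, h, h), dtype=np.float32)
        cls = np.full((1, 1, h, h), -10.0, dtype=np.float32)
        kpt = np.zeros((1, 48, h, h), dtype=np.float32)
        cls[0, 0, gy, gx] = 5.0
        target_ltrb = (2.0, 1.0, 3.0, 2.5)  # stride units
        for side, val in enumerate(target_ltrb):
            lo, frac = int(val), val - int(val)
            box[0, side * REG_MAX:(side + 1) * REG_MAX, gy, gx] = -20.0
            if frac > 0:  # split the mass over the two bracketing bins
                box[0, side * REG_MAX + lo, gy, gx] = 20.0 + np.log(1 - frac)
                box[0, side * REG_MAX + lo + 1, gy, gx] = 20.0 + np.log(frac)
            else:
                box[0, side * REG_MAX + lo, gy, gx] = 20.0
        pred = DensePrediction([(box, cls, kpt)], strides=(stride,))
        det = decode(pred, conf_threshold=0.5)[0]
        cx, cy = det.box[0] + det.box[2] / 2, det.box[1] + det.box[3] / 2
        true_cx = (gx + 0.5) * stride + (target_ltrb[2] - target_ltrb[0]) / 2 * stride
        true_cy = (gy + 0.5) * stride + (target_ltrb[3] - target_ltrb[1]) / 2 * stride
        assert abs(cx - true_cx) < stride
        assert abs(cy - true_cy) < stride


class TestReparamWholeModel:
    def test_decode_agreement_after_fusion(self, tiny_config, rng):
        model = build_model(tiny_config, seed=0)
        model.train()
        with no_grad():
            for _ in range(2):
                model(Tensor(rng.random((2, 3, 64, 64)).astype(np.float32)))
        model.eval()
        x = Tensor(rng.random((1, 3, 64, 64)).astype(np.float32))
        with no_grad():
            d0 = decode(model(x), conf_threshold=0.0)
            reparameterize_network(model)
            d1 = decode(model(x), conf_threshold=0.0)
        assert len(d0) == len(d1)
        for a, b in zip(d0, d1):
            assert np.allclose(a.box, b.box, atol=1e-3)
            assert np.allclose(a.keypoints[:, :2], b.keypoints[:, :2], atol=1e-3)
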