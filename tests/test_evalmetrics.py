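"""mAP protocol oracles, confusion-matrix tallies and complexity counting."""

import numpy as np
import pytest

from shrimpdet.detector import Detection
from shrimpdet.evalmetrics import (PRData, ap_all_point, average_precision,
                                   complexity_report, confusion_matrix,
                                   count_flops, count_params, map_metrics,
                                   match_detections)
from shrimpdet.nn import Conv2d, mac_counter
from shrimpdet.nn import autograd as ag


def det(cx, cy, w, h, score, cls=0):
    return Detection(box=(cx, cy, w, h), score=score, class_id=cls)


def gt(cx, cy, w, h, cls=0):
    return (cls, (cx, cy, w, h))


class TestMatching:
    def test_perfect_detections_all_tp(self):
        dets = [[det(10, 10, 4, 4, 0.9), det(30, 30, 6, 6, 0.8)]]
        gts = [[gt(10, 10, 4, 4), gt(30, 30, 6, 6)]]
        pr = match_detections(dets, gts, 0.5)[0]
        assert pr.is_tp.all() and pr.n_gt == 2

    def test_duplicate_detection_gives_one_tp_one_fp(self):
        dets = [[det(10, 10, 4, 4, 0.9), det(10, 10, 4, 4, 0.8)]]
        gts = [[gt(10, 10, 4, 4)]]
        pr = match_detections(dets, gts, 0.5)[0]
        assert pr.is_tp.tolist() == [True, False]

    def test_class_mismatch_never_matches(self):
        dets = [[det(10, 10, 4, 4, 0.9, cls=1)]]
        gts = [[gt(10, 10, 4, 4, cls=0)]]
        out = match_detections(dets, gts, 0.5)
        assert not out[1].is_tp.any()
        assert out[0].n_gt == 1

    def test_randomized_against_bruteforce_greedy(self, rng):
        """10-box case: compare with an explicit greedy reference."""
        for trial in range(5):
            boxes_gt = [(rng.uniform(10, 90), rng.uniform(10, 90),
                         rng.uniform(5, 20), rng.uniform(5, 20)) for _ in range(5)]
            dets = []
            for _ in range(10):
                b = boxes_gt[int(rng.integers(5))]
                jit = rng.normal(0, 3, 4)
                dets.append(det(b[0] + jit[0], b[1] + jit[1],
                                max(2, b[2] + jit[2]), max(2, b[3] + jit[3]),
                                float(rng.uniform(0.1, 1.0))))
            pr = match_detections([dets], [[gt(*b) for b in boxes_gt]], 0.5)[0]

            # reference: same greedy rule, scalar loops
            from shrimpdet.evalmetrics import _iou_xyxy, _xywh_to_xyxy
            used = [False] * 5
            ref = []
            for d in sorted(dets, key=lambda d: -d.score):
                cand = [(j, _iou_xyxy(_xywh_to_xyxy(d.box), _xywh_to_xyxy(np.array(b))))
                        for j, b in enumerate(boxes_gt) if not used[j]]
                cand = [(j, i) for j, i in cand if i >= 0.5]
                if cand:
                    j = max(cand, key=lambda t: t[1])[0]
                    used[j] = True
                    ref.append(True)
                else:
                    ref.append(False)
            assert pr.is_tp.tolist() == ref


class TestAveragePrecision:
    def test_perfect_coverage_is_one(self):
        pr = PRData(scores=np.array([0.9, 0.8]), is_tp=np.array([True, True]), n_gt=2)
        assert average_precision(pr) == pytest.approx(1.0)

    def test_no_tp_is_zero(self):
        pr = PRData(scores=np.array([0.9]), is_tp=np.array([False]), n_gt=3)
        assert average_precision(pr) == 0.0

    def test_two_gt_three_det_case(self):
        """TP(0.9), FP(0.8), TP(0.7): all-point AP = 1/2*1 + 1/2*2/3 = 0.8333."""
        pr = PRData(scores=np.array([0.9, 0.8, 0.7]),
                    is_tp=np.array([True, False, True]), n_gt=2)
        assert ap_all_point(pr) == pytest.approx(5 / 6)
        assert average_precision(pr) == pytest.approx(5 / 6, abs=0.01)

    def test_zero_gt_warns_nan(self):
        pr = PRData(scores=np.array([0.5]), is_tp=np.array([False]), n_gt=0)
        with pytest.warns(UserWarning):
            assert np.isnan(average_precision(pr))

    def test_101_point_close_to_all_point_randomized(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            n_gt = int(rng.integers(3, 30))
            tp = rng.random(n) < 0.6
            tp[np.cumsum(tp) > n_gt] = False
            pr = PRData(scores=np.sort(rng.random(n))[::-1], is_tp=tp, n_gt=n_gt)
            assert abs(average_precision(pr) - ap_all_point(pr)) <= 0.01

    def test_invariant_to_score_rescaling(self, rng):
        tp = rng.random(30) < 0.5
        scores = np.sort(rng.random(30))[::-1]
        a = average_precision(PRData(scores, tp, 10))
        b = average_precision(PRData(scores * 0.3, tp, 10))
        assert a == b


class TestMapMetrics:
    def test_perfect_detections(self):
        dets = [[det(10, 10, 4, 4, 0.9)]]
        gts = [[gt(10, 10, 4, 4)]]
        map50, map5095, p, r = map_metrics(dets, gts)
        assert map50 == map5095 == 1.0
        assert p == r == 1.0

    def test_iou_055_sweep(self):
        """Detections at IoU ~0.55 count only at the 0.50/0.55 thresholds."""
        # width ratio w/W = 0.55 of concentric boxes -> IoU = 0.55
        dets = [[det(10, 10, 5.5, 10, 0.9)]]
        gts = [[gt(10, 10, 10, 10)]]
        map50, map5095, _, _ = map_metrics(dets, gts)
        assert map50 == pytest.approx(1.0)
        assert map5095 == pytest.approx(0.2, abs=1e-9)   # 2 of 10 thresholds

    def test_map5095_never_exceeds_map50(self, rng):
        dets, gts = [], []
        for i in range(6):
            img_dets, img_gts = [], []
            for _ in range(4):
                b = (rng.uniform(20, 80), rng.uniform(20, 80),
                     rng.uniform(6, 15), rng.uniform(6, 15))
                img_gts.append(gt(*b))
                jit = rng.normal(0, 2, 4)
                img_dets.append(det(b[0] + jit[0], b[1] + jit[1],
                                    max(3, b[2] + jit[2]), max(3, b[3] + jit[3]),
                                    float(rng.uniform(0.2, 1))))
            dets.append(img_dets)
            gts.append(img_gts)
        map50, map5095, _, _ = map_metrics(dets, gts)
        assert map5095 <= map50 + 1e-12

    def test_empty_gt_set_rejected(self):
        with pytest.raises(ValueError):
            map_metrics([[det(1, 1, 1, 1, 0.5)]], [[]])


class TestConfusionMatrix:
    def test_perfect_is_diagonal(self):
        dets = [[det(10, 10, 4, 4, 0.9, 0), det(30, 30, 4, 4, 0.9, 1)]]
        gts = [[gt(10, 10, 4, 4, 0), gt(30, 30, 4, 4, 1)]]
        m = confusion_matrix(dets, gts, 0.25, 0.5, num_classes=2)
        assert m[0, 0] == 1 and m[1, 1] == 1
        assert m.sum() == 2

    def test_no_detections_all_fn(self):
        gts = [[gt(10, 10, 4, 4), gt(30, 30, 4, 4)]]
        m = confusion_matrix([[]], gts, 0.25, 0.5, num_classes=1)
        assert m[1, 0] == 2      # background row collects the misses

    def test_mixed_hand_tally(self):
        dets = [[det(10, 10, 4, 4, 0.9, 0),      # TP class 0
                 det(70, 70, 4, 4, 0.8, 0),      # FP (no gt there)
                 det(30, 30, 4, 4, 0.2, 0)]]     # below conf threshold
        gts = [[gt(10, 10, 4, 4, 0), gt(30, 30, 4, 4, 0)]]
        m = confusion_matrix(dets, gts, 0.25, 0.5, num_classes=1)
        assert m[0, 0] == 1      # TP
        assert m[0, 1] == 1      # FP as background column
        assert m[1, 0] == 1      # missed gt


class TestComplexity:
    def test_conv_param_hand_count(self, rng):
        conv = Conv2d(3, 8, 3, bias=True, rng=rng)
        assert count_params(conv) == 3 * 8 * 9 + 8

    def test_conv_flop_hand_count(self, rng):
        conv = Conv2d(3, 8, 3, bias=True, rng=rng)
        mac_counter.active = True
        mac_counter.reset()
        conv(ag.Tensor(np.zeros((1, 3, 4, 4), dtype=np.float32)))
        mac_counter.active = False
        assert 2 * mac_counter.macs == 2 * 8 * 3 * 9 * 16   # = 6912 FLOPs

    def test_doubling_spatial_quadruples_flops(self, rng):
        conv = Conv2d(4, 4, 3, rng=rng)

        def macs(size):
            mac_counter.active = True
            mac_counter.reset()
            conv(ag.Tensor(np.zeros((1, 4, size, size), dtype=np.float32)))
            mac_counter.active = False
            return mac_counter.macs

        assert macs(16) == 4 * macs(8)

    def test_ghost_block_measured_equals_theoretical(self, rng):
        """Cross-module oracle: the profiler's MACs on a ghost block equal
        the closed-form cost expression (normalization/activation excluded)."""
        from shrimpdet.repghost import GhostConfig, RepGhostBlock, theoretical_cost
        cfg = GhostConfig(16, 32, 2, primary_kernel=1, cheap_kernel=3,
                          use_identity_branch=False)
        blk = RepGhostBlock(cfg, rng=rng)
        blk.eval()
        mac_counter.active = True
        mac_counter.reset()
        blk(ag.Tensor(np.zeros((1, 16, 8, 8), dtype=np.float32)))
        mac_counter.active = False
        _, ghost = theoretical_cost(cfg, 8, 8)
        assert mac_counter.macs == ghost

    def test_report_is_deterministic(self):
        from shrimpdet.architecture import DetectionModel, tiny_config
        m = DetectionModel(tiny_config())
        r1 = complexity_report(m, 160)
        r2 = complexity_report(m, 160)
        assert (r1.n_params, r1.gflops) == (r2.n_params, r2.gflops)

    def test_flops_input_validation(self):
        from shrimpdet.architecture import DetectionModel, tiny_config
        with pytest.raises(ValueError):
            count_flops(DetectionModel(tiny_config()), 100)
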