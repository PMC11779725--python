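"""Box/mask metrics: printed-formula examples, identities, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ap_oracle, greedy_match_oracle
from stomatakit.io import BoundingBox
from stomatakit.metrics import (
    MatchCounts,
    RankedDetections,
    ap50,
    box_iou,
    dice,
    dice_loss,
    fit_reliability,
    giou,
    giou_loss,
    iou,
    match_detections,
    precision_recall,
)


def B(x0, y0, x1, y1, c=None):
    return BoundingBox(x0, y0, x1, y1, c)


class TestGiou:
    def test_identical_boxes(self):
        b = B(3, 4, 10, 12)
        assert giou(b, b) == 1.0
        assert giou_loss(b, b) == 0.0

    def test_abutting_unit_squares(self):
        # IoU 0, union 2, enclosing box 2 -> GIoU 0, loss 1
        assert giou_loss(B(0, 0, 1, 1), B(1, 0, 2, 1)) == pytest.approx(1.0)

    def test_separated_squares(self):
        # union 2, enclosing box 9 -> GIoU = -7/9, loss = 1.7778
        assert giou_loss(B(0, 0, 1, 1), B(2, 2, 3, 3)) == pytest.approx(1 + 7 / 9)

    def test_nested_boxes_equal_iou(self):
        outer, inner = B(0, 0, 10, 10), B(2, 2, 8, 8)
        assert giou(outer, inner) == pytest.approx(box_iou(outer, inner))

    def test_degenerate_box_unconstructible(self):
        with pytest.raises(ValueError):
            B(5, 5, 5, 9)

    def test_range_on_random_boxes(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x0, y0, x1, y1 = rng.integers(0, 50, 4)
            a = B(min(x0, x1), min(y0, y1), min(x0, x1) + 1 + abs(x1 - x0), min(y0, y1) + 1 + abs(y1 - y0))
            x0, y0, x1, y1 = rng.integers(0, 50, 4)
            b = B(min(x0, x1), min(y0, y1), min(x0, x1) + 1 + abs(x1 - x0), min(y0, y1) + 1 + abs(y1 - y0))
            assert -1.0 < giou(a, b) <= 1.0


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "tp,fp,fn,expect",
        [(10, 0, 0, (1.0, 1.0)), (8, 2, 4, (0.8, 8 / 12)), (0, 5, 3, (0.0, 0.0))],
    )
    def test_examples(self, tp, fp, fn, expect):
        p, r = precision_recall(MatchCounts(tp, fp, fn))
        assert (p, r) == pytest.approx(expect)

    def test_undefined_denominators_warn_nan(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            p, _ = precision_recall(MatchCounts(0, 0, 3))
        assert np.isnan(p)
        with pytest.warns(UserWarning, match="recall undefined"):
            _, r = precision_recall(MatchCounts(0, 4, 0))
        assert np.isnan(r)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MatchCounts(-1, 0, 0)


class TestMatchDetections:
    def test_perfect_predictions(self):
        truth = [B(0, 0, 10, 10), B(20, 20, 30, 30)]
        pred = [B(0, 0, 10, 10, 1.0), B(20, 20, 30, 30, 1.0)]
        counts, _ = match_detections(pred, truth)
        assert (counts.TP, counts.FP, counts.FN) == (2, 0, 0)

    def test_one_pred_covering_two_truths(self):
        truth = [B(0, 0, 10, 10), B(0, 0, 11, 10)]
        pred = [B(0, 0, 10, 10, 0.9)]
        counts, _ = match_detections(pred, truth)
        assert (counts.TP, counts.FP, counts.FN) == (1, 0, 1)

    def test_empty_predictions(self):
        counts, _ = match_detections([], [B(0, 0, 5, 5)] * 0 + [B(0, 0, 5, 5), B(9, 9, 14, 14)])
        assert (counts.TP, counts.FP, counts.FN) == (0, 0, 2)

    def test_agrees_with_oracle_on_random_small_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            def rand_boxes(n):
                out = []
                for _ in range(n):
                    x0, y0 = rng.integers(0, 12, 2)
                    out.append(B(x0, y0, x0 + rng.integers(1, 8), y0 + rng.integers(1, 8),
                                 round(float(rng.random()), 3)))
                return out

            pred = rand_boxes(rng.integers(0, 5))
            truth = [BoundingBox(b.x0, b.y0, b.x1, b.y1) for b in rand_boxes(rng.integers(0, 5))]
            counts, ranked = match_detections(pred, truth)
            tp_o, ranked_o = greedy_match_oracle(pred, truth)
            assert counts.TP == tp_o
            assert ranked.ranked == ranked_o
            assert ap50(ranked) == pytest.approx(ap_oracle(ranked_o, len(truth)), abs=1e-12)


class TestAp50:
    def test_all_correct(self):
        r = RankedDetections([(1.0, True)] * 4, 4)
        assert ap50(r) == 1.0

    def test_no_matches(self):
        assert ap50(RankedDetections([(0.9, False), (0.8, False)], 3)) == 0.0

    def test_match_miss_match_staircase(self):
        # precisions 1, 1/2, 2/3 at recalls 1/2, 1/2, 1 -> AP = 0.8333
        r = RankedDetections([(0.9, True), (0.8, False), (0.7, True)], 2)
        assert ap50(r) == pytest.approx(5 / 6)

    def test_empty_problem_scores_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert ap50(RankedDetections([], 0)) == 1.0

    def test_invariant_to_uniform_confidence_rescaling(self):
        base = [(0.9, True), (0.5, False), (0.4, True), (0.2, False)]
        r1 = ap50(RankedDetections(base, 3))
        r2 = ap50(RankedDetections([(c / 2, m) for c, m in base], 3))
        assert r1 == r2

    def test_101_point_variant_close_to_all_point(self):
        r = RankedDetections([(0.9, True), (0.8, False), (0.7, True)], 2)
        assert ap50(r, n_interp=101) == pytest.approx(ap50(r), abs=0.02)


class TestMaskMetrics:
    def test_identical_masks(self):
        m = np.random.default_rng(0).random((8, 8)) < 0.4
        assert dice(m, m) == 1.0 and iou(m, m) == 1.0 and dice_loss(m, m) == 0.0

    def test_half_overlap_arithmetic(self):
        x = np.zeros((4, 4), bool); x[0, 0] = x[0, 1] = True
        y = np.zeros((4, 4), bool); y[0, 1] = y[0, 2] = True
        assert dice(x, y) == pytest.approx(0.5)
        assert iou(x, y) == pytest.approx(1 / 3)

    def test_disjoint_masks(self):
        x = np.zeros((4, 4), bool); x[0, 0] = True
        y = np.zeros((4, 4), bool); y[3, 3] = True
        assert dice(x, y) == 0.0 and iou(x, y) == 0.0 and dice_loss(x, y) == 1.0

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), bool)
        with pytest.warns(UserWarning):
            assert dice(z, z) == 1.0
        with pytest.warns(UserWarning):
            assert iou(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4), bool), np.zeros((4, 5), bool))

    @settings(deadline=None, max_examples=80)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_iou_dice_identity_fuzzed(self, seed):
        rng = np.random.default_rng(seed)
        side = int(rng.integers(1, 64))
        x = rng.random((side, side)) < rng.uniform(0, 1)
        y = rng.random((side, side)) < rng.uniform(0, 1)
        if not (x.any() or y.any()):
            return
        d = dice(x, y)
        assert iou(x, y) == pytest.approx(d / (2 - d), abs=1e-12)
        assert dice_loss(x, y) == 1.0 - d


class TestFitReliability:
    def test_perfect_agreement(self):
        fit = fit_reliability([1, 2, 3], [1, 2, 3])
        assert fit.r2 == pytest.approx(1.0) and fit.rmse == 0.0

    def test_constant_offset(self):
        fit = fit_reliability([1, 2, 3], [2, 3, 4])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_uncorrelated_data_low_r2(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        assert fit_reliability(x, y).r2 < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_reliability([2, 2, 2], [1, 2, 3])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_reliability([1, 2], [1, 2])
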