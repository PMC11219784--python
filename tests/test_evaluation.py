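import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmbisnet.evaluation import (ConfusionCounts, accuracy, auc_closed_form,
                                 binarize_prediction, confusion,
                                 evaluate_dataset, f1_score, metrics_report,
                                 render_error_overlay, roc_auc_sweep,
                                 sensitivity, specificity)
from lmbisnet.training import dice_loss
from lmbisnet.types import ValidationError

counts_st = st.builds(ConfusionCounts, tp=st.integers(0, 1000), tn=st.integers(0, 1000),
                      fp=st.integers(0, 1000), fn=st.integers(0, 1000))


class TestConfusion:
    def test_perfect_all_ones(self):
        m = np.ones((4, 4), dtype=np.uint8)
        c = confusion(m, m)
        assert (c.tp, c.tn, c.fp, c.fn) == (16, 0, 0, 0)

    def test_all_false_positive(self):
        c = confusion(np.ones((2, 2), dtype=np.uint8), np.zeros((2, 2), dtype=np.uint8))
        assert c.fp == 4 and c.tp == c.tn == c.fn == 0

    def test_matches_brute_force_loop(self, rng):
        pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        gt = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        c = confusion(pred, gt)
        tp = tn = fp = fn = 0
        for i in range(8):
            for j in range(8):
                if pred[i, j] and gt[i, j]:
                    tp += 1
                elif pred[i, j] and not gt[i, j]:
                    fp += 1
                elif not pred[i, j] and gt[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_fov_restriction(self, rng):
        pred = np.ones((4, 4), dtype=np.uint8)
        gt = np.ones((4, 4), dtype=np.uint8)
        fov = np.zeros((4, 4), dtype=np.uint8)
        fov[:2] = 1
        c = confusion(pred, gt, fov)
        assert c.total == 8 and c.tp == 8

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            confusion(np.full((2, 2), 3), np.zeros((2, 2), dtype=np.uint8))


class TestPointMetrics:
    @pytest.mark.parametrize("fn,counts,expected", [
        (sensitivity, dict(tp=1, fn=0, tn=0, fp=0), 1.0),
        (sensitivity, dict(tp=3, fn=1, tn=0, fp=0), 0.75),
        (sensitivity, dict(tp=0, fn=5, tn=0, fp=0), 0.0),
        (specificity, dict(tn=1, fp=0, tp=0, fn=0), 1.0),
        (specificity, dict(tn=9, fp=1, tp=0, fn=0), 0.9),
        (specificity, dict(tn=0, fp=2, tp=0, fn=0), 0.0),
        (accuracy, dict(tp=5, tn=5, fp=0, fn=0), 1.0),
        (accuracy, dict(tp=2, tn=6, fp=1, fn=1), 0.8),
        (accuracy, dict(tp=0, tn=0, fp=3, fn=3), 0.0),
        (f1_score, dict(tp=4, tn=0, fp=0, fn=0), 1.0),
        (f1_score, dict(tp=2, fp=1, fn=1, tn=0), 2 / 3),
        (f1_score, dict(tp=0, fp=2, fn=3, tn=0), 0.0),
        (auc_closed_form, dict(tp=1, tn=1, fp=0, fn=0), 1.0),
        (auc_closed_form, dict(tp=8, fn=2, tn=9, fp=1), 0.85),
    ])
    def test_hand_computed_values(self, fn, counts, expected):
        assert fn(ConfusionCounts(**counts)) == pytest.approx(expected)

    def test_all_background_prediction_on_balanced_pixels(self):
        # FPR=0, FNR=1 -> AUC = 1 - 0.5
        c = ConfusionCounts(tp=0, fn=50, tn=50, fp=0)
        assert auc_closed_form(c) == pytest.approx(0.5)

    def test_undefined_metrics_are_nan_not_zero(self):
        c = ConfusionCounts(tp=0, fn=0, tn=4, fp=0)
        assert math.isnan(sensitivity(c))
        assert math.isnan(auc_closed_form(c))
        assert math.isnan(f1_score(ConfusionCounts(0, 5, 0, 0)))

    @settings(deadline=None, max_examples=200)
    @given(counts_st)
    def test_auc_identity_with_balanced_accuracy(self, c):
        """Closed-form AUC equals (Se+Sp)/2 exactly, in rational arithmetic."""
        if c.fp + c.tn == 0 or c.fn + c.tp == 0:
            assert math.isnan(auc_closed_form(c))
            return
        se = Fraction(c.tp, c.tp + c.fn)
        sp = Fraction(c.tn, c.tn + c.fp)
        exact = 1 - Fraction(1, 2) * (Fraction(c.fp, c.fp + c.tn) + Fraction(c.fn, c.fn + c.tp))
        assert exact == (se + sp) / 2
        assert auc_closed_form(c) == pytest.approx(float(exact), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(counts_st)
    def test_adding_a_true_positive_never_hurts(self, c):
        c2 = ConfusionCounts(c.tp + 1, c.tn, c.fp, c.fn)
        for fn in (sensitivity, accuracy, f1_score):
            a, b = fn(c), fn(c2)
            if not (math.isnan(a) or math.isnan(b)):
                assert b >= a - 1e-12

    def test_f1_equals_one_minus_dice_loss(self, rng):
        pred = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        gt = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        c = confusion(pred, gt)
        assert f1_score(c) == pytest.approx(
            1.0 - dice_loss(pred.astype(float), gt.astype(float), smooth=0.0))


class TestBinarize:
    def test_strict_threshold_ties_to_background(self):
        assert binarize_prediction(np.full((3, 3), 0.5)).sum() == 0

    def test_simple_values(self):
        out = binarize_prediction(np.array([[0.2, 0.9]]))
        assert out.tolist() == [[0, 1]]

    def test_zero_threshold(self):
        out = binarize_prediction(np.array([[0.0, 0.01]]), threshold=0.0)
        assert out.tolist() == [[0, 1]]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            binarize_prediction(np.array([[1.2]]))


class TestEvaluateDataset:
    def test_single_image_mean_is_itself(self, rng):
        pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        gt = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        summary, table = evaluate_dataset([pred], [gt])
        assert summary.se == pytest.approx(table["Se"].iloc[0])

    def test_mean_of_two_images(self):
        # image 1: Se 0.8 ; image 2: Se 0.6
        gt = np.ones((1, 10), dtype=np.uint8)
        p1 = np.array([[1, 1, 1, 1, 1, 1, 1, 1, 0, 0]], dtype=np.uint8)
        p2 = np.array([[1, 1, 1, 1, 1, 1, 0, 0, 0, 0]], dtype=np.uint8)
        summary, _ = evaluate_dataset([p1, p2], [gt, gt])
        assert summary.se == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_dataset([], [])

    def test_misaligned_rejected(self, rng):
        m = (rng.random((4, 4)) > 0.5).astype(np.uint8)
        with pytest.raises(ValidationError):
            evaluate_dataset([m], [m, m])

    def test_pooled_aggregation(self, rng):
        preds = [(rng.random((6, 6)) > 0.5).astype(np.uint8) for _ in range(3)]
        gts = [(rng.random((6, 6)) > 0.5).astype(np.uint8) for _ in range(3)]
        summary, table = evaluate_dataset(preds, gts, pooled=True)
        tot = ConfusionCounts(int(table["TP"].sum()), int(table["TN"].sum()),
                              int(table["FP"].sum()), int(table["FN"].sum()))
        assert summary.acc == pytest.approx(accuracy(tot))


class TestOverlay:
    def test_perfect_prediction_only_green_and_black(self, rng):
        gt = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        img = render_error_overlay(gt, gt)
        colours = {tuple(c) for c in img.reshape(-1, 3)}
        assert colours <= {(0, 255, 0), (0, 0, 0)}

    def test_missed_vessels_are_blue(self):
        gt = np.ones((4, 4), dtype=np.uint8)
        img = render_error_overlay(np.zeros_like(gt), gt)
        assert (img == (0, 0, 255)).all(axis=-1).all()

    def test_colour_counts_equal_confusion_counts(self, rng):
        pred = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        gt = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        c = confusion(pred, gt)
        img = render_error_overlay(pred, gt)
        assert (img == (0, 255, 0)).all(axis=-1).sum() == c.tp
        assert (img == (255, 0, 0)).all(axis=-1).sum() == c.fp
        assert (img == (0, 0, 255)).all(axis=-1).sum() == c.fn
        assert (img == (0, 0, 0)).all(axis=-1).sum() == c.tn


def test_sweep_auc_on_separable_probabilities(rng):
    """The trapezoidal ROC-AUC reaches 1 on perfectly separated scores and
    stays near 0.5 for uninformative ones."""
    gt = (rng.random((32, 32)) > 0.5).astype(np.uint8)
    assert roc_auc_sweep(gt.astype(float), gt) == pytest.approx(1.0)
    noise = rng.random((32, 32))
    assert abs(roc_auc_sweep(noise, gt) - 0.5) < 0.1


def test_metrics_report_percent_rendering():
    r = metrics_report(ConfusionCounts(tp=8, fn=2, tn=9, fp=1))
    pct = r.as_percent()
    assert pct["Se"] == pytest.approx(80.0)
    assert pct["AUC"] == pytest.approx(85.0)
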