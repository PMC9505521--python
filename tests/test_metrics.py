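"""Confusion-count metrics against a brute-force pixel oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rfilm.metrics import ConfusionCounts, confusion, miou_over_set, panel


def brute_force_counts(pred, truth):
    """Independent double-loop recount of TP/TN/FP/FN."""
    tp = tn = fp = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j], truth[i, j]
            if p == 1 and t == 1:
                tp += 1
            elif p == 0 and t == 0:
                tn += 1
            elif p == 1 and t == 0:
                fp += 1
            else:
                fn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def brute_force_panel(counts):
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = tp + tn + fp + fn
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return {
        "accuracy": (tp + tn) / total,
        "precision": prec,
        "recall": rec,
        "f1": 2 * prec * rec / (prec + rec),
        "iou": 0.5 * (tp / (tp + fp + fn) + tn / (tn + fn + fp)),
    }


class TestConfusion:
    def test_perfect_all_ones(self):
        ones = np.ones((10, 10), dtype=np.uint8)
        c = confusion(ones, ones)
        assert (c.tp, c.tn, c.fp, c.fn) == (100, 0, 0, 0)

    def test_complement_masks(self):
        truth = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        pred = 1 - truth
        c = confusion(pred, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 2, 2)

    def test_matches_double_loop_recount(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pred = rng.integers(0, 2, (64, 64), dtype=np.uint8)
            truth = rng.integers(0, 2, (64, 64), dtype=np.uint8)
            assert confusion(pred, truth) == brute_force_counts(pred, truth)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 2)))


class TestPanel:
    def test_hand_computed_case(self):
        p = panel(ConfusionCounts(tp=50, tn=30, fp=10, fn=10))
        assert p.accuracy == pytest.approx(0.80)
        assert p.precision == pytest.approx(50 / 60)
        assert p.recall == pytest.approx(50 / 60)
        assert p.f1 == pytest.approx(50 / 60)
        assert p.iou == pytest.approx(0.5 * (50 / 70 + 30 / 50))

    def test_absent_film_class_is_vacuously_perfect(self):
        p = panel(ConfusionCounts(tp=0, tn=100, fp=0, fn=0))
        assert p.accuracy == 1.0
        assert p.iou == 1.0
        assert p.precision == 1.0 and p.recall == 1.0

    def test_perfect_nontrivial_mask(self):
        p = panel(ConfusionCounts(tp=40, tn=60, fp=0, fn=0))
        assert (p.accuracy, p.precision, p.recall, p.f1, p.iou) == (1, 1, 1, 1, 1)

    def test_all_false_positive_precision_zero(self):
        p = panel(ConfusionCounts(tp=0, tn=0, fp=4, fn=0))
        assert p.precision == 0.0

    def test_zero_pixels_rejected(self):
        with pytest.raises(ValueError):
            panel(ConfusionCounts(0, 0, 0, 0))

    @settings(max_examples=50, derandomize=True)
    @given(
        masks=hnp.arrays(np.uint8, (2, 12, 12), elements=st.integers(0, 1)),
    )
    def test_label_swap_symmetry(self, masks):
        """Swapping class labels in both masks leaves the mean IOU unchanged."""
        pred, truth = masks
        a = panel(confusion(pred, truth)).iou
        b = panel(confusion(1 - pred, 1 - truth)).iou
        assert a == pytest.approx(b, abs=1e-15)

    @settings(max_examples=50, derandomize=True)
    @given(
        masks=hnp.arrays(np.uint8, (2, 10, 10), elements=st.integers(0, 1)),
    )
    def test_accuracy_dominates_class_fractions(self, masks):
        pred, truth = masks
        c = confusion(pred, truth)
        p = panel(c)
        assert p.accuracy >= c.tp / c.total - 1e-15
        assert p.accuracy >= c.tn / c.total - 1e-15


class TestMiouOverSet:
    def test_per_image_mean_of_two(self):
        # image A: IOU 1 (perfect empty); image B computed by hand
        a = (np.zeros((2, 2), dtype=np.uint8), np.zeros((2, 2), dtype=np.uint8))
        pred_b = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        truth_b = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        iou_b = panel(confusion(pred_b, truth_b)).iou
        result = miou_over_set([a, (pred_b, truth_b)], "per_image_mean")
        assert result == pytest.approx(0.5 * (1 + iou_b))

    def test_single_image_modes_agree(self):
        rng = np.random.default_rng(1)
        pair = (rng.integers(0, 2, (8, 8)), rng.integers(0, 2, (8, 8)))
        assert miou_over_set([pair], "per_image_mean") == miou_over_set([pair], "pooled")

    def test_pooled_equals_summed_counts(self):
        rng = np.random.default_rng(2)
        pairs = [
            (rng.integers(0, 2, (16, 16), dtype=np.uint8), rng.integers(0, 2, (16, 16), dtype=np.uint8))
            for _ in range(10)
        ]
        total = ConfusionCounts(0, 0, 0, 0)
        for p, t in pairs:
            total = total + brute_force_counts(p, t)
        assert miou_over_set(pairs, "pooled") == pytest.approx(panel(total).iou, abs=1e-15)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            miou_over_set([])
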