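import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonguecrack import BinaryCounts, ConfusionCounts, cls_metrics, confusion, seg_metrics


def brute_force_metrics(gt, pred):
    """Per-pixel tally and direct formulas, independent of the library
    implementation."""
    P = np.zeros((2, 2), dtype=int)
    for i in range(gt.shape[0]):
        for j in range(gt.shape[1]):
            P[int(gt[i, j] > 0), int(pred[i, j] > 0)] += 1
    total = P.sum()
    rows = P.sum(axis=1)
    cols = P.sum(axis=0)
    cpa = [P[i, i] / rows[i] for i in range(2) if rows[i] > 0]
    iou, weights = [], []
    for i in range(2):
        union = rows[i] + cols[i] - P[i, i]
        if rows[i] > 0 or cols[i] > 0:
            iou.append(P[i, i] / union)
            weights.append(rows[i] / total)
    mpa = sum(cpa) / len(cpa)
    miou = sum(iou) / len(iou)
    fwiou = sum(w * v for w, v in zip(weights, iou))
    return P, mpa, miou, fwiou


class TestConfusion:
    def test_identical_masks_are_diagonal(self):
        mask = (np.arange(64).reshape(8, 8) % 3 == 0).astype(np.uint8)
        P = confusion(mask, mask).P
        assert P[0, 1] == P[1, 0] == 0
        assert P.sum() == 64

    def test_all_background_vs_all_crack(self):
        gt = np.zeros((10, 10), np.uint8)
        pred = np.ones((10, 10), np.uint8)
        P = confusion(gt, pred).P
        assert P[0, 1] == 100 and P.sum() == 100

    def test_accepts_0_255_masks(self):
        gt = np.zeros((4, 4), np.uint8)
        gt[0, 0] = 255
        P = confusion(gt, gt).P
        assert P[1, 1] == 1 and P[0, 0] == 15

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_accumulation_is_entrywise_sum(self):
        rng = np.random.default_rng(0)
        a_gt, a_pr = (rng.random((8, 8)) < 0.5), (rng.random((8, 8)) < 0.5)
        b_gt, b_pr = (rng.random((8, 8)) < 0.5), (rng.random((8, 8)) < 0.5)
        both = confusion(a_gt, a_pr) + confusion(b_gt, b_pr)
        stacked = confusion(
            np.concatenate([a_gt, b_gt]), np.concatenate([a_pr, b_pr])
        )
        assert np.array_equal(both.P, stacked.P)


class TestSegMetrics:
    def test_worked_two_class_example(self):
        m = seg_metrics(ConfusionCounts(np.array([[8, 2], [1, 9]])))
        assert m["MPA"] == pytest.approx(0.85)
        assert m["CPA_crack"] == pytest.approx(0.9)
        assert m["IoU_crack"] == pytest.approx(9 / 12)
        assert m["MIoU"] == pytest.approx((8 / 11 + 9 / 12) / 2)
        assert m["FWIoU"] == pytest.approx(0.5 * 8 / 11 + 0.5 * 9 / 12)

    def test_perfect_prediction_scores_one_everywhere(self):
        m = seg_metrics(ConfusionCounts(np.array([[40, 0], [0, 24]])))
        assert all(v == pytest.approx(1.0) for v in m.values())

    def test_complement_prediction_gives_zero_mpa(self):
        m = seg_metrics(ConfusionCounts(np.array([[0, 7], [5, 0]])))
        assert m["MPA"] == 0.0 and m["MIoU"] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            seg_metrics(ConfusionCounts.zeros())

    def test_single_class_fwiou_equals_its_iou(self):
        m = seg_metrics(ConfusionCounts(np.array([[37, 0], [0, 0]])))
        assert m["FWIoU"] == pytest.approx(1.0)
        m = seg_metrics(ConfusionCounts(np.array([[30, 7], [0, 0]])))
        assert m["FWIoU"] == pytest.approx(30 / 37)

    def test_transposing_confusion_preserves_miou(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            P = rng.integers(0, 50, size=(2, 2))
            P[0, 0] += 1
            a = seg_metrics(ConfusionCounts(P))["MIoU"]
            b = seg_metrics(ConfusionCounts(P.T))["MIoU"]
            assert a == pytest.approx(b)

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            gt = (rng.random((8, 8)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
            pred = (rng.random((8, 8)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
            counts = confusion(gt, pred)
            P, mpa, miou, fwiou = brute_force_metrics(gt, pred)
            assert np.array_equal(counts.P, P)
            m = seg_metrics(counts)
            assert m["MPA"] == pytest.approx(mpa, abs=1e-12)
            assert m["MIoU"] == pytest.approx(miou, abs=1e-12)
            assert m["FWIoU"] == pytest.approx(fwiou, abs=1e-12)


class TestClsMetrics:
    def test_full_sensitivity_when_no_false_negatives(self):
        m = cls_metrics(BinaryCounts(TP=35, FN=0, TN=20, FP=8))
        assert m["SE"] == pytest.approx(1.0)

    def test_symmetric_counts_give_half(self):
        m = cls_metrics(BinaryCounts(TP=1, FP=1, TN=1, FN=1))
        assert m["SE"] == m["SP"] == m["ACC"] == pytest.approx(0.5)

    def test_worked_example(self):
        m = cls_metrics(BinaryCounts(TP=3, FN=1, TN=2, FP=2))
        assert m["SE"] == pytest.approx(0.75)
        assert m["SP"] == pytest.approx(0.5)
        assert m["ACC"] == pytest.approx(0.625)

    def test_zero_denominator_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="specificity"):
            m = cls_metrics(BinaryCounts(TP=3, FN=1, TN=0, FP=0))
        assert np.isnan(m["SP"]) and m["SE"] == pytest.approx(0.75)

    def test_from_pairs(self):
        m = BinaryCounts.from_pairs([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (m.TP, m.FN, m.TN, m.FP) == (2, 1, 1, 1)

    @settings(max_examples=50, deadline=None)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_metrics_lie_in_unit_interval(self, tp, fp, tn, fn):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = cls_metrics(BinaryCounts(TP=tp, FP=fp, TN=tn, FN=fn))
        for v in m.values():
            assert np.isnan(v) or 0.0 <= v <= 1.0
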