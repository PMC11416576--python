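import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundusseg.losses_metrics import (
    DiceLossConfig,
    MetricsReport,
    SideOutputConfig,
    dice_coefficient,
    iou,
    mean_iou,
    multilabel_dice_grad,
    multilabel_dice_loss,
    pixel_accuracy,
    side_output_loss,
)


def eq9_scalar_reference(p, g, w, eps=0.0):
    """Term-by-term scalar evaluation of the weighted Dice loss (oracle)."""
    total = 0.0
    for k in range(len(w)):
        inter = sum(p[i][k] * g[i][k] for i in range(len(p)))
        den = (sum(p[i][k] ** 2 for i in range(len(p)))
               + sum(g[i][k] ** 2 for i in range(len(p))) + eps)
        total += 2.0 * w[k] * inter / den
    return 1.0 - total


def fd_gradient(p, g, cfg, h=1e-6):
    grad = np.zeros_like(p)
    for idx in np.ndindex(*p.shape):
        pp = p.copy()
        pp[idx] = p[idx] + h
        pm = p.copy()
        pm[idx] = p[idx] - h
        grad[idx] = (multilabel_dice_loss(pp.clip(0, 1 + h), g, cfg)
                     - multilabel_dice_loss(pm.clip(-h, 1), g, cfg)) / (2 * h)
    return grad


class TestDiceLoss:
    def test_perfect_overlap_zero(self, rng):
        g = (rng.random((20, 2)) > 0.5).astype(float)
        g[0] = [1, 1]  # both classes non-empty
        assert multilabel_dice_loss(g, g) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_one(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        g = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 0.0]])
        assert multilabel_dice_loss(p, g) == pytest.approx(1.0, abs=1e-6)

    def test_hand_worked_example(self):
        # N=2, K=2, w=(0.5, 0.5): loss = 1 - 0.8/1.8 - 0.9/1.85 = 23/333
        p = np.array([[0.8, 0.2], [0.4, 0.9]])
        g = np.array([[1.0, 0.0], [0.0, 1.0]])
        cfg = DiceLossConfig(smoothing_eps=0.0)
        expected = eq9_scalar_reference(p.tolist(), g.tolist(), (0.5, 0.5))
        assert expected == pytest.approx(23.0 / 333.0, abs=1e-12)
        assert multilabel_dice_loss(p, g, cfg) == pytest.approx(expected,
                                                                abs=1e-10)

    def test_range_and_k1_reduction(self, rng):
        for _ in range(20):
            p = rng.random((30, 1))
            g = (rng.random((30, 1)) > 0.4).astype(float)
            if g.sum() == 0:
                g[0] = 1
            cfg = DiceLossConfig(n_classes=1, class_weights=(1.0,),
                                 smoothing_eps=0.0)
            loss = multilabel_dice_loss(p, g, cfg)
            soft_dice = 2 * (p * g).sum() / ((p ** 2).sum() + (g ** 2).sum())
            assert loss == pytest.approx(1.0 - soft_dice, abs=1e-12)
            assert 0.0 <= loss <= 1.0

    def test_empty_class_with_zero_eps_raises(self):
        p = np.zeros((4, 1))
        g = np.zeros((4, 1))
        with pytest.raises(FloatingPointError):
            multilabel_dice_loss(p, g, DiceLossConfig(n_classes=1,
                                                      class_weights=(1.0,),
                                                      smoothing_eps=0.0))

    def test_shape_and_value_validation(self):
        cfg = DiceLossConfig()
        with pytest.raises(ValueError):
            multilabel_dice_loss(np.zeros((3, 2)), np.zeros((4, 2)), cfg)
        with pytest.raises(ValueError):
            multilabel_dice_loss(np.full((3, 2), 1.5), np.zeros((3, 2)), cfg)
        with pytest.raises(ValueError):
            multilabel_dice_loss(np.zeros((3, 2)), np.full((3, 2), 0.5), cfg)
        with pytest.raises(ValueError):
            DiceLossConfig(class_weights=(0.7, 0.7))


class TestDiceGradient:
    def test_matches_finite_differences(self, rng):
        cfg = DiceLossConfig()
        for _ in range(10):
            p = rng.uniform(0.05, 0.95, (12, 2))
            g = (rng.random((12, 2)) > 0.5).astype(float)
            g[0] = [1, 1]
            ana = multilabel_dice_grad(p, g, cfg)
            num = fd_gradient(p, g, cfg)
            rel = np.abs(ana - num) / np.maximum(np.abs(num), 1e-3)
            assert rel.max() < 1e-5

    def test_perfect_prediction_descent_direction(self, rng):
        g = (rng.random((15, 2)) > 0.5).astype(float)
        g[:2] = [[1, 0], [0, 1]]
        grad = multilabel_dice_grad(g, g)
        # at a perfect binary prediction the matched coordinates cannot
        # decrease the loss by growing
        assert np.all(grad[g == 1] <= 1e-9)

    def test_k1_classic_dice_gradient(self, rng):
        p = rng.uniform(0.1, 0.9, (10, 1))
        g = (rng.random((10, 1)) > 0.5).astype(float)
        g[0] = 1
        cfg = DiceLossConfig(n_classes=1, class_weights=(1.0,),
                             smoothing_eps=0.0)
        den = (p ** 2).sum() + (g ** 2).sum()
        classic = -2 * g / den + 4 * p * (p * g).sum() / den ** 2
        assert np.allclose(multilabel_dice_grad(p, g, cfg), classic,
                           atol=1e-12)


class TestSideOutputLoss:
    def test_zero_and_identity(self):
        assert side_output_loss([0, 0, 0, 0]) == 0.0
        cfg = SideOutputConfig(n_side_outputs=1, fusion_weights=(1.0,))
        assert side_output_loss([0.37], cfg) == pytest.approx(0.37)

    def test_quarter_weights_example(self):
        assert side_output_loss([0.2, 0.4, 0.6, 0.8]) == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            side_output_loss([0.1, 0.2])


class TestMetrics:
    def test_pixel_accuracy(self, rng):
        m = rng.integers(0, 6, (8, 8))
        assert pixel_accuracy(m, m) == 1.0
        assert pixel_accuracy(np.array([1, 0, 1, 0]),
                              np.array([0, 1, 0, 1])) == 0.0
        assert pixel_accuracy(np.array([1, 1, 1, 0]),
                              np.array([1, 1, 1, 1])) == 0.75

    def test_iou_cases(self):
        a = np.array([1, 1, 1, 0, 0])
        assert iou(a, a) == 1.0
        assert iou(np.array([1, 0]), np.array([0, 1])) == 0.0
        # pred covers 2 of 4 gt pixels plus 1 false positive -> 2/5
        pred = np.array([1, 1, 1, 0, 0, 0])
        gt = np.array([1, 1, 0, 1, 1, 0])
        assert iou(pred, gt) == pytest.approx(0.4)
        assert iou(np.zeros(4), np.zeros(4)) == 1.0

    def test_dice_cases(self):
        pred = np.array([1, 1, 1, 0, 0, 0, 0])
        gt = np.array([1, 1, 0, 1, 1, 0, 0])
        assert dice_coefficient(pred, gt) == pytest.approx(4.0 / 7.0)
        assert dice_coefficient(np.zeros(3), np.zeros(3)) == 1.0

    def test_mean_iou(self):
        pred = np.array([0, 0, 1, 1, 1])
        gt = np.array([0, 1, 1, 1, 0])
        per_class = [iou(pred, gt, class_id=c) for c in (0, 1)]
        assert mean_iou(pred, gt, 2) == pytest.approx(np.mean(per_class))
        assert mean_iou(pred, gt, 2) <= max(per_class)
        with pytest.raises(ValueError):
            mean_iou(np.array([0, 3]), np.array([0, 1]), 2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                    max_size=40))
    def test_dice_iou_identity(self, pairs):
        pred = np.array([a for a, _ in pairs])
        gt = np.array([b for _, b in pairs])
        j = iou(pred, gt)
        assert dice_coefficient(pred, gt) == pytest.approx(2 * j / (1 + j))

    def test_permutation_invariance(self, rng):
        pred = rng.integers(0, 6, 64)
        gt = rng.integers(0, 6, 64)
        perm = rng.permutation(64)
        assert pixel_accuracy(pred, gt) == pixel_accuracy(pred[perm], gt[perm])
        assert iou(pred, gt) == iou(pred[perm], gt[perm])
        assert mean_iou(pred, gt, 6) == mean_iou(pred[perm], gt[perm], 6)

    def test_report_json(self, tmp_path):
        rep = MetricsReport(0.9, 0.8, 0.85, 0.7, 0.3)
        text = rep.to_json(tmp_path / "r.json")
        assert (tmp_path / "r.json").read_text() == text
        assert '"mean_iou": 0.7' in text
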