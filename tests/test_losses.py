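"""Closed-form and oracle checks for the four loss terms and their combination."""

import numpy as np
import pytest

from sellarnet import losses as L
from sellarnet.data import SegmentationMask
from sellarnet.nn import Tensor


def softmax_np(x, axis=0):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def one_hot_probs(labels, n_classes=3):
    return np.stack([(labels == c).astype(np.float32) for c in range(n_classes)])


def brute_force_signed_distance(region):
    """Signed distance by exhaustive pixel-pair minimization (test oracle)."""
    region = np.asarray(region, dtype=bool)
    h, w = region.shape
    inside = np.argwhere(region)
    outside = np.argwhere(~region)
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            if region[i, j]:
                d = np.sqrt(((outside - [i, j]) ** 2).sum(axis=1)).min()
                out[i, j] = -d
            else:
                d = np.sqrt(((inside - [i, j]) ** 2).sum(axis=1)).min()
                out[i, j] = d
    return out


class TestDice:
    def test_perfect_overlap_is_zero(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[1:4, 1:4] = 1
        labels[5, :] = 2
        assert float(L.dice_loss(one_hot_probs(labels), labels)) < 1e-4

    def test_disjoint_foregrounds_near_one(self):
        target = np.zeros((6, 6), dtype=int)
        target[:3] = 1
        pred_labels = np.zeros((6, 6), dtype=int)
        pred_labels[3:] = 1
        mask = SegmentationMask(target, class_annotated={1: True, 2: False})
        assert float(L.dice_loss(one_hot_probs(pred_labels), mask)) > 0.999

    def test_two_by_two_matches_hand_formula(self):
        target = np.array([[1, 0], [0, 0]])
        probs = np.zeros((3, 2, 2), dtype=np.float32)
        probs[1] = np.array([[0.5, 0.0], [0.0, 0.0]])
        probs[0] = 1.0 - probs[1]
        s = 1e-5
        expected = 1.0 - (2 * 0.5 + s) / (0.5 + 1.0 + s)
        mask = SegmentationMask(target, class_annotated={1: True, 2: False})
        assert float(L.dice_loss(probs, mask, smooth=s)) == pytest.approx(expected, abs=1e-6)

    def test_probabilities_outside_unit_interval_rejected(self):
        target = np.zeros((2, 2), dtype=int)
        bad = np.full((3, 2, 2), 1.5, dtype=np.float32)
        with pytest.raises(ValueError):
            L.dice_loss(bad, target)


class TestGeneralizedDice:
    def test_perfect_match_is_zero(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[:2, :2] = 1
        labels[2:, 2:] = 2
        assert float(L.generalized_dice_loss(one_hot_probs(labels), labels)) < 1e-4

    def test_equal_volumes_equals_plain_dice(self):
        # symmetric construction: both classes have identical volume and the
        # predictions are the mirrored pattern, so per-class Dice terms agree
        target = np.zeros((4, 4), dtype=int)
        target[:, :2] = 1
        target[:, 2:] = 2
        probs = np.zeros((3, 4, 4), dtype=np.float32)
        probs[1, :, :2] = 0.6
        probs[2, :, 2:] = 0.6
        probs[0] = 1.0 - probs[1] - probs[2]
        plain = float(L.dice_loss(probs, target, smooth=0.0))
        gen = float(L.generalized_dice_loss(probs, target, smooth=0.0))
        assert gen == pytest.approx(plain, abs=1e-6)

    def test_empty_class_no_division_by_zero(self):
        target = np.zeros((4, 4), dtype=int)
        target[:2] = 1  # class 2 absent
        probs = one_hot_probs(target)
        value = float(L.generalized_dice_loss(probs, target))
        assert np.isfinite(value)


class TestBoundary:
    def test_mass_inside_region_gives_nonpositive_value(self):
        target = np.zeros((8, 8), dtype=int)
        target[2:6, 2:6] = 1
        probs = one_hot_probs(target).astype(np.float32)
        mask = SegmentationMask(target, class_annotated={1: True, 2: False})
        assert float(L.boundary_loss(probs, mask)) <= 0

    def test_uniform_probability_equals_mean_signed_distance(self):
        target = np.zeros((4, 4), dtype=int)
        target[1:3, 1:3] = 1
        probs = np.zeros((3, 4, 4), dtype=np.float32)
        probs[1] = 1.0  # unit probability everywhere for class 1
        mask = SegmentationMask(target, class_annotated={1: True, 2: False})
        expected = brute_force_signed_distance(target == 1).mean()
        assert float(L.boundary_loss(probs, mask)) == pytest.approx(expected, abs=1e-5)

    def test_signed_distance_map_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            region = rng.random((4, 4)) > 0.5
            if not region.any() or region.all():
                continue
            np.testing.assert_allclose(
                L.signed_distance_map(region), brute_force_signed_distance(region),
                atol=1e-6)

    def test_empty_unannotated_class_skipped(self):
        target = np.zeros((4, 4), dtype=int)  # both classes empty
        probs = one_hot_probs(target)
        mask = SegmentationMask(target, class_annotated={1: False, 2: False})
        assert float(L.boundary_loss(probs, mask)) == 0.0


class TestWing:
    def test_exact_prediction_is_zero(self):
        coords = np.full(8, 0.4)
        ann = np.ones(4, bool)
        assert float(L.wing_loss(coords, coords, ann)) == 0.0

    def test_continuity_at_omega(self):
        cfg = L.LossConfig()
        omega, eps = cfg.wing_omega, cfg.wing_epsilon
        log_branch = omega * np.log(1 + omega / eps)
        linear_branch = omega - (omega - omega * np.log(1 + omega / eps))
        assert log_branch == pytest.approx(linear_branch, abs=1e-9)

    def test_no_annotation_returns_zero_with_zero_gradient(self):
        pred = Tensor(np.full(8, 0.3, dtype=np.float32), requires_grad=True)
        out = L.wing_loss(pred, np.full(8, 0.9), np.zeros(4, bool))
        assert float(out) == 0.0
        out.backward()
        np.testing.assert_array_equal(pred.grad, np.zeros(8))

    def test_monotone_nondecreasing_and_continuous_in_error(self):
        cfg = L.LossConfig()
        xs = np.linspace(0, 0.5, 400)  # normalized errors, scale -> [0, 50]
        ann = np.ones(4, bool)
        vals = [float(L.wing_loss(np.full(8, 0.25 + x / 2), np.full(8, 0.25 - x / 2), ann, cfg))
                for x in xs]
        diffs = np.diff(vals)
        assert np.all(diffs >= -1e-9)
        # no jump: per-step change bounded by the curve's max slope omega/eps
        step = (xs[1] - xs[0]) * cfg.wing_scale
        assert np.max(np.abs(diffs)) <= (cfg.wing_omega / cfg.wing_epsilon) * step + 1e-6

    def test_masked_landmark_never_changes_value(self):
        rng = np.random.default_rng(3)
        pred = rng.random(8).astype(np.float32)
        tgt = rng.random(8).astype(np.float32)
        ann = np.array([True, True, False, True])
        base = float(L.wing_loss(pred, tgt, ann))
        pred2, tgt2 = pred.copy(), tgt.copy()
        pred2[4:6] = rng.random(2)  # left_optic coords are masked out
        tgt2[4:6] = rng.random(2)
        assert float(L.wing_loss(pred2, tgt2, ann)) == pytest.approx(base, abs=1e-7)


class TestFocal:
    def test_gamma_zero_alpha_half_is_half_bce(self):
        rng = np.random.default_rng(11)
        logits = rng.normal(size=4).astype(np.float32)
        targets = np.array([1.0, 0.0, 1.0, 1.0], dtype=np.float32)
        cfg = L.LossConfig(focal_gamma=0.0, focal_alpha=0.5)
        p = 1 / (1 + np.exp(-logits))
        bce = -np.mean(targets * np.log(p) + (1 - targets) * np.log(1 - p))
        assert float(L.focal_loss(logits, targets, cfg)) == pytest.approx(0.5 * bce, rel=1e-5)

    def test_confident_correct_predictions_vanish(self):
        logits = np.array([30.0, -30.0, 30.0, -30.0], dtype=np.float32)
        targets = np.array([1.0, 0.0, 1.0, 0.0])
        assert float(L.focal_loss(logits, targets)) < 1e-8

    def test_single_probability_hand_value(self):
        p = 0.6
        logit = np.log(p / (1 - p))
        expected = -0.25 * (1 - p) ** 2 * np.log(p)
        cfg = L.LossConfig(focal_gamma=2.0, focal_alpha=0.25)
        assert float(L.focal_loss(np.array([logit]), np.array([1.0]), cfg)) == \
            pytest.approx(expected, rel=1e-5)


class TestCombined:
    def test_paper_weights_and_unit_terms(self):
        w = L.LossWeights()
        assert (w.w1, w.w2, w.w3, w.w4) == (0.9, 0.1, 0.8, 0.2)
        assert w.w1 * 1 + w.w2 * 1 + w.w3 * 1 + w.w4 * 1 == pytest.approx(2.0)

    def test_all_zero_components_give_zero_total(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[1:3, 1:3] = 1
        probs = one_hot_probs(labels)
        coords = np.full(8, 0.5, dtype=np.float32)
        ann = np.ones(4, bool)
        logits = np.full(4, 40.0, dtype=np.float32)  # presence certain and correct
        mask = SegmentationMask(labels, class_annotated={1: True, 2: False})
        bd = L.combined_loss(probs, mask, coords, coords, ann, logits)
        assert bd.total == pytest.approx(
            0.9 * bd.dice + 0.1 * bd.bdl, abs=1e-5)
        assert bd.wing == 0.0 and bd.focal < 1e-8

    @pytest.mark.parametrize("trial", range(20))
    def test_decomposition_matches_components_on_random_inputs(self, trial):
        rng = np.random.default_rng(trial)
        labels = rng.integers(0, 3, size=(6, 6))
        probs = softmax_np(rng.normal(size=(3, 6, 6)).astype(np.float32), axis=0)
        pred = rng.random(8).astype(np.float32)
        tgt = rng.random(8).astype(np.float32)
        ann = rng.random(4) > 0.3
        logits = rng.normal(size=4).astype(np.float32)
        w = L.LossWeights()
        bd = L.combined_loss(probs, labels, pred, tgt, ann, logits)
        manual = (w.w1 * float(L.dice_loss(probs, labels))
                  + w.w2 * float(L.boundary_loss(probs, labels))
                  + w.w3 * float(L.wing_loss(pred, tgt, ann))
                  + w.w4 * float(L.focal_loss(logits, ann.astype(np.float32))))
        assert bd.total == pytest.approx(manual, abs=1e-6)
        assert np.isfinite([bd.dice, bd.bdl, bd.wing, bd.focal, bd.total]).all()
        assert bd.dice >= 0 and bd.wing >= 0 and bd.focal >= 0

    def test_ablation_variants_selectable(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 3, size=(4, 4))
        probs = softmax_np(rng.normal(size=(3, 4, 4)).astype(np.float32), axis=0)
        pred, tgt = rng.random(8).astype(np.float32), rng.random(8).astype(np.float32)
        ann = np.ones(4, bool)
        cfg = L.LossConfig(seg_variant=L.SegVariant.CROSS_ENTROPY,
                           boundary_variant=L.BoundaryVariant.NONE,
                           coord_variant=L.CoordVariant.MSE)
        bd = L.combined_loss(probs, labels, pred, tgt, ann, None, config=cfg)
        assert bd.bdl == 0.0 and bd.focal == 0.0
        assert bd.dice == pytest.approx(float(L.cross_entropy_loss(probs, labels)), abs=1e-6)
        assert bd.wing == pytest.approx(
            float(L.mse_coordinate_loss(pred, tgt, ann)), abs=1e-6)
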