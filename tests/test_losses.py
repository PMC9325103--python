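"""Loss-function unit tests against hand-computed and brute-force oracles."""

import numpy as np
import pytest

from eomseg.losses import (
    DegenerateMaskError,
    LossBatch,
    boundary_loss,
    compound_loss,
    dice_loss,
    focal_tversky_loss,
    inverse_frequency_weights,
    iou_loss,
    signed_distance_map,
    wce_loss,
)


def binary_batch(pred_mask, gt_mask, eps=1e-6, **kw):
    """Two-class batch (background + one foreground class) from flat masks."""
    p = np.asarray(pred_mask, dtype=float).ravel()
    g = np.asarray(gt_mask, dtype=float).ravel()
    probs = np.stack([1 - p, p], axis=1)
    onehot = np.stack([1 - g, g], axis=1)
    return LossBatch(probs, onehot, epsilon=eps, **kw)


class TestWCE:
    def test_perfect_prediction_is_zero(self):
        b = binary_batch([1, 0, 1], [1, 0, 1], class_weights=[3.0, 7.0])
        assert wce_loss(b) == pytest.approx(0.0, abs=1e-9)

    def test_single_pixel_half_probability(self):
        probs = np.array([[0.5, 0.5]])
        onehot = np.array([[0.0, 1.0]])
        b = LossBatch(probs, onehot)
        assert wce_loss(b) == pytest.approx(np.log(2), abs=1e-9)

    def test_two_pixel_hand_sum(self):
        probs = np.array([[0.2, 0.8], [0.4, 0.6]])
        onehot = np.array([[0.0, 1.0], [0.0, 1.0]])
        b = LossBatch(probs, onehot)
        expected = -(np.log(0.8) + np.log(0.6)) / 2
        assert wce_loss(b) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.3669, abs=5e-4)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            binary_batch([1], [1], class_weights=[-1.0, 1.0])


class TestDice:
    def test_identical_masks(self):
        m = np.zeros(25)
        m[:10] = 1
        assert dice_loss(binary_batch(m, m)) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_masks(self):
        p = np.r_[np.ones(10), np.zeros(10)]
        g = np.r_[np.zeros(10), np.ones(10)]
        assert dice_loss(binary_batch(p, g)) == pytest.approx(1.0, abs=1e-6)

    def test_half_overlap(self):
        p = np.array([1, 1, 0, 0])
        g = np.array([0, 1, 1, 0])
        assert dice_loss(binary_batch(p, g)) == pytest.approx(0.5, abs=1e-6)


class TestIoU:
    def test_identical(self):
        m = np.r_[np.ones(5), np.zeros(5)]
        assert iou_loss(binary_batch(m, m)) == pytest.approx(0.0, abs=1e-6)

    def test_one_pixel_overlap_union_three(self):
        p = np.array([1, 1, 0])
        g = np.array([0, 1, 1])
        assert iou_loss(binary_batch(p, g)) == pytest.approx(1 - 1 / 3, abs=1e-6)

    def test_random_pairs_match_set_counting(self, rng):
        for _ in range(20):
            p = rng.integers(0, 2, 64)
            g = rng.integers(0, 2, 64)
            if not (p | g).any():
                continue
            inter = (p & g).sum()
            union = (p | g).sum()
            assert iou_loss(binary_batch(p, g)) == pytest.approx(
                1 - inter / union, abs=1e-5
            )

    def test_dice_iou_metric_relation(self, rng):
        """IoU loss = 1 − d/(2−d) with d the Dice score, as ε → 0."""
        for _ in range(20):
            p = rng.integers(0, 2, 64)
            g = rng.integers(0, 2, 64)
            if not p.any() and not g.any():
                continue
            b = binary_batch(p, g, eps=1e-12)
            d = 1 - dice_loss(b)
            assert iou_loss(b) == pytest.approx(1 - d / (2 - d), abs=1e-6)


class TestFocalTversky:
    def test_perfect_prediction(self):
        m = np.r_[np.ones(4), np.zeros(4)]
        assert focal_tversky_loss(binary_batch(m, m, gamma=1.0)) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_reduces_to_dice_at_alpha_beta_half_gamma_one(self, rng):
        for _ in range(10):
            p = rng.random(36)
            g = rng.integers(0, 2, 36)
            b = binary_batch(
                p, g, eps=1e-9, tversky_alpha=0.5, tversky_beta=0.5, gamma=1.0
            )
            ftl = focal_tversky_loss(b, per_class=True)
            d = dice_loss(b, per_class=True)
            assert ftl == pytest.approx(d, abs=1e-6)

    def test_fixed_pair_matches_exhaustive_sum(self):
        rng = np.random.default_rng(4)
        p = rng.random(16)
        g = rng.integers(0, 2, 16).astype(float)
        a, bta, gam, eps = 0.7, 0.3, 4 / 3, 1e-6
        inter = sum(pi * gi for pi, gi in zip(p, g))
        fp = sum(pi * (1 - gi) for pi, gi in zip(p, g))
        fn = sum((1 - pi) * gi for pi, gi in zip(p, g))
        ti = (inter + eps) / (inter + a * fp + bta * fn + eps)
        expected = (1 - ti) ** (1 / gam)
        b = binary_batch(p, g, tversky_alpha=a, tversky_beta=bta, gamma=gam)
        assert focal_tversky_loss(b) == pytest.approx(expected, abs=1e-9)

    def test_gamma_outside_range_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            binary_batch([1.0], [1.0], gamma=4.0)


class TestSignedDistance:
    def test_single_pixel_neighbours(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        phi = signed_distance_map(m)
        assert phi[2, 2] == 0.0
        for r, c in [(1, 2), (3, 2), (2, 1), (2, 3)]:
            assert phi[r, c] == pytest.approx(1.0)

    def test_sign_convention(self):
        m = np.zeros((9, 9), bool)
        m[2:7, 2:7] = True
        phi = signed_distance_map(m)
        assert np.all(phi[3:6, 3:6] < 0)  # strict interior
        assert np.all(phi[~m] > 0)
        assert np.all(phi[m][np.abs(phi[m]) < 1e-12] == 0)

    def test_matches_all_pairs_oracle(self, rng):
        m = rng.random((16, 16)) < 0.4
        if not m.any() or m.all():
            m[0, 0] = True
            m[5, 5] = False
        phi = signed_distance_map(m)
        # oracle: exhaustive distance to the 4-connected boundary pixel set
        bnd = []
        h, w = m.shape
        for r in range(h):
            for c in range(w):
                if not m[r, c]:
                    continue
                nb = [
                    (r + dr, c + dc)
                    for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]
                ]
                if any(
                    not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]
                    for rr, cc in nb
                ):
                    bnd.append((r, c))
        bnd = np.array(bnd)
        for r in range(h):
            for c in range(w):
                d = np.sqrt(((bnd - [r, c]) ** 2).sum(axis=1)).min()
                expected = -d if m[r, c] else d
                assert phi[r, c] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("mask", [np.zeros((4, 4), bool), np.ones((4, 4), bool)])
    def test_degenerate_masks_rejected(self, mask):
        with pytest.raises(DegenerateMaskError):
            signed_distance_map(mask)


class TestBoundaryLoss:
    def _batch_with_phi(self, p, g):
        b = binary_batch(p.ravel(), g.ravel())
        phi = np.full_like(b.probs, np.nan)
        phi[:, 1] = signed_distance_map(g.astype(bool)).ravel()
        phi[:, 0] = np.nan  # background class skipped
        b.phi_g = phi
        return b

    def test_zero_prediction_gives_zero(self):
        g = np.zeros((8, 8))
        g[2:6, 2:6] = 1
        b = self._batch_with_phi(np.zeros((8, 8)), g)
        assert boundary_loss(b) == pytest.approx(0.0)

    def test_interior_mass_decreases_loss(self):
        g = np.zeros((8, 8))
        g[2:6, 2:6] = 1
        p = np.zeros((8, 8))
        base = boundary_loss(self._batch_with_phi(p, g))
        p[3, 3] = 0.9  # strictly interior ground-truth pixel
        assert boundary_loss(self._batch_with_phi(p, g)) < base

    def test_matches_exhaustive_sum(self, rng):
        g = (rng.random((16, 16)) < 0.3).astype(float)
        g[0, 0], g[8, 8] = 1, 0
        p = rng.random((16, 16))
        b = self._batch_with_phi(p, g)
        phi = signed_distance_map(g.astype(bool))
        expected = sum(
            phi[r, c] * p[r, c] for r in range(16) for c in range(16)
        )
        assert boundary_loss(b) == pytest.approx(expected, rel=1e-9)

    def test_missing_phi_rejected(self):
        b = binary_batch([1, 0], [1, 0])
        with pytest.raises(ValueError, match="phi_g"):
            boundary_loss(b)


class TestCompound:
    def test_wce_dice_is_member_sum(self, rng):
        p = rng.random(25)
        g = rng.integers(0, 2, 25)
        b = binary_batch(p, g)
        members = {}
        total = compound_loss(b, "wce+dice", members=members)
        assert total == pytest.approx(wce_loss(b) + dice_loss(b), rel=1e-12)
        assert set(members) == {"wce", "dice"}

    def test_perfect_prediction_zero(self):
        m = np.r_[np.ones(5), np.zeros(5)]
        assert compound_loss(binary_batch(m, m), "wce+dice") == pytest.approx(
            0.0, abs=1e-5
        )

    def test_dice_boundary_on_zero_prediction(self):
        g = np.zeros((8, 8))
        g[2:5, 2:5] = 1
        b = binary_batch(np.zeros(64), g.ravel())
        phi = np.full_like(b.probs, np.nan)
        phi[:, 1] = signed_distance_map(g.astype(bool)).ravel()
        b.phi_g = phi
        members = {}
        compound_loss(b, "dice+boundary", members=members)
        assert members["dice"] == pytest.approx(1.0, abs=1e-5)
        assert members["boundary"] == pytest.approx(0.0)

    def test_unknown_recipe_rejected(self):
        with pytest.raises(ValueError, match="recipe"):
            compound_loss(binary_batch([1], [1]), "dice+jaccard")


class TestInvariantsAndGradients:
    def test_permutation_invariance(self, rng):
        p = rng.random(40)
        g = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        for fn in (wce_loss, dice_loss, iou_loss, focal_tversky_loss):
            a = fn(binary_batch(p, g))
            b = fn(binary_batch(p[perm], g[perm]))
            assert a == pytest.approx(b, rel=1e-9)

    def test_ranges(self, rng):
        for _ in range(10):
            p = rng.random(30)
            g = rng.integers(0, 2, 30)
            b = binary_batch(p, g)
            assert 0 <= dice_loss(b) <= 1
            assert 0 <= iou_loss(b) <= 1
            assert wce_loss(b) >= 0
            assert focal_tversky_loss(b) >= 0

    def test_moving_mass_to_true_class_never_hurts(self, rng):
        p = rng.random(30) * 0.8
        g = rng.integers(0, 2, 30).astype(float)
        p2 = p + 0.1 * (g - p) * (g == 1)  # raise true-class probability
        p2 = np.where(g == 1, np.minimum(p + 0.1, 1.0), p)
        for fn in (wce_loss, dice_loss, iou_loss, focal_tversky_loss):
            assert fn(binary_batch(p2, g)) <= fn(binary_batch(p, g)) + 1e-9

    def test_analytic_gradients_match_finite_differences(self, rng):
        """Each loss's dL/dp agrees with central differences (float64)."""
        n, c = 30, 3
        raw = rng.random((n, c)) + 0.1
        probs = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, c, n)
        onehot = np.eye(c)[labels]
        phi = np.empty((n, c))
        for k in range(c):
            m = (labels == k).reshape(6, 5)
            phi[:, k] = signed_distance_map(m).ravel() if m.any() and not m.all() else np.nan

        weights = rng.random(c) + 0.5

        def make(pb):
            b = LossBatch(pb, onehot, class_weights=weights,
                          phi_g=phi, validate=False)
            return b

        for fn in (wce_loss, dice_loss, iou_loss, focal_tversky_loss, boundary_loss):
            val, grad = fn(make(probs), grad=True)
            for _ in range(6):
                i, j = rng.integers(0, n), rng.integers(0, c)
                eps = 1e-6
                pp = probs.copy(); pp[i, j] += eps
                pm = probs.copy(); pm[i, j] -= eps
                num = (fn(make(pp)) - fn(make(pm))) / (2 * eps)
                assert num == pytest.approx(grad[i, j], rel=1e-3, abs=1e-7), fn.__name__


def test_inverse_frequency_weights_mean_one(rng):
    labs = [rng.integers(0, 4, (10, 10)) for _ in range(3)]
    w = inverse_frequency_weights(labs, 9)
    assert w.mean() == pytest.approx(1.0)
    assert np.all(w > 0)
    # rarer classes get larger weights
    counts = np.bincount(np.concatenate([l.ravel() for l in labs]), minlength=9)[:4]
    order_by_count = np.argsort(counts)
    assert w[order_by_count[0]] >= w[order_by_count[-1]]
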