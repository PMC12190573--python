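import numpy as np
import pytest

from liunet.objectives import (CombinedLossConfig, FocalLossConfig,
                               combined_loss, dice_loss, dice_loss_and_grad,
                               focal_loss, focal_loss_and_grad,
                               focal_loss_binary, multiclass_focal_and_grad,
                               multiclass_focal_loss, soft_dice_and_grad,
                               soft_dice_coefficient)


def _random_probs(rng, shape):
    p = rng.random(shape) + 0.05
    return p / p.sum(axis=-1, keepdims=True)


def _random_onehot(rng, shape):
    labels = rng.integers(0, shape[-1], shape[:-1])
    return np.eye(shape[-1])[labels]


class TestSoftDice:
    def test_half_overlap_arithmetic(self):
        p = np.array([1.0, 1, 0, 0])
        g = np.array([0.0, 1, 1, 0])
        assert soft_dice_coefficient(p.reshape(1, 1, 4), g.reshape(1, 1, 4),
                                     eps=0.0) == pytest.approx(0.5)

    def test_perfect_overlap(self, rng):
        g = _random_onehot(rng, (4, 4, 4, 4))
        assert soft_dice_coefficient(g, g) == pytest.approx(1.0, abs=1e-6)
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_binary_masks(self):
        p = np.array([1.0, 0]).reshape(1, 1, 2)
        g = np.array([0.0, 1]).reshape(1, 1, 2)
        eps = 1e-6
        assert soft_dice_coefficient(p, g, eps=eps) == pytest.approx(eps / (2 + eps))
        assert dice_loss(p, g) == pytest.approx(1.0, abs=1e-5)

    def test_multiclass_averages_foreground_only(self, rng):
        p = _random_probs(rng, (3, 3, 3, 4))
        g = _random_onehot(rng, (3, 3, 3, 4))
        per_channel = [soft_dice_coefficient(p[..., c].ravel(), g[..., c].ravel(),
                                             eps=1e-6)
                       for c in range(1, 4)]
        assert soft_dice_coefficient(p, g) == pytest.approx(np.mean(per_channel))

    def test_loss_bounds(self, rng):
        p = _random_probs(rng, (3, 3, 3, 4))
        g = _random_onehot(rng, (3, 3, 3, 4))
        assert 0.0 <= dice_loss(p, g) <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice_loss(np.zeros((2, 2, 2, 4)), np.zeros((2, 2, 3, 4)))


class TestFocal:
    def test_zero_at_certain_prediction(self):
        assert focal_loss(np.ones((4, 4, 4))) == 0.0

    def test_reduces_to_cross_entropy(self, rng):
        p_t = rng.uniform(0.05, 0.95, (5, 5, 5))
        fl = focal_loss(p_t, FocalLossConfig(alpha=1.0, gamma=0.0))
        assert fl == pytest.approx(float(-np.log(p_t).mean()), abs=1e-9)

    def test_single_voxel_hand_value(self):
        # -0.25 * (1-0.5)^2 * ln 0.5 = 0.25 * 0.25 * ln 2
        expected = 0.25 * 0.25 * np.log(2.0)
        got = focal_loss(np.array([0.5]), FocalLossConfig(alpha=0.25, gamma=2.0))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.0433217, abs=1e-7)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            FocalLossConfig(gamma=-1.0)

    def test_monotone_nonincreasing_in_pt(self):
        grid = np.linspace(0.01, 1.0, 200)
        values = [focal_loss(np.array([p])) for p in grid]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_binary_form_consistency(self, rng):
        """Eq-style binary expansion agrees with the p_t formulation on the
        positive class and weights the negative class by 1 - alpha."""
        cfg = FocalLossConfig(alpha=0.25, gamma=2.0)
        p = rng.uniform(0.1, 0.9, (4, 4, 4))
        all_pos = focal_loss_binary(np.ones_like(p), p, cfg)
        assert all_pos == pytest.approx(focal_loss(p, cfg), rel=1e-9)
        all_neg = focal_loss_binary(np.zeros_like(p), p, cfg)
        expected = float((-(1 - cfg.alpha) * p ** 2 * np.log(1 - p)).mean())
        assert all_neg == pytest.approx(expected, rel=1e-9)

    def test_per_class_alpha_weights(self, rng):
        g = _random_onehot(rng, (3, 3, 3, 4))
        p = _random_probs(rng, (3, 3, 3, 4))
        alpha_t = np.array([0.1, 0.3, 0.3, 0.3])
        cfg = FocalLossConfig(alpha=0.25, gamma=2.0, alpha_t=alpha_t)
        p_t = (p * g).sum(-1)
        a = (g * alpha_t).sum(-1)
        expected = float((-a * (1 - p_t) ** 2 * np.log(p_t)).mean())
        assert multiclass_focal_loss(p, g, cfg) == pytest.approx(expected, rel=1e-9)


class TestCombined:
    def test_lambda_linearity_is_exact(self, rng):
        p = _random_probs(rng, (3, 3, 3, 4))
        g = _random_onehot(rng, (3, 3, 3, 4))
        dl = dice_loss(p, g)
        fl = multiclass_focal_loss(p, g)
        assert combined_loss(p, g, CombinedLossConfig(0.0, 1.0)) == dl
        assert combined_loss(p, g, CombinedLossConfig(1.0, 0.0)) == fl
        assert combined_loss(p, g, CombinedLossConfig(1.0, 1.0)) == fl + dl
        both = combined_loss(p, g, CombinedLossConfig(0.3, 1.7))
        assert both == pytest.approx(0.3 * fl + 1.7 * dl, abs=1e-9)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            CombinedLossConfig(0.0, 0.0)


class TestGradients:
    """Analytic loss gradients against central finite differences."""

    @staticmethod
    def _fd(fn, p, eps=1e-6):
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            pp = p.copy(); pp[idx] += eps
            pm = p.copy(); pm[idx] -= eps
            g[idx] = (fn(pp) - fn(pm)) / (2 * eps)
        return g

    @pytest.fixture
    def pg(self, rng):
        p = _random_probs(rng, (2, 3, 3, 4))
        g = _random_onehot(rng, (2, 3, 3, 4))
        return p, g

    def test_dice_gradient(self, pg):
        p, g = pg
        _, grad = dice_loss_and_grad(p, g)
        fd = self._fd(lambda q: dice_loss_and_grad(q, g)[0], p)
        np.testing.assert_allclose(grad, fd, rtol=1e-3, atol=1e-9)

    def test_focal_gradient(self, pg):
        p, g = pg
        _, grad = multiclass_focal_and_grad(p, g)
        fd = self._fd(lambda q: multiclass_focal_and_grad(q, g)[0], p)
        np.testing.assert_allclose(grad, fd, rtol=1e-3, atol=1e-9)

    def test_focal_gradient_pt_form(self, rng):
        p_t = rng.uniform(0.05, 0.95, (4, 4, 4))
        _, grad = focal_loss_and_grad(p_t)
        fd = self._fd(lambda q: focal_loss_and_grad(q)[0], p_t)
        np.testing.assert_allclose(grad, fd, rtol=1e-3, atol=1e-9)

    def test_combined_gradient_is_weighted_sum(self, pg):
        from liunet.objectives import combined_loss_and_grad
        p, g = pg
        cfg = CombinedLossConfig(0.4, 1.3)
        _, grad = combined_loss_and_grad(p, g, cfg)
        _, fg = multiclass_focal_and_grad(p, g)
        _, dg = dice_loss_and_grad(p, g)
        np.testing.assert_allclose(grad, 0.4 * fg + 1.3 * dg, atol=1e-12)
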