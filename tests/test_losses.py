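import numpy as np
import pytest

from msunet.losses import (LossConfig, composite_loss, downsample_target,
                           schedules, smooth_truncated_ce, soft_dice_loss)
from msunet.nn import Tensor


class TestSmoothTruncatedCE:
    def test_continuity_at_knot(self):
        val = smooth_truncated_ce(0.1, 0.1)
        assert val == pytest.approx(-np.log(0.1), abs=1e-12)
        # approach from below
        below = smooth_truncated_ce(0.1 - 1e-9, 0.1)
        assert below == pytest.approx(val, abs=1e-6)

    def test_perfect_prediction_is_zero(self):
        assert smooth_truncated_ce(1.0, 0.1) == pytest.approx(0.0)

    def test_quadratic_branch_at_zero(self):
        assert smooth_truncated_ce(0.0, 0.1) == pytest.approx(
            -np.log(0.1) + 0.5)  # 2.802585

    def test_c1_at_knot_random_gammas(self):
        """Both one-sided derivatives at gamma equal -1/gamma."""
        rng = np.random.default_rng(0)
        eps = 1e-7
        for gamma in rng.uniform(0.02, 0.9, size=20):
            f = lambda p: smooth_truncated_ce(p, gamma)
            left = (f(gamma) - f(gamma - eps)) / eps
            right = (f(gamma + eps) - f(gamma)) / eps
            assert left == pytest.approx(-1 / gamma, rel=1e-4)
            assert right == pytest.approx(-1 / gamma, rel=1e-4)

    def test_bounded_by_cross_entropy(self):
        """ST <= -log(p) everywhere, equality for p >= gamma."""
        p = np.linspace(1e-9, 1.0, 1001)
        gamma = 0.1
        st = smooth_truncated_ce(p, gamma)
        ce = -np.log(p)
        assert (st <= ce + 1e-12).all()
        np.testing.assert_allclose(st[p >= gamma], ce[p >= gamma])

    def test_printed_variant_is_constant_above_knot(self):
        p = np.array([0.2, 0.5, 0.9])
        st = smooth_truncated_ce(p, 0.1, variant="printed")
        np.testing.assert_allclose(st, -np.log(0.1))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            smooth_truncated_ce(1.5, 0.1)
        with pytest.raises(ValueError):
            smooth_truncated_ce(0.5, 1.5)


class TestSoftDice:
    def test_identical_binary_is_zero(self):
        q = np.array([0, 1, 1, 0, 1], dtype=float)
        assert soft_dice_loss(q, q) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_half_closed_form(self):
        # p = 0.5 everywhere, foreground fraction f = 0.5:
        # 1 - f/(0.25 + f) = 1/3
        q = np.zeros(100)
        q[:50] = 1
        p = np.full(100, 0.5)
        assert soft_dice_loss(p, q) == pytest.approx(1 / 3, abs=1e-6)

    def test_disjoint_supports(self):
        p = np.array([1.0, 0, 0, 0])
        q = np.array([0.0, 0, 0, 1])
        assert soft_dice_loss(p, q) == pytest.approx(1.0, abs=1e-5)

    def test_empty_vs_empty_is_zero(self):
        z = np.zeros(10)
        assert soft_dice_loss(z, z) == pytest.approx(0.0)


class TestSchedules:
    def test_gamma_endpoints(self):
        cfg = LossConfig(total_epochs=30)
        g0, _, _ = schedules(0, 100, cfg)
        g_last, _, _ = schedules(29, 100, cfg)
        assert g0 == pytest.approx(0.02)
        assert g_last == pytest.approx(0.15)

    def test_alpha_at_midpoint_volume(self):
        cfg = LossConfig()
        _, alpha, beta = schedules(0, cfg.schedule_midpoint_volume, cfg)
        assert alpha == pytest.approx(50.5)
        assert beta == pytest.approx(0.5)

    def test_alpha_limits(self):
        cfg = LossConfig()
        _, a_small, _ = schedules(0, 0, cfg)
        _, a_big, b_big = schedules(0, 1e9, cfg)
        assert a_small == pytest.approx(100.0, rel=0.15)
        assert a_big == pytest.approx(1.0, abs=1e-6)
        assert b_big == pytest.approx(1.0, abs=1e-6)

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            schedules(30, 0, LossConfig(total_epochs=30))


class TestDownsampleTarget:
    def test_maxpool_keeps_single_voxel_lesion(self):
        t = np.zeros((4, 4, 4), dtype=np.uint8)
        t[1, 2, 3] = 1
        down = downsample_target(t, (2, 2, 2))
        assert down.sum() == 1
        assert down[0, 1, 1] == 1


class TestCompositeLoss:
    def test_perfect_prediction_all_terms_zero(self):
        target = np.zeros((4, 4, 4), dtype=np.uint8)
        target[1:3, 1:3, 1:3] = 1
        preds = [target.astype(float),
                 downsample_target(target, (2, 2, 2)).astype(float)]
        total, bd = composite_loss(preds, target, 0, LossConfig())
        assert bd.dice == pytest.approx(0.0, abs=1e-6)
        assert bd.fg_st == pytest.approx(0.0, abs=1e-6)
        assert bd.bg_st == pytest.approx(0.0, abs=1e-6)
        assert float(total.data) == pytest.approx(0.0, abs=1e-5)

    def test_breakdown_identity(self):
        rng = np.random.default_rng(0)
        target = (rng.random((4, 4, 4)) < 0.3).astype(np.uint8)
        pred = rng.random((4, 4, 4))
        total, bd = composite_loss([pred], target, 3,
                                   LossConfig(total_epochs=10))
        assert bd.total == pytest.approx(
            bd.alpha * bd.fg_st + bd.beta * bd.bg_st + bd.dice, rel=1e-5)

    def test_hand_computed_single_voxel_target(self):
        """Single foreground voxel, p = 0.5 everywhere, gamma = 0.1."""
        target = np.zeros((2, 2, 2), dtype=np.uint8)
        target[0, 0, 0] = 1
        p = np.full((2, 2, 2), 0.5)
        cfg = LossConfig(gamma_start=0.1, gamma_end=0.1, total_epochs=1,
                         alpha_max=100, beta_max=1.0,
                         schedule_midpoint_volume=100,
                         schedule_steepness=50)
        total, bd = composite_loss([p], target, 0, cfg)
        st_half = -np.log(0.5)             # 0.6931, p >= gamma branch
        assert bd.fg_st == pytest.approx(st_half, rel=1e-6)
        assert bd.bg_st == pytest.approx(st_half, rel=1e-6)
        # dice: 2*0.5 / (8*0.25 + 1) = 1/3
        assert bd.dice == pytest.approx(1 - (2 * 0.5) / (8 * 0.25 + 1),
                                        rel=1e-5)
        # schedules at v=1: alpha = 1 + 99*sigma(99/50), beta = sigma(-99/50)
        sig = 1 / (1 + np.exp(-(1 - 100) / 50))
        assert bd.alpha == pytest.approx(1 + 99 * (1 - sig), rel=1e-6)
        assert bd.beta == pytest.approx(sig, rel=1e-6)
        assert float(total.data) == pytest.approx(bd.total, rel=1e-6)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        target = (rng.random((3, 3, 3)) < 0.3).astype(np.uint8)
        logits = rng.standard_normal((3, 3, 3))
        cfg = LossConfig(total_epochs=5)

        def loss_value(lg):
            p = Tensor(lg).sigmoid()
            total, _ = composite_loss([p], target, 2, cfg)
            return float(total.data)

        t = Tensor(logits, requires_grad=True)
        total, _ = composite_loss([t.sigmoid()], target, 2, cfg)
        total.backward()
        eps = 1e-6
        num = np.zeros_like(logits)
        for idx in np.ndindex(logits.shape):
            lg = logits.copy()
            lg[idx] += eps
            fp = loss_value(lg)
            lg[idx] -= 2 * eps
            fm = loss_value(lg)
            num[idx] = (fp - fm) / (2 * eps)
        np.testing.assert_allclose(t.grad, num, atol=1e-4)

    def test_empty_foreground_target(self):
        target = np.zeros((2, 2, 2), dtype=np.uint8)
        p = np.full((2, 2, 2), 0.2)
        total, bd = composite_loss([p], target, 0, LossConfig())
        assert bd.fg_st == 0.0
        assert np.isfinite(float(total.data))
        # alpha schedule evaluated at v = 0: 1 + 99*sigma(100/50)
        assert bd.alpha == pytest.approx(1 + 99 / (1 + np.exp(-2.0)),
                                         rel=1e-6)

    def test_descent_under_gradient_flow(self):
        """Loss decreases monotonically along small gradient steps."""
        rng = np.random.default_rng(2)
        target = (rng.random((3, 3, 3)) < 0.4).astype(np.uint8)
        logits = 0.5 * rng.standard_normal((3, 3, 3))
        cfg = LossConfig(total_epochs=5)
        losses = []
        for _ in range(30):
            t = Tensor(logits, requires_grad=True)
            total, _ = composite_loss([t.sigmoid()], target, 0, cfg)
            total.backward()
            losses.append(float(total.data))
            logits = logits - 0.01 * t.grad
        assert all(b < a + 1e-9 for a, b in zip(losses, losses[1:]))
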