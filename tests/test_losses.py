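"""Loss functions: closed forms, binary-limit consistency, gradients."""

import numpy as np
import pytest

import oracles
from topotube.autodiff import Tensor
from topotube.losses import (
    EPSILON,
    LossWeights,
    cascaded_loss,
    soft_cl_dice_loss,
    soft_dice_loss,
)
from topotube.metrics import SegPair, cl_dice, dice_coefficient


def _rand_binary(rng, shape=(6, 6, 6), p=0.3):
    return (rng.random(shape) < p).astype(np.float64)


class TestSoftDice:
    def test_perfect_prediction_near_zero(self, rng):
        t = _rand_binary(rng)
        assert soft_dice_loss(t, t).item() == pytest.approx(0.0, abs=1e-4)

    def test_inverted_prediction_near_one(self, rng):
        t = _rand_binary(rng)
        assert soft_dice_loss(1.0 - t, t).item() == pytest.approx(1.0, abs=1e-3)

    def test_uniform_half_closed_form(self):
        # pred = 0.5 everywhere, target fills half the volume
        t = np.zeros((4, 4, 4)); t[:2] = 1.0
        p = np.full((4, 4, 4), 0.5)
        n = t.size
        expected = 1 - (2 * 0.5 * n / 2 + EPSILON) / (0.5 * n + n / 2 + EPSILON)
        assert soft_dice_loss(p, t).item() == pytest.approx(expected, rel=1e-6)

    def test_binary_limit_matches_metric(self, rng):
        p, t = _rand_binary(rng), _rand_binary(rng)
        loss = soft_dice_loss(p, t).item()
        assert loss == pytest.approx(1 - dice_coefficient(p > 0, t > 0), abs=1e-4)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((4, 4, 4)), np.zeros((5, 5, 5)))


class TestSoftClDice:
    def test_identical_consistent_pairs_near_zero(self, rng):
        s = _rand_binary(rng, p=0.4)
        c = s * _rand_binary(rng, p=0.3)  # centerline inside the segmentation
        assert soft_cl_dice_loss(s, s, c, c).item() == pytest.approx(0.0, abs=1e-3)

    def test_disjoint_inputs_near_one(self):
        s_p = np.zeros((6, 6, 6)); s_p[0] = 1
        s_g = np.zeros((6, 6, 6)); s_g[3] = 1
        c_p = np.zeros((6, 6, 6)); c_p[0, 0] = 1
        c_g = np.zeros((6, 6, 6)); c_g[3, 3] = 1
        assert soft_cl_dice_loss(s_p, s_g, c_p, c_g).item() == pytest.approx(1.0, abs=1e-3)

    def test_near_binary_matches_hard_metric(self, rng):
        """Soft loss on {0.01, 0.99} inputs tracks the hard clDice after
        thresholding at 0.5, within 0.05."""
        for _ in range(5):
            s_g, c_g = _rand_binary(rng, p=0.4), _rand_binary(rng, p=0.15)
            s_p = np.where(_rand_binary(rng, p=0.4) > 0, 0.99, 0.01)
            c_p = np.where(_rand_binary(rng, p=0.15) > 0, 0.99, 0.01)
            soft = 1 - soft_cl_dice_loss(s_p, s_g, c_p, c_g).item()
            hard = cl_dice(SegPair(s_p > 0.5, s_g > 0.5, c_p > 0.5, c_g > 0.5))
            assert soft == pytest.approx(hard, abs=0.05)

    def test_binary_limit_matches_bruteforce(self, rng):
        s_p, s_g = _rand_binary(rng, p=0.5), _rand_binary(rng, p=0.5)
        c_p, c_g = _rand_binary(rng, p=0.2), _rand_binary(rng, p=0.2)
        soft = 1 - soft_cl_dice_loss(s_p, s_g, c_p, c_g).item()
        assert soft == pytest.approx(
            oracles.cl_dice_bruteforce(s_p, s_g, c_p, c_g), abs=1e-3
        )


class TestCascadedLoss:
    def test_linear_combination_of_terms(self, rng):
        s_p, s_g = rng.random((6, 6, 6)), _rand_binary(rng)
        c_p, c_g = rng.random((6, 6, 6)), _rand_binary(rng, p=0.15)
        w = LossWeights(0.5, 0.5)
        total = cascaded_loss(s_p, s_g, c_p, c_g, w).item()
        expected = (
            soft_dice_loss(s_p, s_g).item()
            + 0.5 * soft_dice_loss(c_p, c_g).item()
            + 0.5 * soft_cl_dice_loss(s_p, s_g, c_p, c_g).item()
        )
        assert total == pytest.approx(expected, rel=1e-6)

    def test_zero_weights_reduce_to_dice(self, rng):
        s_p, s_g = rng.random((6, 6, 6)), _rand_binary(rng)
        c_p, c_g = rng.random((6, 6, 6)), _rand_binary(rng)
        w = LossWeights(0.0, 0.0)
        assert cascaded_loss(s_p, s_g, c_p, c_g, w).item() == pytest.approx(
            soft_dice_loss(s_p, s_g).item()
        )

    def test_perfect_prediction_near_zero(self, rng):
        s = _rand_binary(rng, p=0.4)
        c = s * _rand_binary(rng, p=0.3)
        assert cascaded_loss(s, s, c, c).item() == pytest.approx(0.0, abs=1e-3)

    def test_bounded(self, rng):
        for _ in range(10):
            s_p, c_p = rng.random((6, 6, 6)), rng.random((6, 6, 6))
            s_g, c_g = _rand_binary(rng), _rand_binary(rng)
            v = cascaded_loss(s_p, s_g, c_p, c_g, LossWeights(0.5, 0.5)).item()
            assert 0.0 <= v <= 2.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0.5)


class TestGradients:
    def test_finite_difference_agreement(self, rng):
        """Autodiff gradient of the combined loss w.r.t. both predictions
        matches central differences at 1e-4 relative tolerance (4^3 input)."""
        sp = rng.random((4, 4, 4))
        cp = rng.random((4, 4, 4))
        sg = _rand_binary(rng, (4, 4, 4))
        cg = _rand_binary(rng, (4, 4, 4), p=0.2)
        SP, CP = Tensor(sp, True), Tensor(cp, True)
        loss = cascaded_loss(SP, sg, CP, cg, LossWeights(0.5, 0.5))
        loss.backward()
        h = 1e-6
        for which, T, arr in (("S_P", SP, sp), ("C_P", CP, cp)):
            for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3), (2, 0, 1)]:
                plus, minus = arr.copy(), arr.copy()
                plus[idx] += h
                minus[idx] -= h
                if which == "S_P":
                    lp = cascaded_loss(Tensor(plus), sg, Tensor(cp), cg).item()
                    lm = cascaded_loss(Tensor(minus), sg, Tensor(cp), cg).item()
                else:
                    lp = cascaded_loss(Tensor(sp), sg, Tensor(plus), cg).item()
                    lm = cascaded_loss(Tensor(sp), sg, Tensor(minus), cg).item()
                fd = (lp - lm) / (2 * h)
                assert fd == pytest.approx(float(T.grad[idx]), rel=1e-4, abs=1e-10)

    def test_gradients_reach_both_inputs(self, rng):
        SP = Tensor(rng.random((4, 4, 4)), True)
        CP = Tensor(rng.random((4, 4, 4)), True)
        loss = cascaded_loss(SP, _rand_binary(rng, (4, 4, 4)), CP, _rand_binary(rng, (4, 4, 4)))
        loss.backward()
        assert SP.grad is not None and np.abs(SP.grad).max() > 0
        assert CP.grad is not None and np.abs(CP.grad).max() > 0
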