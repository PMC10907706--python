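"""Losses: worked examples, degeneracy, the hard/easy ratio mechanism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsfnet.losses import (
    LossConfig,
    dice_loss,
    focal_loss,
    improved_dice_loss,
    mixed_loss,
)
from dsfnet.nn.tensor import Tensor


def scalar(p):
    return np.array([float(p)], dtype=np.float64)


ONE = scalar(1.0)


@pytest.mark.parametrize(
    "pred, gamma_prime, expected",
    [
        (0.8, 0.0, 0.111),
        (0.5, 0.0, 0.333),
        (0.8, 1.0, 0.012),
        (0.5, 1.0, 0.111),
    ],
)
def test_improved_dice_worked_examples(pred, gamma_prime, expected):
    """Scalar Dice / improved-Dice values at y=1 match to 3 decimals (eps=0)."""
    got = improved_dice_loss(scalar(pred), ONE, gamma_prime, epsilon=0.0)
    assert round(got, 3) == expected


@pytest.mark.parametrize(
    "pred, gamma, expected, tol",
    [
        (1.0, 2.0, 0.0, 1e-6),            # perfect prediction
        (0.5, 0.0, math.log(2.0), 1e-9),  # gamma=0 is cross-entropy
        (0.9, 2.0, 0.01 * -math.log(0.9), 1e-12),
    ],
)
def test_focal_worked_examples(pred, gamma, expected, tol):
    assert focal_loss(scalar(pred), ONE, gamma) == pytest.approx(expected, abs=tol)


def test_mixed_loss_hand_derived_example():
    """alpha=0.5, y_hat=0.8, y=1, gamma=2, gamma'=1: both closed forms by hand."""
    cfg = LossConfig(alpha=0.5, gamma=2.0, gamma_prime=1.0, epsilon=1e-12)
    expected_dice = 1.0 - (4 * 0.8) / (1.8 ** 2)
    expected_focal = 0.2 ** 2 * -math.log(0.8)
    got = mixed_loss(scalar(0.8), ONE, cfg)
    assert got == pytest.approx(0.5 * expected_dice + 0.5 * expected_focal, abs=1e-6)
    assert got == pytest.approx(0.010635, abs=1e-5)


def test_mixed_loss_alpha_endpoints(rng):
    pred = rng.random((2, 1, 8, 8))
    target = (rng.random((2, 1, 8, 8)) > 0.7).astype(float)
    d = improved_dice_loss(pred, target, 1.0, 1e-6)
    f = focal_loss(pred, target, 2.0)
    assert mixed_loss(pred, target, LossConfig(alpha=1.0)) == pytest.approx(d, rel=1e-12)
    assert mixed_loss(pred, target, LossConfig(alpha=0.0)) == pytest.approx(f, rel=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    seed=st.integers(0, 2 ** 31 - 1),
    eps=st.floats(1e-8, 1e-3),
    fg=st.floats(0.0, 1.0),
)
def test_gamma_prime_zero_degenerates_to_dice(seed, eps, fg):
    """improved_dice_loss with gamma'=0 equals dice_loss on arbitrary tensors."""
    r = np.random.default_rng(seed)
    pred = r.random((3, 1, 6, 6))
    target = (r.random((3, 1, 6, 6)) < fg).astype(float)
    assert improved_dice_loss(pred, target, 0.0, eps) == pytest.approx(
        dice_loss(pred, target, eps), abs=1e-9
    )


def test_hard_easy_loss_ratio_mechanism():
    """L(t=0.5)/L(t=0.8) is 3 at gamma'=0, 9 at gamma'=1, non-decreasing between."""
    def ratio(gp):
        return improved_dice_loss(scalar(0.5), ONE, gp, 0.0) / improved_dice_loss(
            scalar(0.8), ONE, gp, 0.0
        )

    assert ratio(0.0) == pytest.approx(3.0, rel=1e-9)
    assert ratio(1.0) == pytest.approx(9.0, rel=1e-9)
    grid = [ratio(g) for g in np.linspace(0.0, 1.0, 11)]
    assert all(b >= a - 1e-12 for a, b in zip(grid, grid[1:]))


def test_focal_gamma_zero_is_cross_entropy(rng):
    """Against an independent mean-BCE oracle on random inputs."""
    pred = np.clip(rng.random((4, 1, 16, 16)), 1e-6, 1 - 1e-6)
    target = (rng.random((4, 1, 16, 16)) > 0.5).astype(float)
    bce = -(target * np.log(pred) + (1 - target) * np.log(1 - pred)).mean()
    assert focal_loss(pred, target, gamma=0.0) == pytest.approx(bce, abs=1e-6)


def test_improved_dice_monotone_in_t_with_endpoints():
    ts = np.linspace(0.0, 1.0, 201)
    for gp in (0.0, 0.3, 0.7, 1.0):
        vals = [improved_dice_loss(scalar(t), ONE, gp, 0.0) for t in ts]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(0.0, abs=1e-6)
        assert vals[0] == pytest.approx(1.0, abs=1e-6)


def test_losses_finite_nonnegative_on_edge_cases(rng):
    cases = [
        (np.zeros((2, 4, 4)), np.zeros((2, 4, 4))),          # all background
        (np.ones((2, 4, 4)), np.ones((2, 4, 4))),            # saturated, correct
        (np.zeros((2, 4, 4)), np.ones((2, 4, 4))),           # saturated, wrong
        (rng.random((2, 4, 4)), np.zeros((2, 4, 4))),        # empty foreground
    ]
    for pred, target in cases:
        for val in (
            focal_loss(pred, target, 2.0),
            dice_loss(pred, target),
            improved_dice_loss(pred, target, 1.0),
            mixed_loss(pred, target, LossConfig()),
        ):
            assert np.isfinite(val) and val >= 0.0


def test_empty_foreground_dice_is_zero(rng):
    pred = rng.random((2, 4, 4))
    target = np.zeros((2, 4, 4))
    assert dice_loss(pred, target) == 0.0
    assert improved_dice_loss(pred, target, 1.0) == 0.0


def test_easy_sample_gradient_downweighted():
    """Near t=1 the improved Dice gradient is smaller for gamma'=1 than 0."""
    def grad_mag(gp):
        p = Tensor(np.array([0.97], dtype=np.float32), requires_grad=True)
        loss = improved_dice_loss(p, Tensor(np.array([1.0], np.float32)), gp, 1e-6)
        loss.backward()
        return abs(float(p.grad[0]))

    assert grad_mag(1.0) < grad_mag(0.0)


def test_contract_violations(rng):
    pred = rng.random((2, 4))
    with pytest.raises(ValueError):
        focal_loss(pred, np.zeros((2, 5)), 2.0)  # shape mismatch
    with pytest.raises(ValueError):
        focal_loss(pred, np.full((2, 4), 0.5), 2.0)  # non-binary target
    with pytest.raises(ValueError):
        focal_loss(pred, np.zeros((2, 4)), -1.0)  # negative gamma
    with pytest.raises(ValueError):
        improved_dice_loss(pred, np.zeros((2, 4)), 1.5)  # gamma' out of range
    for bad in (
        dict(alpha=1.2),
        dict(gamma=-0.1),
        dict(gamma_prime=-0.2),
        dict(epsilon=0.0),
    ):
        with pytest.raises(ValueError):
            LossConfig(**bad)
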