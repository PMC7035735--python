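"""Adversarial objectives and Bhattacharyya distances against oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate

from dra import objectives as obj
from dra.autodiff import Tensor
from dra.objectives import (
    AdversarialLossPair,
    ScoreBatch,
    bd_adversarial_loss,
    bhattacharyya_discrete,
    bhattacharyya_gaussian,
    gradient_penalty,
    standard_gan_loss,
    wasserstein_loss,
)


class TestScoreBatch:
    def test_probability_domain_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ScoreBatch([0.5, 1.0], [0.2], "probability")

    def test_unbounded_domain_accepts_any_reals(self):
        sb = ScoreBatch([-5.0, 3.0], [0.0], "unbounded")
        assert sb.score_domain == "unbounded"


class TestStandardGAN:
    def test_uninformative_discriminator_value(self):
        pair = standard_gan_loss(ScoreBatch([0.5, 0.5], [0.5, 0.5]))
        assert pair.discriminator_loss == pytest.approx(2 * np.log(2), rel=1e-9)

    def test_perfect_discriminator_loss_vanishes(self):
        losses = [
            standard_gan_loss(ScoreBatch([r], [1 - r])).discriminator_loss
            for r in [0.6, 0.9, 0.99, 0.999]
        ]
        assert np.all(np.diff(losses) < 0)
        assert losses[-1] < 0.01

    def test_hand_computed_value(self):
        pair = standard_gan_loss(ScoreBatch([0.8], [0.3]))
        assert pair.discriminator_loss == pytest.approx(-np.log(0.8) - np.log(0.7), rel=1e-9)
        assert pair.generator_loss == pytest.approx(-np.log(0.3), rel=1e-9)

    def test_requires_probability_domain(self):
        with pytest.raises(ValueError):
            standard_gan_loss(ScoreBatch([2.0], [-1.0], "unbounded"))


class TestWasserstein:
    @pytest.mark.parametrize(
        "real,fake,expected",
        [([1, 1], [0, 0], -1.0), ([0.3, 0.7], [0.3, 0.7], 0.0), ([0.2, 0.6], [-0.1, 0.3], -0.3)],
    )
    def test_discriminator_loss(self, real, fake, expected):
        pair = wasserstein_loss(ScoreBatch(real, fake, "unbounded"))
        assert pair.discriminator_loss == pytest.approx(expected, abs=1e-12)

    def test_generator_loss_is_negative_mean_fake(self):
        pair = wasserstein_loss(ScoreBatch([0.0], [2.0, 4.0], "unbounded"))
        assert pair.generator_loss == pytest.approx(-3.0)


class TestGradientPenalty:
    def test_unit_slope_linear_critic_has_zero_penalty(self):
        w = np.array([0.6, 0.8])  # ‖w‖ = 1

        def critic(x):
            return x @ Tensor(w)

        rng = np.random.default_rng(0)
        pen = gradient_penalty(critic, rng.normal(size=(8, 2)), rng.normal(size=(8, 2)),
                               penalty_weight=10.0, rng=rng)
        assert pen == pytest.approx(0.0, abs=1e-9)

    def test_constant_critic_penalty_equals_weight(self):
        def critic(x):
            return x.sum(axis=1) * 0.0

        rng = np.random.default_rng(1)
        pen = gradient_penalty(critic, rng.normal(size=(6, 3)), rng.normal(size=(6, 3)),
                               penalty_weight=7.0, rng=rng)
        assert pen == pytest.approx(7.0, rel=1e-4)

    def test_slope_two_critic_penalty_equals_weight(self):
        w = np.array([2 * 0.6, 2 * 0.8])  # ‖w‖ = 2 → (2−1)² = 1

        def critic(x):
            return x @ Tensor(w)

        rng = np.random.default_rng(2)
        pen = gradient_penalty(critic, rng.normal(size=(5, 2)), rng.normal(size=(5, 2)),
                               penalty_weight=10.0, rng=rng)
        assert pen == pytest.approx(10.0, rel=1e-6)

    def test_mismatched_batches_rejected(self):
        with pytest.raises(ValueError):
            gradient_penalty(lambda x: x.sum(axis=1), np.zeros((3, 2)), np.zeros((4, 2)))


class TestBhattacharyyaDiscrete:
    def test_identical_distributions_distance_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert bhattacharyya_discrete(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_infinite(self):
        assert bhattacharyya_discrete([1.0, 0.0], [0.0, 1.0]) == np.inf

    def test_hand_computed_value(self):
        expected = -np.log(np.sqrt(0.45) + np.sqrt(0.05))
        assert bhattacharyya_discrete([0.5, 0.5], [0.9, 0.1]) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("p,q", [([0.5, 0.5], [0.5]), ([0.5, 0.6], [0.5, 0.5])])
    def test_invalid_inputs(self, p, q):
        with pytest.raises(ValueError):
            bhattacharyya_discrete(p, q)

    @given(st.integers(0, 500))
    def test_nonnegative_and_zero_iff_equal(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(5))
        q = rng.dirichlet(np.ones(5))
        bd = bhattacharyya_discrete(p, q)
        assert bd >= 0.0
        if not np.allclose(p, q):
            assert bd > 0.0


class TestBhattacharyyaGaussian:
    def test_identical_gaussians(self):
        assert bhattacharyya_gaussian(1.0, 2.0, 1.0, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_value(self):
        assert bhattacharyya_gaussian(0.0, 1.0, 1.0, 1.0) == pytest.approx(0.125, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m1, m2 = rng.normal(size=2)
            v1, v2 = rng.uniform(0.1, 5, size=2)
            assert bhattacharyya_gaussian(m1, v1, m2, v2) == pytest.approx(
                bhattacharyya_gaussian(m2, v2, m1, v1), rel=1e-12
            )

    def test_matches_numeric_integration(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            m1, m2 = rng.normal(0, 2, size=2)
            v1, v2 = rng.uniform(0.2, 4, size=2)

            def integrand(x):
                p = np.exp(-((x - m1) ** 2) / (2 * v1)) / np.sqrt(2 * np.pi * v1)
                q = np.exp(-((x - m2) ** 2) / (2 * v2)) / np.sqrt(2 * np.pi * v2)
                return np.sqrt(p * q)

            coeff, _ = integrate.quad(integrand, -50, 50, limit=200)
            assert bhattacharyya_gaussian(m1, v1, m2, v2) == pytest.approx(
                -np.log(coeff), abs=1e-6
            )

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            bhattacharyya_gaussian(0.0, 0.0, 1.0, 1.0)


class TestBDAdversarial:
    def test_identical_batches_zero_losses(self):
        sb = ScoreBatch([0.4, 0.6], [0.4, 0.6])
        pair = bd_adversarial_loss(sb)
        assert pair.discriminator_loss == pytest.approx(0.0, abs=1e-12)
        assert pair.generator_loss == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_separation(self):
        # moments: N(0.85, 0.0025) vs N(0.15, 0.0025) → BD = 0.25·0.49/0.005 = 24.5
        pair = bd_adversarial_loss(ScoreBatch([0.9, 0.8], [0.1, 0.2]))
        assert pair.discriminator_loss == pytest.approx(-24.5, rel=1e-9)
        assert pair.generator_loss == pytest.approx(24.5, rel=1e-9)

    def test_swap_preserves_magnitude(self):
        a = bd_adversarial_loss(ScoreBatch([0.9, 0.8], [0.1, 0.2]))
        b = bd_adversarial_loss(ScoreBatch([0.1, 0.2], [0.9, 0.8]))
        assert abs(a.discriminator_loss) == pytest.approx(abs(b.discriminator_loss), rel=1e-12)

    def test_single_score_batches_rejected(self):
        with pytest.raises(ValueError):
            bd_adversarial_loss(ScoreBatch([0.5], [0.5]))


@given(st.integers(0, 999))
def test_all_objectives_finite_on_random_batches(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 40)
    probs = ScoreBatch(rng.uniform(0.01, 0.99, n), rng.uniform(0.01, 0.99, n))
    unb = ScoreBatch(rng.normal(size=n) * 10, rng.normal(size=n) * 10, "unbounded")
    for pair in (standard_gan_loss(probs), wasserstein_loss(unb), bd_adversarial_loss(probs)):
        assert np.isfinite(pair.discriminator_loss)
        assert np.isfinite(pair.generator_loss)
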