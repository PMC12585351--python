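"""Beta-binomial kernel: exactness, stability, and parameter transforms."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from asepop import (
    BetaBinParams,
    PrecisionPolicy,
    betabin_cmf,
    betabin_logpmf,
    betabin_loglik_grad,
    rho_theta_transform,
    rho_to_theta,
    theta_to_rho,
)
from asepop.distributions import betabin_logpmf_vec


def product_logpmf_exact(x, n, pi, theta):
    """Independent oracle: exact-rational evaluation of the rising-product
    PMF form."""
    pi, theta = Fraction(pi), Fraction(theta)
    val = Fraction(math.comb(n, x))
    for k in range(x):
        val *= pi + k * theta
    for k in range(n - x):
        val *= (1 - pi) + k * theta
    for k in range(1, n):
        val /= 1 + k * theta
    return math.log(val)


class TestLogPmf:
    def test_single_trial_collapses_to_one_minus_pi(self):
        # n=1 product has a single factor; theta cancels entirely
        val = betabin_logpmf(0, 1, BetaBinParams(pi=0.3, theta=0.7))
        assert val == pytest.approx(np.log(0.7), abs=1e-12)

    def test_theta_zero_is_exact_binomial(self):
        val = betabin_logpmf(2, 5, BetaBinParams(pi=0.5, theta=0.0))
        assert val == pytest.approx(np.log(0.3125), abs=1e-14)

    def test_matches_exact_rational_product(self):
        expected = product_logpmf_exact(3, 10, Fraction(3, 10), Fraction(1, 5))
        val = betabin_logpmf(3, 10, BetaBinParams(pi=0.3, theta=0.2))
        assert val == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("pi,theta", [(0.5, 0.01), (0.2, 0.3), (0.9, 1.5)])
    def test_normalization(self, pi, theta):
        for n in (1, 7, 30, 50):
            lp = betabin_logpmf_vec(np.arange(n + 1), n, pi, theta)
            assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-9)

    @given(
        n=st.integers(1, 40),
        x_frac=st.floats(0, 1),
        pi=st.floats(0.01, 0.99),
        theta=st.floats(1e-4, 5.0),
    )
    @settings(max_examples=80, deadline=None)
    def test_symmetry_under_allele_relabeling(self, n, x_frac, pi, theta):
        x = int(round(x_frac * n))
        a = betabin_logpmf(x, n, BetaBinParams(pi, theta))
        b = betabin_logpmf(n - x, n, BetaBinParams(1.0 - pi, theta))
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    @given(
        n=st.integers(2, 25),
        x_frac=st.floats(0, 1),
        pi=st.floats(0.05, 0.95),
        theta=st.floats(1e-3, 2.0),
    )
    @settings(max_examples=80, deadline=None)
    def test_product_and_beta_forms_agree(self, n, x_frac, pi, theta):
        from asepop.distributions import _logpmf_beta_terms, _logpmf_product

        x = int(round(x_frac * n))
        beta_val, _, _ = _logpmf_beta_terms(float(x), float(n), pi, theta)
        prod_val = _logpmf_product(x, n, pi, theta)
        assert beta_val == pytest.approx(prod_val, rel=1e-9, abs=1e-9)

    def test_variance_monotone_in_theta(self):
        # larger overdispersion strictly inflates the count variance
        n, pi = 30, 0.4
        xs = np.arange(n + 1)
        prev = -np.inf
        for theta in (0.0, 0.05, 0.2, 1.0):
            p = np.exp(betabin_logpmf_vec(xs, n, pi, theta))
            var = float(np.sum(p * xs ** 2) - np.sum(p * xs) ** 2)
            assert var > prev
            prev = var

    def test_tiny_theta_approaches_binomial(self):
        policy = PrecisionPolicy()
        val = betabin_logpmf(12, 40, BetaBinParams(pi=0.35, theta=1e-13),
                             policy=policy)
        assert val == pytest.approx(binom.logpmf(12, 40, 0.35), rel=1e-4)
        assert policy.counters["cancellation"] >= 1

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            betabin_logpmf(6, 5, BetaBinParams(0.5, 0.1))
        with pytest.raises(ValueError):
            BetaBinParams(pi=1.2, theta=0.1)
        with pytest.raises(ValueError):
            BetaBinParams(pi=0.5, theta=-0.1)


class TestCmf:
    def test_full_support_is_one(self):
        assert betabin_cmf(17, 17, BetaBinParams(0.37, 0.8)) == pytest.approx(
            1.0, abs=1e-10)

    def test_symmetric_odd_split(self):
        for theta in (0.01, 0.3, 1.0):
            assert betabin_cmf(4, 9, BetaBinParams(0.5, theta)) == pytest.approx(
                0.5, abs=1e-9)

    def test_matches_pmf_summation_oracle(self):
        expected = sum(
            math.exp(product_logpmf_exact(x, 10, Fraction(3, 10), Fraction(1, 5)))
            for x in range(4)
        )
        assert betabin_cmf(3, 10, BetaBinParams(0.3, 0.2)) == pytest.approx(
            expected, rel=1e-9)


class TestGradient:
    def test_symmetric_data_stationary_in_pi(self):
        g_pi, _ = betabin_loglik_grad([(5, 10), (5, 10)],
                                      BetaBinParams(0.5, 0.1))
        assert g_pi == pytest.approx(0.0, abs=1e-8)

    def test_binomial_mle_stationary(self):
        g_pi, _ = betabin_loglik_grad([(3, 10)], BetaBinParams(0.3, 0.0))
        assert g_pi == pytest.approx(0.0, abs=1e-5)

    def test_matches_finite_difference_oracle(self):
        data = [(3, 10), (8, 10)]
        pi, theta = 0.55, 0.1

        def ll(p, t):
            return sum(betabin_logpmf(x, n, BetaBinParams(p, t))
                       for x, n in data)

        h = 1e-6
        fd_pi = (ll(pi + h, theta) - ll(pi - h, theta)) / (2 * h)
        fd_th = (ll(pi, theta + h) - ll(pi, theta - h)) / (2 * h)
        g_pi, g_th = betabin_loglik_grad(data, BetaBinParams(pi, theta))
        assert g_pi == pytest.approx(fd_pi, rel=1e-6)
        assert g_th == pytest.approx(fd_th, rel=1e-6)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            betabin_loglik_grad([(3, 10)], BetaBinParams(0.5, 0.1),
                                weights=[1.5])


class TestTransforms:
    def test_known_values(self):
        assert theta_to_rho(1.0) == pytest.approx(0.5)
        assert theta_to_rho(0.0) == 0.0
        assert rho_to_theta(0.2) == pytest.approx(0.25)

    def test_round_trip(self):
        for rho in (0.0, 0.2, 0.5, 0.99):
            assert theta_to_rho(rho_to_theta(rho)) == pytest.approx(
                rho, abs=1e-14)

    def test_directions_and_errors(self):
        assert rho_theta_transform(1.0, "theta_to_rho") == pytest.approx(0.5)
        assert rho_theta_transform(0.5, "rho_to_theta") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            rho_to_theta(1.0)
        with pytest.raises(ValueError):
            rho_theta_transform(0.5, "sideways")
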