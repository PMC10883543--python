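"""Binomial and negative-binomial EBFs: exact sums and Beta-mass identities."""

import math

import numpy as np
import pytest
from scipy.special import betaln, comb
from scipy.stats import beta as beta_dist
from scipy.stats import binom as binom_dist

from ebf.binomial import (
    BinomialCount,
    binom_expected_bias,
    binom_posterior_marginal_likelihood,
    ebf_binom,
    ebf_model_average,
    ebf_negbinom,
    negbinom_expected_bias,
)
from ebf.core import Favoured, Hypothesis

FULL = Hypothesis.full()
LOWER = Hypothesis.less(0.5)
UPPER = Hypothesis.greater(0.5)

TABLE_FULL = [0.231, 0.316, 0.360, 0.387, 0.405, 0.418, 0.428, 0.436, 0.442, 0.447]
TABLE_HALF = [0.093, 0.133, 0.157, 0.172, 0.183, 0.191, 0.198, 0.203, 0.207, 0.210]


class TestPosteriorMarginalLikelihood:
    def test_single_success_single_trial(self):
        val = binom_posterior_marginal_likelihood(BinomialCount(1, 1), FULL)
        assert math.exp(val) == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_symmetry_in_successes_failures(self):
        a = binom_posterior_marginal_likelihood(BinomialCount(0, 1), FULL)
        b = binom_posterior_marginal_likelihood(BinomialCount(1, 1), FULL)
        assert a == pytest.approx(b, rel=1e-12)

    def test_full_interval_region_factor_is_one(self):
        # [0,1] region: both incomplete-Beta masses are 1
        c = BinomialCount(3, 7)
        got = binom_posterior_marginal_likelihood(c, FULL)
        expected = (
            math.log(comb(7, 3))
            + betaln(2 * 3 + 1, 2 * 4 + 1)
            - betaln(3 + 1, 4 + 1)
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_region_factor_against_direct_beta_masses(self):
        c = BinomialCount(8, 10)
        got = binom_posterior_marginal_likelihood(c, LOWER)
        expected = (
            math.log(comb(10, 8))
            + betaln(17, 5)
            - betaln(9, 3)
            + math.log(beta_dist.cdf(0.5, 17, 5))
            - math.log(beta_dist.cdf(0.5, 9, 3))
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_point_hypothesis_is_the_pmf(self):
        c = BinomialCount(5, 10)
        got = binom_posterior_marginal_likelihood(c, Hypothesis.point(0.5))
        assert got == pytest.approx(binom_dist.logpmf(5, 10, 0.5), rel=1e-12)

    def test_large_counts_stay_finite(self):
        c = BinomialCount(4200, 9000)
        assert math.isfinite(binom_posterior_marginal_likelihood(c, FULL))


class TestExpectedBias:
    @pytest.mark.parametrize("n, expected", list(zip(range(1, 11), TABLE_FULL)))
    def test_full_region_table(self, n, expected):
        assert binom_expected_bias(n).value == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("n, expected", list(zip(range(1, 11), TABLE_HALF)))
    def test_half_region_table(self, n, expected):
        assert binom_expected_bias(n, 1.0, LOWER).value == pytest.approx(
            expected, abs=5e-3
        )

    def test_single_trial_closed_form(self):
        # hand enumeration: off-diagonal outcomes each contribute log 2
        assert binom_expected_bias(1).value == pytest.approx(
            math.log(2.0) / 3.0, abs=1e-12
        )

    def test_upper_half_equals_lower_half(self):
        for n in (3, 10):
            assert binom_expected_bias(n, 1.0, UPPER).value == pytest.approx(
                binom_expected_bias(n, 1.0, LOWER).value, rel=1e-9
            )

    def test_monotone_toward_normal_theory(self):
        full = [binom_expected_bias(n).value for n in (1, 5, 10, 40)]
        half = [binom_expected_bias(n, 1.0, LOWER).value for n in (1, 5, 10, 40)]
        assert all(a < b for a, b in zip(full, full[1:]))
        assert all(a < b for a, b in zip(half, half[1:]))
        assert full[-1] < 0.5 and half[-1] < 0.25
        assert binom_expected_bias(200).value == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("n", [1, 7, 20])
    def test_joint_predictive_sums_to_one(self, n, alpha):
        xs = np.arange(n + 1)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        log_pr = (
            np.log(comb(n, X))
            + np.log(comb(n, Y))
            + betaln(X + Y + alpha, 2 * n - X - Y + alpha)
            - betaln(alpha, alpha)
        )
        assert np.exp(log_pr).sum() == pytest.approx(1.0, rel=1e-10)

    def test_uniform_prior_predictive(self):
        n = 9
        for x in range(n + 1):
            pr = comb(n, x) * math.exp(betaln(x + 1, n - x + 1))
            assert pr == pytest.approx(1.0 / (n + 1), rel=1e-12)


class TestEbfBinom:
    def test_balanced_count_is_neutral(self):
        res = ebf_binom(BinomialCount(5, 10), LOWER, UPPER)
        assert res.ebf01 == pytest.approx(1.0, rel=1e-12)
        assert res.favoured is Favoured.NEUTRAL

    def test_half_versus_half_biases_cancel(self):
        # oracle: pure incomplete-Beta ratio, no bias terms
        c = BinomialCount(8, 10)
        res = ebf_binom(c, LOWER, UPPER)
        num = beta_dist.cdf(0.5, 17, 5) / beta_dist.cdf(0.5, 9, 3)
        den = beta_dist.sf(0.5, 17, 5) / beta_dist.sf(0.5, 9, 3)
        assert res.ebf01 == pytest.approx(num / den, rel=1e-10)

    def test_point_versus_full(self):
        c = BinomialCount(5, 10)
        res = ebf_binom(c, Hypothesis.point(0.5), FULL)
        log_m1 = binom_posterior_marginal_likelihood(c, FULL)
        expected = binom_dist.logpmf(5, 10, 0.5) - (
            log_m1 - binom_expected_bias(10).value
        )
        assert res.log_ebf01 == pytest.approx(expected, rel=1e-12)


class TestNegativeBinomial:
    def test_sampling_model_matters(self):
        b = ebf_binom(BinomialCount(8, 10), LOWER, UPPER)
        nb = ebf_negbinom(8, 10, LOWER, UPPER)
        assert b.ebf01 != pytest.approx(nb.ebf01, rel=1e-4)

    def test_requires_at_least_one_success(self):
        with pytest.raises(ValueError):
            negbinom_expected_bias(0)

    def test_average_of_equal_values_is_identity(self):
        res = ebf_model_average(8, 10, LOWER, UPPER, weights=(1.0, 0.0))
        only_binom = ebf_binom(BinomialCount(8, 10), LOWER, UPPER)
        assert res.log_ebf01 == pytest.approx(only_binom.log_ebf01, rel=1e-12)

    def test_average_lies_between_models(self):
        b = ebf_binom(BinomialCount(8, 10), LOWER, UPPER).log_ebf01
        nb = ebf_negbinom(8, 10, LOWER, UPPER).log_ebf01
        avg = ebf_model_average(8, 10, LOWER, UPPER).log_ebf01
        assert min(b, nb) <= avg <= max(b, nb)
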