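"""Normal-theory EBFs: closed forms, the general quadrature route, comparators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import norm

from ebf.core import Hypothesis
from ebf.normal import (
    ZStatistic,
    comparator_bayes_factors,
    deviance_criterion,
    ebf_directional,
    ebf_interval,
    ebf_point_vs_onesided,
    ebf_point_vs_twosided,
    log_marginal_likelihood,
)

KNIFE_EDGE = 1.0 + math.log(2.0)  # z^2 where the two-sided EBF crosses 1


def quadrature_log_ml(estimate: float, se: float, lo: float, hi: float) -> float:
    """Independent oracle: direct quadrature of the defining integrals."""
    num, _ = integrate.quad(
        lambda mu: norm.pdf(mu, estimate, se / math.sqrt(2.0)), lo, hi
    )
    den, _ = integrate.quad(lambda mu: norm.pdf(mu, estimate, se), lo, hi)
    return -0.5 * math.log(4.0 * math.pi * se * se) + math.log(num) - math.log(den)


class TestTwoSided:
    def test_stent_z(self):
        assert ebf_point_vs_twosided(ZStatistic(1.28)).ebf01 == pytest.approx(
            1.03, abs=5e-3
        )

    def test_maximum_evidence_for_null_at_z_zero(self):
        # sqrt(2) e^{1/2}: the bounded ceiling of evidence for the point null
        assert ebf_point_vs_twosided(ZStatistic(0.0)).ebf01 == pytest.approx(
            math.sqrt(2.0) * math.exp(0.5), rel=1e-12
        )

    @pytest.mark.parametrize("d", [1, 2, 5])
    def test_vanishing_exponent(self, d):
        stat = ZStatistic(math.sqrt(d), d)
        assert ebf_point_vs_twosided(stat).ebf01 == pytest.approx(2.0 ** (d / 2.0))

    def test_knife_edge_location(self):
        eps = 1e-9
        below = ebf_point_vs_twosided(ZStatistic(math.sqrt(KNIFE_EDGE - eps)))
        above = ebf_point_vs_twosided(ZStatistic(math.sqrt(KNIFE_EDGE + eps)))
        assert below.ebf01 > 1.0 > above.ebf01

    def test_extreme_z_keeps_log(self):
        res = ebf_point_vs_twosided(ZStatistic(60.0))
        assert res.ebf01 == 0.0
        assert math.isfinite(res.log_ebf01)


class TestOneSided:
    def test_higgs_five_sigma(self):
        res = ebf_point_vs_onesided(ZStatistic(5.0))
        assert res.ebf10 == pytest.approx(1.48e5, rel=1e-2)

    def test_at_zero_opposite_possible(self):
        # oracle: truncated-normal integrals at z=0 halve top and bottom
        oracle = math.exp(quadrature_log_ml(0.0, 1.0, 0.0, 40.0))
        expected = norm.pdf(0.0) / (oracle * math.exp(-0.25))
        res = ebf_point_vs_onesided(ZStatistic(0.0))
        assert res.ebf01 == pytest.approx(expected, rel=1e-8)
        assert res.ebf01 == pytest.approx(math.sqrt(2.0) * math.exp(0.25), rel=1e-9)

    def test_at_zero_opposite_impossible(self):
        res = ebf_point_vs_onesided(ZStatistic(0.0), opposite_sign_possible=False)
        assert res.ebf01 == pytest.approx(math.sqrt(2.0) * math.exp(0.5), rel=1e-9)

    def test_vector_unsupported(self):
        with pytest.raises(ValueError):
            ebf_point_vs_onesided(ZStatistic(1.0, d=2))

    def test_large_z_ratio_of_phis_tends_to_one(self):
        # one-sided form over sqrt(2) e^{1/4 - z^2/2} -> 1 (Phi ratio -> 1)
        for z in (4.0, 6.0, 8.0):
            res = ebf_point_vs_onesided(ZStatistic(z))
            ref = math.sqrt(2.0) * math.exp(0.25 - 0.5 * z * z)
            assert res.ebf01 / ref == pytest.approx(1.0, abs=1e-4)


class TestDirectional:
    def test_symmetric_at_zero(self):
        assert ebf_directional(ZStatistic(0.0)).ebf01 == pytest.approx(1.0)

    def test_stent_clinical_threshold(self):
        z = (16.6 - 30.0) / 12.96
        assert ebf_directional(ZStatistic(z)).ebf01 == pytest.approx(2.29, abs=5e-3)

    @given(z=st.floats(-6, 6))
    @settings(max_examples=60, deadline=None)
    def test_antisymmetry(self, z):
        fwd = ebf_directional(ZStatistic(z)).log_ebf01
        rev = ebf_directional(ZStatistic(-z)).log_ebf01
        assert fwd == pytest.approx(-rev, abs=1e-10)


class TestIntervalRoute:
    @pytest.mark.parametrize("z", np.linspace(-3, 3, 13))
    def test_agrees_with_two_sided_closed_form(self, z):
        general = ebf_interval(z, 1.0, Hypothesis.point(0.0), Hypothesis.full())
        closed = ebf_point_vs_twosided(ZStatistic(z))
        assert general.log_ebf01 == pytest.approx(closed.log_ebf01, abs=1e-6)

    @pytest.mark.parametrize("z", np.linspace(-3, 3, 13))
    def test_agrees_with_one_sided_closed_form(self, z):
        general = ebf_interval(z, 1.0, Hypothesis.point(0.0), Hypothesis.greater(0.0))
        closed = ebf_point_vs_onesided(ZStatistic(z))
        assert general.log_ebf01 == pytest.approx(closed.log_ebf01, abs=1e-6)

    @pytest.mark.parametrize("z", np.linspace(-3, 3, 13))
    def test_agrees_with_directional_closed_form(self, z):
        general = ebf_interval(z, 1.0, Hypothesis.less(0.0), Hypothesis.greater(0.0))
        closed = ebf_directional(ZStatistic(z))
        assert general.log_ebf01 == pytest.approx(closed.log_ebf01, abs=1e-6)

    def test_stent_directional_through_general_route(self):
        res = ebf_interval(16.6, 12.96, Hypothesis.less(30.0), Hypothesis.greater(30.0))
        assert res.ebf01 == pytest.approx(2.29, abs=5e-3)

    def test_finite_interval_vs_full_against_quadrature(self):
        # oracle: brute-force quadrature of both region integrals
        log_m0 = quadrature_log_ml(0.0, 1.0, -1.0, 1.0)
        log_m1 = -0.5 * math.log(4.0 * math.pi)  # full line closed form
        expected = (log_m0 - 0.0) - (log_m1 - 0.5)
        res = ebf_interval(0.0, 1.0, Hypothesis.interval(-1.0, 1.0), Hypothesis.full())
        assert res.log_ebf01 == pytest.approx(expected, rel=1e-8)

    def test_far_tail_region_is_stable(self):
        # a region 40 sigma out still has representable log mass
        val = log_marginal_likelihood(0.0, 1.0, Hypothesis.interval(40.0, 41.0))
        assert math.isfinite(val)

    def test_zero_mass_region_rejected(self):
        with pytest.raises(ValueError):
            log_marginal_likelihood(0.0, 1.0, Hypothesis.interval(1e300, 2e300))


class TestDevianceCriterion:
    def test_penalty_constant(self):
        assert deviance_criterion(0.0, 1) == pytest.approx(1.6931, abs=5e-5)

    def test_no_parameters_no_penalty(self):
        assert deviance_criterion(-3.7, 0) == pytest.approx(7.4)

    def test_identity_with_bias_corrected_ml(self):
        # -2 (log M_full - d/2) for a scalar normal equals the criterion
        se, est = 0.7, 1.9
        log_m = log_marginal_likelihood(est, se, Hypothesis.full())
        max_ll = norm.logpdf(est, est, se)
        assert deviance_criterion(max_ll, 1) == pytest.approx(
            -2.0 * (log_m - 0.5), rel=1e-12
        )


class TestComparators:
    def test_reference_points(self):
        c = comparator_bayes_factors(0.0, 0.05, 100)
        assert c["min_bf"] == pytest.approx(1.0)
        assert c["brc"] == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_sellke_boundary(self):
        p = math.exp(-1.0)
        c = comparator_bayes_factors(1.0, p * (1 - 1e-12), 10)
        assert c["sellke_bound"] == pytest.approx(1.0, rel=1e-9)
        with pytest.raises(ValueError):
            comparator_bayes_factors(1.0, 0.5, 10)

    def test_held_ott_and_unit_information(self):
        z, p, n = 2.0, 0.0455, 1000
        c = comparator_bayes_factors(z, p, n)
        assert c["held_ott_bound"] == pytest.approx(
            -math.e * (1 - p) * math.log(1 - p), rel=1e-12
        )
        assert c["unit_information_bf"] == pytest.approx(
            math.sqrt(n + 1) * math.exp(-0.5 * z * z * n / (n + 1)), rel=1e-12
        )


class TestSamplingBehaviourUnderNull:
    """Frequentist behaviour of the two-sided EBF when H0 is true."""

    def test_probability_of_favouring_true_null(self):
        rng = np.random.default_rng(20240222)
        reps = 100_000
        z = rng.standard_normal(reps)
        frac = np.mean(z * z < KNIFE_EDGE)
        expected = 1.0 - 2.0 * norm.cdf(-math.sqrt(KNIFE_EDGE))
        se = math.sqrt(expected * (1 - expected) / reps)
        assert abs(frac - expected) < 3.0 * se

    def test_expected_log_ebf_is_half_log_two(self):
        rng = np.random.default_rng(7)
        reps = 100_000
        z = rng.standard_normal(reps)
        log_ebf = 0.5 * math.log(2.0) - 0.5 * (z * z - 1.0)
        se = log_ebf.std(ddof=1) / math.sqrt(reps)
        assert abs(log_ebf.mean() - 0.5 * math.log(2.0)) < 3.0 * se
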