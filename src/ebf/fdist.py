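"""EBFs for scale parameters with F-distributed statistics, incl. ANOVA.

Observed X with r X ~ F(nu1, nu2) for an unknown scale r > 0, improper
prior pi(r) ∝ 1/r.  The posterior density is x f_{nu1,nu2}(r x) and the
likelihood-times-posterior integral reduces to a rescaled F density with
doubled degrees of freedom:

    int_Theta x r f(rx)^2 dr = K(nu1, nu2) int_Theta f_{2nu1,2nu2}(r x) dr,
    K = B(nu1, nu2) / B(nu1/2, nu2/2)^2.

For Theta = (0, 1] this is the closed cumulative form
K F_{2nu1,2nu2}(x) / (x F_{nu1,nu2}(x)), the one-sided ANOVA alternative
H1: r < 1 (r > 1 implausible by construction, so the expected bias equals
the unrestricted one).

The expected bias itself needs a double integral over (x, y) with
standard F densities.  Writing the cross term through h(rho) =
int u f(u) f(u rho) du with rho = y/x, the E log x terms cancel and

    bias = log K - E log h(Y/X),  X, Y iid F(nu1, nu2),

evaluated as nested 1-D quadratures on the log scale (the density of
log(Y/X) is the self-convolution of the log-F density).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from scipy import integrate
from scipy.special import betaln, gammaln
from scipy.stats import f as f_dist

from .core import (
    BiasSpec,
    EvidenceResult,
    Family,
    Hypothesis,
    HypothesisKind,
    assemble_ebf,
)

__all__ = [
    "FStatistic",
    "log_f_constant",
    "f_posterior_marginal_likelihood",
    "f_expected_bias",
    "ebf_anova",
    "ebf_f",
]

_TAIL_Q = 1e-9


@dataclass(frozen=True)
class FStatistic:
    """Observed F statistic with numerator/denominator degrees of freedom."""

    f: float
    nu1: float
    nu2: float

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("F statistic must be positive")
        if self.nu1 < 1 or self.nu2 < 1:
            raise ValueError("degrees of freedom must be >= 1")


def log_f_constant(nu1: float, nu2: float) -> float:
    """log K = log B(nu1, nu2) - 2 log B(nu1/2, nu2/2)."""
    return betaln(nu1, nu2) - 2.0 * betaln(nu1 / 2.0, nu2 / 2.0)


def _log_f_mass(lo: float, hi: float, df1: float, df2: float) -> float:
    """log P[lo < F(df1, df2) < hi]."""
    if lo <= 0.0 and hi == math.inf:
        return 0.0
    if lo <= 0.0:
        return float(f_dist.logcdf(hi, df1, df2))
    if hi == math.inf:
        return float(f_dist.logsf(lo, df1, df2))
    mass = f_dist.cdf(hi, df1, df2) - f_dist.cdf(lo, df1, df2)
    if mass <= 0.0:
        return -math.inf
    return math.log(mass)


def f_posterior_marginal_likelihood(stat: FStatistic, h: Hypothesis) -> float:
    """Log posterior marginal likelihood of an F summary over a region of r.

    Point hypotheses use the plain likelihood r f(r x) at r = r0.
    Regions: K * P[F(2nu1, 2nu2) in x*Theta] / (x * P[F(nu1, nu2) in x*Theta]).
    """
    x, nu1, nu2 = stat.f, stat.nu1, stat.nu2
    if h.kind is HypothesisKind.POINT:
        r0 = h.value
        if r0 <= 0:
            raise ValueError("scale hypothesis must be positive")
        return math.log(r0) + float(f_dist.logpdf(r0 * x, nu1, nu2))
    lo, hi = h.bounds()
    lo = max(lo, 0.0)
    if hi <= lo:
        raise ValueError("empty region for a positive scale parameter")
    log_num = _log_f_mass(lo * x, hi * x if hi != math.inf else math.inf, 2 * nu1, 2 * nu2)
    log_den = _log_f_mass(lo * x, hi * x if hi != math.inf else math.inf, nu1, nu2)
    if log_den == -math.inf:
        raise ValueError("hypothesis region carries zero posterior mass")
    return log_f_constant(nu1, nu2) - math.log(x) + log_num - log_den


def _log_f_logpdf_fast(nu1: float, nu2: float):
    """Log density of W = log X, X ~ F(nu1, nu2), as a cheap closure."""
    # f_X(x) = C x^{a-1} (1 + nu1 x / nu2)^{-b}; f_W(w) = f_X(e^w) e^w
    const = 0.5 * nu1 * math.log(nu1 / nu2) - betaln(0.5 * nu1, 0.5 * nu2)
    a, b = 0.5 * nu1, 0.5 * (nu1 + nu2)
    lr = math.log(nu1 / nu2)

    def logpdf(w: float) -> float:
        if w + lr > 500.0:  # avoid exp overflow far in the right tail
            return const + a * w - b * (lr + w)
        return const + a * w - b * math.log1p(nu1 / nu2 * math.exp(w))

    return logpdf


@lru_cache(maxsize=256)
def _log_h(nu1: float, nu2: float, w: float) -> float:
    """log h(e^w), h(rho) = int_0^inf u f(u) f(u rho) du, on the log scale.

    Substituting u = e^s gives int e^{2s} f(e^s) f(e^s rho) ds with an
    exponentially localised integrand; adaptive quadrature over the
    union of the two supports.
    """
    lw = _log_f_logpdf_fast(nu1, nu2)

    def integrand(s: float) -> float:
        # e^{2s} f(e^s) f(e^s rho) = [e^s f(e^s)] [e^{s+w} f(e^{s+w})] e^{-w}
        return math.exp(lw(s) + lw(s + w) - w)

    lo_q = float(f_dist.ppf(_TAIL_Q, nu1, nu2))
    hi_q = float(f_dist.ppf(1.0 - _TAIL_Q, nu1, nu2))
    s_lo, s_hi = math.log(lo_q), math.log(hi_q)
    # supports of the two factors: [s_lo, s_hi] and shifted by -w
    edges = sorted({s_lo, s_hi, s_lo - w, s_hi - w, -0.5 * w})
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        if a >= b:
            continue
        val, _ = integrate.quad(integrand, a, b, epsabs=1e-15, epsrel=1e-9, limit=150)
        total += val
    if total <= 0.0:
        return -math.inf
    return math.log(total)


@lru_cache(maxsize=256)
def f_expected_bias_value(nu1: float, nu2: float) -> float:
    """Expected bias (nats) for the unrestricted scale hypothesis.

    bias = log K - E log h(Y/X): the outer expectation integrates over the
    density of W = log Y - log X (self-convolution of the log-F density,
    itself a 1-D quadrature), and each outer point evaluates log h by an
    inner quadrature.
    """
    lw = _log_f_logpdf_fast(nu1, nu2)
    lo_q = math.log(float(f_dist.ppf(_TAIL_Q, nu1, nu2)))
    hi_q = math.log(float(f_dist.ppf(1.0 - _TAIL_Q, nu1, nu2)))

    def logf_w_density(w: float) -> float:
        """Density of W = log Y - log X by convolution."""

        def conv(v: float) -> float:
            return math.exp(lw(v) + lw(v - w))

        edges = sorted({lo_q, hi_q, lo_q + w, hi_q + w, 0.5 * w})
        total = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            if a >= b:
                continue
            val, _ = integrate.quad(conv, a, b, epsabs=1e-13, epsrel=1e-8, limit=120)
            total += val
        return total

    def integrand(w: float) -> float:
        d = logf_w_density(w)
        if d <= 0.0:
            return 0.0
        return d * _log_h(nu1, nu2, w)

    span = hi_q - lo_q
    out, _ = integrate.quad(
        integrand, -span, span, epsabs=5e-7, epsrel=1e-6, limit=300
    )
    return log_f_constant(nu1, nu2) - out


def f_expected_bias(nu1: float, nu2: float, h: Hypothesis | None = None) -> BiasSpec:
    """Expected bias for F-statistic hypotheses.

    Half-line scale hypotheses (the ANOVA H1: r < 1) carry the same bias
    as the unrestricted hypothesis, because the excluded side is
    implausible by construction; points and finite intervals have none.
    """
    if h is None:
        h = Hypothesis.full()
    if h.kind in (HypothesisKind.POINT, HypothesisKind.INTERVAL):
        return BiasSpec(0.0, Family.F, h)
    return BiasSpec(f_expected_bias_value(nu1, nu2), Family.F, h)


def ebf_anova(stat: FStatistic) -> EvidenceResult:
    """One-sided ANOVA EBF: H0: r = 1 versus H1: r < 1.

    H0 uses the plain F likelihood at the observed statistic; H1 the
    closed cumulative form with the unrestricted bias.  Evidence for H1
    grows without bound as the statistic grows; evidence for the point
    null is bounded as it shrinks.
    """
    h0 = Hypothesis.point(1.0)
    h1 = Hypothesis(
        HypothesisKind.LOWER_HALF, upper=1.0, d1=1, d2=0, opposite_sign_possible=False
    )
    log_m0 = f_posterior_marginal_likelihood(stat, h0)
    log_m1 = f_posterior_marginal_likelihood(stat, h1)
    return assemble_ebf(
        log_m0,
        f_expected_bias(stat.nu1, stat.nu2, h0),
        log_m1,
        f_expected_bias(stat.nu1, stat.nu2, h1),
    )


def ebf_f(stat: FStatistic, h0: Hypothesis, h1: Hypothesis) -> EvidenceResult:
    """General EBF between two hypotheses on the scale r."""
    log_m0 = f_posterior_marginal_likelihood(stat, h0)
    log_m1 = f_posterior_marginal_likelihood(stat, h1)
    return assemble_ebf(
        log_m0,
        f_expected_bias(stat.nu1, stat.nu2, h0),
        log_m1,
        f_expected_bias(stat.nu1, stat.nu2, h1),
    )
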