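"""EBFs for normal-theory summary statistics (z and chi-squared).

A single (possibly vector) observation x with known variance Sigma and a
flat prior on the mean gives posterior N(x, Sigma).  The posterior
marginal likelihood over a region Theta is

    (4 pi |Sigma|)^(-1/2) * P[N(x, Sigma/2) in Theta] / P[N(x, Sigma) in Theta]

and the expected bias follows the regular-model rule (half the dimension,
with directional/interval refinements).  Closed forms are provided for the
common scalar tests; :func:`ebf_interval` is the general scalar route and
agrees with them on their domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .core import (
    BiasSpec,
    EvidenceResult,
    Hypothesis,
    HypothesisKind,
    assemble_ebf,
    normal_bias_rule,
)

__all__ = [
    "ZStatistic",
    "ebf_point_vs_twosided",
    "ebf_point_vs_onesided",
    "ebf_directional",
    "ebf_interval",
    "log_marginal_likelihood",
    "deviance_criterion",
    "comparator_bayes_factors",
]


@dataclass(frozen=True)
class ZStatistic:
    """A standardised normal summary statistic.

    For d = 1, ``z`` is estimate/se.  For d > 1, ``z`` carries the square
    root of the quadratic form x' Sigma^-1 x and only the point-vs-full
    chi-squared form applies.
    """

    z: float
    d: int = 1
    estimate: float | None = None
    se: float | None = None

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("dimension d must be >= 1")
        if self.se is not None and self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.estimate is not None and self.se is not None:
            if not math.isclose(self.z, self.estimate / self.se, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("z inconsistent with estimate/se")

    @classmethod
    def from_estimate(cls, estimate: float, se: float, d: int = 1) -> "ZStatistic":
        return cls(z=estimate / se, d=d, estimate=estimate, se=se)

    @classmethod
    def from_chisq(cls, chisq: float, df: int) -> "ZStatistic":
        if chisq < 0:
            raise ValueError("chi-squared statistic must be non-negative")
        return cls(z=math.sqrt(chisq), d=df)

    @property
    def z2(self) -> float:
        return self.z * self.z


def ebf_point_vs_twosided(stat: ZStatistic) -> EvidenceResult:
    """EBF for H0: mu = 0 versus the unrestricted alternative.

    Closed form 2^(d/2) exp(-(z^2 - d)/2); the scalar case is
    sqrt(2) exp(-(z^2 - 1)/2), which favours H0 iff z^2 < 1 + log 2.
    """
    d = stat.d
    log_ebf = 0.5 * d * math.log(2.0) - 0.5 * (stat.z2 - d)
    return EvidenceResult.from_log(log_ebf)


def ebf_point_vs_onesided(
    stat: ZStatistic, opposite_sign_possible: bool = True
) -> EvidenceResult:
    """EBF for H0: mu = 0 versus H1: mu > 0 (scalar only).

    sqrt(2) Phi(z)/Phi(z sqrt 2) exp(-(z^2 - 1/2)/2) when mu < 0 remains a
    priori possible (bias 1/4); the exponent penalty becomes (z^2 - 1)/2
    when the opposite sign is impossible by definition (bias 1/2).
    """
    if stat.d != 1:
        raise ValueError("one-sided EBF is defined for scalar statistics only")
    z = stat.z
    bias1 = 0.25 if opposite_sign_possible else 0.5
    log_ebf = (
        0.5 * math.log(2.0)
        + norm.logcdf(z)
        - norm.logcdf(z * math.sqrt(2.0))
        - 0.5 * stat.z2
        + bias1
    )
    return EvidenceResult.from_log(log_ebf)


def ebf_directional(stat: ZStatistic) -> EvidenceResult:
    """EBF for H0: mu < 0 versus H1: mu > 0 (scalar only).

    Phi(-z sqrt 2) Phi(z) / [Phi(z sqrt 2) Phi(-z)]; the quarter biases of
    the two half-lines cancel, and the EBF is consistent for whichever
    hypothesis holds as |z| grows.
    """
    if stat.d != 1:
        raise ValueError("directional EBF is defined for scalar statistics only")
    z = stat.z
    s2 = math.sqrt(2.0)
    log_ebf = (
        norm.logcdf(-z * s2) + norm.logcdf(z) - norm.logcdf(z * s2) - norm.logcdf(-z)
    )
    return EvidenceResult.from_log(log_ebf)


def log_marginal_likelihood(estimate: float, se: float, h: Hypothesis) -> float:
    """Log posterior marginal likelihood of a normal summary over a region.

    Point hypotheses use the plain likelihood phi(x; mu0, se^2).  Regions
    use (4 pi se^2)^(-1/2) times the N(x, se^2/2) mass over Theta divided
    by the N(x, se^2) (posterior) mass over Theta.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    if h.kind is HypothesisKind.POINT:
        return norm.logpdf(estimate, loc=h.value, scale=se)
    lo, hi = h.bounds()
    half = se / math.sqrt(2.0)
    log_num = _log_mass(lo, hi, estimate, half)
    log_den = _log_mass(lo, hi, estimate, se)
    if log_den == -math.inf:
        raise ValueError("hypothesis region carries zero posterior mass")
    return -0.5 * math.log(4.0 * math.pi * se * se) + log_num - log_den


def _log_mass(lo: float, hi: float, loc: float, scale: float) -> float:
    """log P[lo < N(loc, scale^2) < hi], stable in the far tails."""
    if lo == -math.inf and hi == math.inf:
        return 0.0
    if lo == -math.inf:
        return norm.logcdf(hi, loc=loc, scale=scale)
    if hi == math.inf:
        return norm.logsf(lo, loc=loc, scale=scale)
    a = norm.cdf(hi, loc=loc, scale=scale) - norm.cdf(lo, loc=loc, scale=scale)
    if a <= 0.0:
        # interval deep in a tail: both cdfs round to the same float
        # fall back to a logsumexp-style difference of log tail masses
        la = norm.logsf(lo, loc=loc, scale=scale)
        lb = norm.logsf(hi, loc=loc, scale=scale)
        if la == lb:
            return -math.inf
        return la + math.log1p(-math.exp(lb - la))
    return math.log(a)


def ebf_interval(
    estimate: float, se: float, h0: Hypothesis, h1: Hypothesis
) -> EvidenceResult:
    """General scalar normal EBF between two hypothesis regions.

    Generalises the closed forms: point-vs-full reduces to
    :func:`ebf_point_vs_twosided`, half-line pairs to
    :func:`ebf_directional`, and so on.  Biases follow
    :func:`~ebf.core.normal_bias_rule`.
    """
    log_m0 = log_marginal_likelihood(estimate, se, h0)
    log_m1 = log_marginal_likelihood(estimate, se, h1)
    return assemble_ebf(log_m0, normal_bias_rule(h0), log_m1, normal_bias_rule(h1))


def deviance_criterion(max_loglik: float, d: int) -> float:
    """-2 max log-likelihood + d (1 + log 2): a WAIC-like criterion.

    Equals -2 log of the bias-corrected posterior marginal likelihood for
    the unrestricted normal hypothesis, so differences are interpretable
    on the Bayes-factor scale (penalty 1.69 per parameter).
    """
    if d < 0:
        raise ValueError("parameter count must be non-negative")
    return -2.0 * max_loglik + d * (1.0 + math.log(2.0))


def comparator_bayes_factors(z: float, p: float, n: int) -> dict[str, float]:
    """Reference quantities the EBF is commonly compared against.

    Returns the Sellke et al. bound -e p log p (p < 1/e only), the
    Held-Ott bound -e (1-p) log(1-p), the Bayesian reference criterion
    exp(-(z^2+1)/2), the minimum Bayes factor over all priors
    exp(-z^2/2), and the unit-information Bayes factor
    sqrt(n+1) exp(-z^2 n / (2(n+1))).  All in favour of H0.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if n < 1:
        raise ValueError("sample size n must be positive")
    if p > math.exp(-1.0):
        raise ValueError("the Sellke bound is valid only for p < exp(-1)")
    z2 = z * z
    return {
        "sellke_bound": -math.e * p * math.log(p),
        "held_ott_bound": -math.e * (1.0 - p) * math.log1p(-p),
        "brc": math.exp(-0.5 * (z2 + 1.0)),
        "min_bf": math.exp(-0.5 * z2),
        "unit_information_bf": math.sqrt(n + 1.0)
        * math.exp(-0.5 * z2 * n / (n + 1.0)),
    }
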