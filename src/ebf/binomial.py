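"""Exact EBFs for a binomial probability, with a negative-binomial variant.

With x successes in n trials and a symmetric Beta(alpha, alpha) prior
(default alpha = 1, the uniform prior, whose prior predictive is uniform
on {0..n}), the posterior is Beta(x+alpha, n-x+alpha) and the posterior
marginal likelihood over a region Theta of [0, 1] is

    C(n,x) B(2x+a, 2(n-x)+a)/B(x+a, n-x+a)
        * I_Theta[Beta(2x+a, 2(n-x)+a)] / I_Theta[Beta(x+a, n-x+a)]

where I_Theta[.] is the incomplete-Beta mass of a Beta law on Theta.  The
expected bias is an exact finite double sum over the joint prior
predictive of the data and a replicate, so the bias table is computed to
machine precision rather than by quadrature.

If instead the number of successes is fixed and the trial count random,
the same construction applied to the negative-binomial likelihood yields
a different EBF; when the sampling model is uncertain the two
bias-corrected marginal likelihoods can be averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import betaln, gammaln
from scipy.stats import beta as beta_dist

from .core import (
    BiasSpec,
    EvidenceResult,
    Family,
    Hypothesis,
    HypothesisKind,
    assemble_ebf,
)

__all__ = [
    "BinomialCount",
    "binom_posterior_marginal_likelihood",
    "binom_replicate_marginal_likelihood",
    "binom_expected_bias",
    "ebf_binom",
    "negbinom_posterior_marginal_likelihood",
    "negbinom_expected_bias",
    "ebf_negbinom",
    "ebf_model_average",
]


@dataclass(frozen=True)
class BinomialCount:
    """x successes in n Bernoulli trials with a Beta(alpha, alpha) prior."""

    x: int
    n: int
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("number of trials must be positive")
        if not 0 <= self.x <= self.n:
            raise ValueError("successes must satisfy 0 <= x <= n")
        if self.alpha <= 0:
            raise ValueError("Beta prior parameter alpha must be positive")


def _clip_unit(h: Hypothesis) -> tuple[float, float]:
    lo, hi = h.bounds()
    lo, hi = max(lo, 0.0), min(hi, 1.0)
    if lo >= hi:
        raise ValueError("hypothesis region does not intersect [0, 1]")
    return lo, hi


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(200)


def _log_upper_beta_tail(q, a: float, b) -> np.ndarray:
    """log P[Beta(a, b) > q] for integer a, vectorised over b.

    Uses the exact identity P[Beta(a, b) > q] = P[Bin(a+b-1, q) <= a-1],
    a logsumexp over only a terms, so far tails (e.g. Beta(9, 2000) above
    0.5) stay on the log scale.
    """
    b = np.asarray(b, dtype=float)
    n_tot = a + b - 1.0
    ks = np.arange(int(a))
    terms = (
        gammaln(n_tot[..., None] + 1.0)
        - gammaln(ks + 1.0)
        - gammaln(n_tot[..., None] - ks + 1.0)
        + ks * math.log(q)
        + (n_tot[..., None] - ks) * math.log1p(-q)
    )
    m = terms.max(axis=-1)
    return m + np.log(np.sum(np.exp(terms - m[..., None]), axis=-1))


def _log_beta_mass_quad(lo: float, hi: float, a: float, b: float) -> float:
    """Gauss-Legendre logsumexp fallback for non-integer shapes."""
    p = 0.5 * (hi - lo) * _GL_NODES + 0.5 * (hi + lo)
    with np.errstate(divide="ignore"):
        logf = (a - 1.0) * np.log(p) + (b - 1.0) * np.log1p(-p) - betaln(a, b)
    m = logf.max()
    if m == -math.inf:
        return -math.inf
    s = float(np.sum(_GL_WEIGHTS * np.exp(logf - m))) * 0.5 * (hi - lo)
    if s <= 0.0:
        return -math.inf
    return m + math.log(s)


def _log_beta_mass(lo: float, hi: float, a: float, b: float) -> float:
    """log of the Beta(a, b) mass on [lo, hi], stable deep in the tails."""
    if lo <= 0.0 and hi >= 1.0:
        return 0.0
    mass = beta_dist.cdf(hi, a, b) - beta_dist.cdf(lo, a, b)
    if mass > 1e-280:
        return math.log(mass)
    if float(a).is_integer() and a <= 512:
        if hi >= 1.0:
            return float(_log_upper_beta_tail(lo, a, b))
        lu_lo = float(_log_upper_beta_tail(lo, a, b))
        lu_hi = float(_log_upper_beta_tail(hi, a, b))
        if lu_lo > lu_hi:
            return lu_lo + math.log1p(-math.exp(lu_hi - lu_lo))
        # remaining mass sits below lo; fall through to quadrature
    return _log_beta_mass_quad(lo, hi, a, b)


def _log_choose(n: int, x: int) -> float:
    return gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)


def binom_posterior_marginal_likelihood(c: BinomialCount, h: Hypothesis) -> float:
    """Log posterior marginal likelihood of a binomial count over Theta.

    Point hypotheses use the binomial pmf at p0.  All Beta quantities are
    handled in log space so counts in the thousands are safe.
    """
    x, n, a = c.x, c.n, c.alpha
    if h.kind is HypothesisKind.POINT:
        p0 = h.value
        if not 0.0 <= p0 <= 1.0:
            raise ValueError("point hypothesis outside [0, 1]")
        return (
            _log_choose(n, x)
            + (x * math.log(p0) if x else 0.0)
            + ((n - x) * math.log1p(-p0) if n - x else 0.0)
        )
    lo, hi = _clip_unit(h)
    a_num, b_num = 2 * x + a, 2 * (n - x) + a
    a_post, b_post = x + a, n - x + a
    log_den_mass = _log_beta_mass(lo, hi, a_post, b_post)
    if log_den_mass == -math.inf:
        raise ValueError("hypothesis region carries zero posterior mass")
    return (
        _log_choose(n, x)
        + betaln(a_num, b_num)
        - betaln(a_post, b_post)
        + _log_beta_mass(lo, hi, a_num, b_num)
        - log_den_mass
    )


def binom_replicate_marginal_likelihood(
    x: int, y: int, n: int, alpha: float, h: Hypothesis
) -> float:
    """Log marginal likelihood of x with prior = posterior from replicate y."""
    lo, hi = _clip_unit(h)
    a = alpha
    log_den = _log_beta_mass(lo, hi, y + a, n - y + a)
    if log_den == -math.inf:
        return -math.inf
    return (
        _log_choose(n, x)
        + betaln(x + y + a, 2 * n - x - y + a)
        - betaln(y + a, n - y + a)
        + _log_beta_mass(lo, hi, x + y + a, 2 * n - x - y + a)
        - log_den
    )


@lru_cache(maxsize=1024)
def _binom_expected_bias_value(n: int, alpha: float, lo: float, hi: float) -> float:
    """Exact (n+1)^2-term double sum for the expected bias."""
    a = alpha
    xs = np.arange(n + 1)
    # joint prior predictive Pr(x, y) under Beta(a, a)
    lc = gammaln(n + 1) - gammaln(xs + 1) - gammaln(n - xs + 1)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    log_pr = (
        lc[:, None]
        + lc[None, :]
        + betaln(X + Y + a, 2 * n - X - Y + a)
        - betaln(a, a)
    )
    h = Hypothesis.interval(lo, hi) if (lo > 0.0 or hi < 1.0) else Hypothesis.full()
    d = np.empty((n + 1, n + 1))
    for x in range(n + 1):
        c = BinomialCount(x, n, a)
        log_m = binom_posterior_marginal_likelihood(c, h)
        for y in range(n + 1):
            d[x, y] = log_m - binom_replicate_marginal_likelihood(x, y, n, a, h)
    return float(np.sum(np.exp(log_pr) * d))


def binom_expected_bias(
    n: int, alpha: float = 1.0, h: Hypothesis | None = None
) -> BiasSpec:
    """Expected bias of the binomial log posterior marginal likelihood.

    Exact finite double sum over the joint prior predictive of (x, y);
    the per-term deviation is log M_H(x) minus the log marginal of x with
    prior taken from the replicate's posterior.  Points and finite
    degenerate regions have zero width only in the continuous families;
    here every sub-interval of [0, 1] has its own (generally non-zero)
    bias, with [0,1] approaching 1/2 and [0,0.5] approaching 1/4 as n
    grows.
    """
    if n < 1:
        raise ValueError("number of trials must be positive")
    if h is None:
        h = Hypothesis.full()
    if h.kind is HypothesisKind.POINT:
        return BiasSpec(0.0, Family.BINOMIAL, h)
    lo, hi = _clip_unit(h)
    return BiasSpec(_binom_expected_bias_value(n, alpha, lo, hi), Family.BINOMIAL, h)


def ebf_binom(c: BinomialCount, h0: Hypothesis, h1: Hypothesis) -> EvidenceResult:
    """EBF between two hypotheses on a binomial probability.

    For the symmetric split [0, 0.5] vs [0.5, 1] the two biases are equal
    and cancel exactly.
    """
    log_m0 = binom_posterior_marginal_likelihood(c, h0)
    log_m1 = binom_posterior_marginal_likelihood(c, h1)
    b0 = binom_expected_bias(c.n, c.alpha, h0)
    b1 = binom_expected_bias(c.n, c.alpha, h1)
    return assemble_ebf(log_m0, b0, log_m1, b1)


# ---------------------------------------------------------------------------
# Negative binomial: x fixed, n random
# ---------------------------------------------------------------------------


def negbinom_posterior_marginal_likelihood(
    x: int, n: int, alpha: float, h: Hypothesis
) -> float:
    """Log posterior marginal likelihood under the negative-binomial model.

    The likelihood C(n-1, x-1) p^x (1-p)^(n-x) has the same Beta posterior
    as the binomial, so only the combinatorial constant differs.
    """
    if x < 1:
        raise ValueError("negative-binomial model requires x >= 1")
    if n < x:
        raise ValueError("trial count cannot be below the success count")
    a = alpha
    if h.kind is HypothesisKind.POINT:
        p0 = h.value
        return (
            _log_choose(n - 1, x - 1)
            + x * math.log(p0)
            + ((n - x) * math.log1p(-p0) if n - x else 0.0)
        )
    lo, hi = _clip_unit(h)
    log_den = _log_beta_mass(lo, hi, x + a, n - x + a)
    if log_den == -math.inf:
        raise ValueError("hypothesis region carries zero posterior mass")
    return (
        _log_choose(n - 1, x - 1)
        + betaln(2 * x + a, 2 * (n - x) + a)
        - betaln(x + a, n - x + a)
        + _log_beta_mass(lo, hi, 2 * x + a, 2 * (n - x) + a)
        - log_den
    )


@lru_cache(maxsize=512)
def _negbinom_expected_bias_value(
    x: int, alpha: float, lo: float, hi: float, nmax: int
) -> float:
    """Expected bias under the negative-binomial prior predictive.

    The replicate pair (n, n') ranges over {x, x+1, ...}; the sum is
    truncated at nmax, chosen so the neglected predictive tail mass is
    small (the summand decays like x/n^2 times slowly varying logs).
    """
    a = alpha
    ns = np.arange(x, nmax + 1)
    lc = gammaln(ns) - gammaln(x) - gammaln(ns - x + 1)  # log C(n-1, x-1)
    N, M = np.meshgrid(ns, ns, indexing="ij")
    log_pr = (
        lc[:, None]
        + lc[None, :]
        + betaln(2 * x + a, N + M - 2 * x + a)
        - betaln(a, a)
    )
    h = Hypothesis.interval(lo, hi) if (lo > 0.0 or hi < 1.0) else Hypothesis.full()

    log_m = np.array(
        [negbinom_posterior_marginal_likelihood(x, int(n), a, h) for n in ns]
    )

    def log_mass_vec(a_scalar, b_arr):
        b_b = np.asarray(b_arr, dtype=float)
        if lo <= 0.0 and hi >= 1.0:
            return np.zeros(b_b.shape)
        mass = beta_dist.cdf(hi, a_scalar, b_b) - beta_dist.cdf(lo, a_scalar, b_b)
        with np.errstate(divide="ignore"):
            out = np.log(np.clip(mass, 0.0, None))
        small = mass <= 1e-280
        if np.any(small):
            if float(a_scalar).is_integer() and hi >= 1.0:
                # b takes few distinct values over the (n, n') grid
                ub, inv = np.unique(b_b[small], return_inverse=True)
                out[small] = _log_upper_beta_tail(lo, a_scalar, ub)[inv]
            else:
                flat_idx = np.nonzero(small.reshape(-1))[0]
                flat_out, flat_b = out.reshape(-1), b_b.reshape(-1)
                for idx in flat_idx:
                    flat_out[idx] = _log_beta_mass(lo, hi, a_scalar, flat_b[idx])
        return out

    # replicate marginal of n with prior = posterior from replicate n'
    log_rep = (
        lc[:, None]
        + betaln(2 * x + a, N + M - 2 * x + a)
        - betaln(x + a, M - x + a)
        + log_mass_vec(2 * x + a, N + M - 2 * x + a)
        - log_mass_vec(x + a, M - x + a)
    )
    d = log_m[:, None] - log_rep
    return float(np.sum(np.exp(log_pr) * d))


def negbinom_expected_bias(
    x: int, alpha: float = 1.0, h: Hypothesis | None = None, nmax: int = 2000
) -> BiasSpec:
    if x < 1:
        raise ValueError("negative-binomial model requires x >= 1")
    if h is None:
        h = Hypothesis.full()
    if h.kind is HypothesisKind.POINT:
        return BiasSpec(0.0, Family.NEGBINOMIAL, h)
    lo, hi = _clip_unit(h)
    return BiasSpec(
        _negbinom_expected_bias_value(x, alpha, lo, hi, nmax), Family.NEGBINOMIAL, h
    )


def ebf_negbinom(
    x: int, n: int, h0: Hypothesis, h1: Hypothesis, alpha: float = 1.0
) -> EvidenceResult:
    """EBF under the negative-binomial sampling model (x fixed, n random)."""
    log_m0 = negbinom_posterior_marginal_likelihood(x, n, alpha, h0)
    log_m1 = negbinom_posterior_marginal_likelihood(x, n, alpha, h1)
    b0 = negbinom_expected_bias(x, alpha, h0)
    b1 = negbinom_expected_bias(x, alpha, h1)
    return assemble_ebf(log_m0, b0, log_m1, b1)


def ebf_model_average(
    x: int,
    n: int,
    h0: Hypothesis,
    h1: Hypothesis,
    alpha: float = 1.0,
    weights: tuple[float, float] = (0.5, 0.5),
) -> EvidenceResult:
    """Model-averaged EBF over the binomial and negative-binomial models.

    Takes the (weighted) arithmetic mean of the bias-corrected posterior
    marginal likelihoods under each sampling model, separately for each
    hypothesis, and forms their ratio.  Equal weights are the default.
    """
    w_b, w_nb = weights
    if w_b < 0 or w_nb < 0 or w_b + w_nb <= 0:
        raise ValueError("model weights must be non-negative and not all zero")
    c = BinomialCount(x, n, alpha)

    def corrected(model: str, h: Hypothesis) -> float:
        if model == "binomial":
            return binom_posterior_marginal_likelihood(c, h) - binom_expected_bias(
                n, alpha, h
            ).value
        return negbinom_posterior_marginal_likelihood(
            x, n, alpha, h
        ) - negbinom_expected_bias(x, alpha, h).value

    def averaged(h: Hypothesis) -> float:
        vals = np.array([corrected("binomial", h), corrected("negbinomial", h)])
        w = np.array([w_b, w_nb]) / (w_b + w_nb)
        m = vals.max()
        return m + math.log(float(np.sum(w * np.exp(vals - m))))

    from .core import EvidenceResult as _ER

    return _ER.from_log(averaged(h0) - averaged(h1))
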