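"""Monte Carlo machinery: bias oracles and multiplicity experiments.

Two roles.  First, a simulation estimate of the expected bias
E_Y b_H(Y) for each test family, averaging

    log M_H(x) - log [replicate-prior marginal likelihood of x given y]

over simulated pairs (x, y).  By the pivotal structure of the normal, t
and F families the bias does not depend on the true parameter, so the
simulations fix mu = 0 (or r = 1); the binomial draws p from its
Beta(alpha, alpha) prior so the predictive is the one the exact sums
integrate over.  This is the independent check on every quadrature/exact
bias table.

Second, the multiplicity experiments: bias and mean-square error of the
mixture-posterior marginal likelihood for m = 1..10 normal-mean tests
under three mean configurations (all zero; N(0,1) random; a fixed grid
on [-5, 5]), and a large-scale screening experiment (many nulls plus a
minority of normal effects) comparing single- and multiple-test EBFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .binomial import (
    BinomialCount,
    binom_posterior_marginal_likelihood,
    binom_replicate_marginal_likelihood,
)
from .core import Hypothesis, HypothesisKind
from .fdist import _log_h, f_dist, log_f_constant
from .multitest import TestEnsemble, ebf_multiple
from .student_t import log_product_t_constant, t_convolution_logpdf, t_dist

__all__ = [
    "ScenarioConfig",
    "BiasEstimate",
    "mc_expected_bias",
    "run_limited_multiplicity",
    "run_large_scale",
    "plot_large_scale",
]


@dataclass(frozen=True)
class BiasEstimate:
    """Monte Carlo mean bias with its standard error."""

    mean_bias: float
    mc_se: float
    reps: int


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of a limited-multiplicity experiment.

    ``scenario``: 'all_zero' (every mean 0), 'normal_effects' (means
    N(0, effect_sd^2) fresh each repetition), or 'grid' (means fixed to a
    uniform grid over grid_range; the single-test case uses the
    midpoint).  Per-test sample size n gives sampling s.e. 1/sqrt(n).
    """

    scenario: str = "all_zero"
    m: int = 1
    n: int = 100
    reps: int = 10000
    seed: int = 0
    effect_sd: float = 1.0
    grid_range: tuple[float, float] = (-5.0, 5.0)
    p_theta: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in ("all_zero", "normal_effects", "grid"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.reps < 1 or self.n < 1 or self.m < 1:
            raise ValueError("reps, n and m must be positive")


# ---------------------------------------------------------------------------
# Monte Carlo bias oracle
# ---------------------------------------------------------------------------


def _log_norm_mass_vec(lo, hi, loc, scale):
    from .multitest import _log_norm_mass

    return _log_norm_mass(lo, hi, loc, scale)


def _mc_bias_normal(
    h: Hypothesis, reps: int, rng: np.random.Generator, mu_prior_sd: float = 0.0
) -> np.ndarray:
    # For the full hypothesis the bias is pivotal in mu, so mu = 0 suffices.
    # Half-line biases depend on the predictive for the location and reach
    # the flat-prior value 1/4 only in the diffuse limit; a large
    # mu_prior_sd approximates that limit.
    mu = mu_prior_sd * rng.standard_normal(reps) if mu_prior_sd > 0 else 0.0
    x = mu + rng.standard_normal(reps)
    y = mu + rng.standard_normal(reps)
    lo, hi = h.bounds()
    s = 1.0
    log_m = (
        -0.5 * math.log(4.0 * math.pi * s * s)
        + _log_norm_mass_vec(lo, hi, x, s / math.sqrt(2.0))
        - _log_norm_mass_vec(lo, hi, x, s)
    )
    log_rep = (
        -0.5 * math.log(4.0 * math.pi * s * s)
        - 0.25 * (x - y) ** 2
        + _log_norm_mass_vec(lo, hi, 0.5 * (x + y), s / math.sqrt(2.0))
        - _log_norm_mass_vec(lo, hi, y, s)
    )
    return log_m - log_rep


def _t_conv_interpolator(nu: float):
    """Fast log k(d) lookup on an asinh grid with a tail closed form."""
    dmax = 2.0 * float(t_dist.ppf(1.0 - 1e-8, df=nu))
    g = np.linspace(0.0, math.asinh(dmax), 400)
    d_nodes = np.sinh(g)
    vals = np.array([t_convolution_logpdf(nu, d) for d in d_nodes])

    def logk(d: np.ndarray) -> np.ndarray:
        ad = np.abs(d)
        out = np.interp(np.arcsinh(ad), g, vals)
        tail = ad > dmax
        if np.any(tail):
            out[tail] = math.log(2.0) + t_dist.logpdf(ad[tail], df=nu)
        return out

    return logk


def _mc_bias_t(nu: float, reps: int, rng: np.random.Generator) -> np.ndarray:
    # full (unrestricted) hypothesis: log M = log C(nu), cross term k(x - y)
    x = rng.standard_t(nu, size=reps)
    y = rng.standard_t(nu, size=reps)
    logk = _t_conv_interpolator(nu)
    return log_product_t_constant(nu) - logk(x - y)


def _mc_bias_binomial(
    n: int, alpha: float, h: Hypothesis, reps: int, rng: np.random.Generator
) -> np.ndarray:
    p = rng.beta(alpha, alpha, size=reps)
    x = rng.binomial(n, p)
    y = rng.binomial(n, p)
    log_m = np.array(
        [
            binom_posterior_marginal_likelihood(BinomialCount(k, n, alpha), h)
            for k in range(n + 1)
        ]
    )
    log_rep = np.array(
        [
            [binom_replicate_marginal_likelihood(k, j, n, alpha, h) for j in range(n + 1)]
            for k in range(n + 1)
        ]
    )
    return log_m[x] - log_rep[x, y]


def _f_h_interpolator(nu1: float, nu2: float):
    span = math.log(float(f_dist.ppf(1.0 - 1e-8, nu1, nu2))) - math.log(
        float(f_dist.ppf(1e-8, nu1, nu2))
    )
    w_nodes = np.linspace(-span, span, 300)
    vals = np.array([_log_h(nu1, nu2, float(w)) for w in w_nodes])

    def logh(w: np.ndarray) -> np.ndarray:
        return np.interp(w, w_nodes, vals)

    return logh, span


def _mc_bias_f(
    nu1: float, nu2: float, reps: int, rng: np.random.Generator
) -> np.ndarray:
    x = rng.f(nu1, nu2, size=reps)
    y = rng.f(nu1, nu2, size=reps)
    logh, span = _f_h_interpolator(nu1, nu2)
    w = np.log(y) - np.log(x)
    w = np.clip(w, -span, span)  # beyond the grid the predictive mass is ~1e-8
    return log_f_constant(nu1, nu2) - logh(w)


def mc_expected_bias(
    family: str,
    params: dict | None = None,
    h: Hypothesis | None = None,
    reps: int = 100_000,
    seed: int = 0,
) -> BiasEstimate:
    """Simulation estimate of the expected bias for one family/hypothesis.

    families: 'normal' (params: none), 't' (nu), 'binomial' (n, alpha),
    'f' (nu1, nu2).  The t and F oracles support the unrestricted
    hypothesis (the tabulated case); normal and binomial support any
    scalar region.
    """
    params = params or {}
    h = Hypothesis.full() if h is None else h
    rng = np.random.default_rng(seed)
    if family == "normal":
        samples = _mc_bias_normal(
            h, reps, rng, float(params.get("mu_prior_sd", 0.0))
        )
    elif family == "t":
        if h.kind is not HypothesisKind.FULL:
            raise ValueError("t Monte Carlo oracle implements the full hypothesis")
        samples = _mc_bias_t(float(params["nu"]), reps, rng)
    elif family == "binomial":
        samples = _mc_bias_binomial(
            int(params["n"]), float(params.get("alpha", 1.0)), h, reps, rng
        )
    elif family == "f":
        if h.kind is not HypothesisKind.FULL:
            raise ValueError("F Monte Carlo oracle implements the full hypothesis")
        samples = _mc_bias_f(float(params["nu1"]), float(params["nu2"]), reps, rng)
    else:
        raise ValueError(f"unknown family {family!r}")
    return BiasEstimate(
        mean_bias=float(np.mean(samples)),
        mc_se=float(np.std(samples, ddof=1) / math.sqrt(reps)),
        reps=reps,
    )


# ---------------------------------------------------------------------------
# Limited multiplicity: bias and MSE tables
# ---------------------------------------------------------------------------


def _scenario_means(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """(reps, m) matrix of true means."""
    if cfg.scenario == "all_zero":
        return np.zeros((cfg.reps, cfg.m))
    if cfg.scenario == "normal_effects":
        return rng.normal(0.0, cfg.effect_sd, size=(cfg.reps, cfg.m))
    lo, hi = cfg.grid_range
    if cfg.m == 1:
        grid = np.array([0.5 * (lo + hi)])
    else:
        grid = np.linspace(lo, hi, cfg.m)
    return np.tile(grid, (cfg.reps, 1))


def _mixture_logml(
    a: np.ndarray, p_theta: float, own_log_factor: float
) -> np.ndarray:
    """log of [w_own A_ii + p sum_{j!=i} A_ij] / [w_own + p (m-1)].

    ``a`` holds log A_ij with shape (reps, m, m); the full-line region
    makes every W term 1.  own_log_factor is 0 (unadjusted) or -bias.
    """
    reps, m, _ = a.shape
    logw = np.full((m, m), math.log(p_theta) if p_theta > 0 else -math.inf)
    np.fill_diagonal(logw, own_log_factor)
    num = logsumexp(a + logw[None, :, :], axis=2)
    # denominator weights never carry the bias factor: own term weight 1
    logw_den = np.full((m, m), math.log(p_theta) if p_theta > 0 else -math.inf)
    np.fill_diagonal(logw_den, 0.0)
    den = logsumexp(logw_den, axis=1)  # region masses are 1 on the full line
    return num - den[None, :]


def run_limited_multiplicity(cfg: ScenarioConfig) -> pd.DataFrame:
    """Bias and MSE of mixture posterior marginal likelihoods for one (scenario, m).

    Simulates ``reps`` datasets of m sample means (s.e. 1/sqrt(n)) plus
    one independent replicate per mean.  Returns a one-row DataFrame with
    the unadjusted and adjusted bias of log M for the unrestricted
    alternative, and the single- and multiple-test mean-square errors
    against the replicate-prior comparator (the mixture over replicate
    posteriors with the same p_theta), all with Monte Carlo s.e.s.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = 1.0 / math.sqrt(cfg.n)
    mu = _scenario_means(cfg, rng)
    x = mu + sigma * rng.standard_normal(mu.shape)
    y = mu + sigma * rng.standard_normal(mu.shape)

    two_s2 = 2.0 * sigma * sigma
    const = -0.5 * math.log(2.0 * math.pi * two_s2)

    def log_a(left: np.ndarray, right: np.ndarray) -> np.ndarray:
        diff = left[:, :, None] - right[:, None, :]
        return const - 0.5 * diff**2 / two_s2

    a_xx = log_a(x, x)  # A_ij for the observed ensemble
    a_xy = log_a(x, y)  # prior from replicate posteriors

    p = cfg.p_theta
    log_unadj = _mixture_logml(a_xx, p, 0.0)
    log_adj = _mixture_logml(a_xx, p, -0.5)
    log_rep = _mixture_logml(a_xy, p, 0.0)  # replicate prior: no own-data bias

    bias_u = log_unadj - log_rep
    bias_a = log_adj - log_rep

    # single-test error has the closed form (x-y)^2/(4 sigma^2) - 1/2
    err_single = (x - y) ** 2 / (4.0 * sigma * sigma) - 0.5
    err_multi = bias_a

    def mean_se(v: np.ndarray) -> tuple[float, float]:
        flat = v.reshape(cfg.reps, -1).mean(axis=1)  # per-rep average over tests
        return float(flat.mean()), float(flat.std(ddof=1) / math.sqrt(cfg.reps))

    bias_u_m, bias_u_se = mean_se(bias_u)
    bias_a_m, bias_a_se = mean_se(bias_a)
    mse_s_m, mse_s_se = mean_se(err_single**2)
    mse_m_m, mse_m_se = mean_se(err_multi**2)

    return pd.DataFrame(
        [
            {
                "scenario": cfg.scenario,
                "m": cfg.m,
                "bias_unadjusted": bias_u_m,
                "bias_unadjusted_se": bias_u_se,
                "bias_adjusted": bias_a_m,
                "bias_adjusted_se": bias_a_se,
                "mse_single": mse_s_m,
                "mse_single_se": mse_s_se,
                "mse_multiple": mse_m_m,
                "mse_multiple_se": mse_m_se,
            }
        ]
    )


def run_limited_multiplicity_table(
    scenarios=("all_zero", "normal_effects", "grid"),
    m_values=range(1, 11),
    reps: int = 10000,
    n: int = 100,
    seed: int = 0,
    p_theta: float = 1.0,
) -> pd.DataFrame:
    """The full bias/MSE table across scenarios and numbers of tests."""
    rows = []
    for s_idx, scenario in enumerate(scenarios):
        for m in m_values:
            cfg = ScenarioConfig(
                scenario=scenario,
                m=m,
                n=n,
                reps=reps,
                seed=seed + 1000 * s_idx + m,
                p_theta=p_theta,
            )
            rows.append(run_limited_multiplicity(cfg))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Large-scale multiplicity
# ---------------------------------------------------------------------------


def run_large_scale(
    m: int = 1000,
    null_fraction: float = 0.9,
    seed: int = 0,
    p_theta_values=(1.0, 0.1, 0.01),
    effect_sd: float = 1.0,
    sigma: float = 1.0,
    thresholds=None,
) -> dict:
    """Screening experiment: many nulls, a minority of normal effects.

    Simulates m tests with a ``null_fraction`` of zero means and the rest
    N(0, effect_sd^2), sampling s.e. ``sigma``.  Computes single-test and
    mixture EBFs (H0: mu = 0 point vs H1 unrestricted) at each p_theta,
    true-positive proportions above a grid of EBF10 thresholds, and mean
    ranks of the non-null tests (rank 1 = strongest evidence against H0).
    """
    if m < 2:
        raise ValueError("large-scale experiment needs at least two tests")
    if not 0.0 <= null_fraction <= 1.0:
        raise ValueError("null_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_null = int(round(null_fraction * m))
    mu = np.concatenate(
        [np.zeros(n_null), rng.normal(0.0, effect_sd, size=m - n_null)]
    )
    perm = rng.permutation(m)
    mu = mu[perm]
    labels = mu != 0.0
    x = mu + sigma * rng.standard_normal(m)
    ses = np.full(m, sigma)

    h0 = Hypothesis.point(0.0)
    h1 = Hypothesis.full()
    out: dict = {"labels": labels, "estimates": x, "mu": mu}

    single = ebf_multiple(TestEnsemble(x, ses, 0.0), h0, h1)
    log10_single = np.array([-r.log_ebf01 for r in single]) / math.log(10.0)
    out["log10_ebf10_single"] = log10_single

    if thresholds is None:
        thresholds = np.logspace(0.0, 3.0, 13)
    thresholds = np.asarray(thresholds, dtype=float)
    out["thresholds"] = thresholds

    def tp_curve(log10_e: np.ndarray) -> np.ndarray:
        if not labels.any():  # no non-null tests: proportion undefined
            return np.full(thresholds.shape, math.nan)
        curve = []
        for t in thresholds:
            sel = log10_e > math.log10(t)
            curve.append(float(labels[sel].mean()) if sel.any() else math.nan)
        return np.array(curve)

    def mean_rank(log10_e: np.ndarray) -> float:
        if not labels.any():
            return math.nan
        ranks = rankdata(-log10_e, method="average")
        return float(ranks[labels].mean())

    out["tp_single"] = tp_curve(log10_single)
    out["mean_rank_single"] = mean_rank(log10_single)

    out["multiple"] = {}
    for p in p_theta_values:
        res = ebf_multiple(TestEnsemble(x, ses, p), h0, h1)
        log10_multi = np.array([-r.log_ebf01 for r in res]) / math.log(10.0)
        out["multiple"][p] = {
            "log10_ebf10": log10_multi,
            "tp": tp_curve(log10_multi),
            "mean_rank": mean_rank(log10_multi),
        }
    return out


def plot_large_scale(result: dict, path_scatter: str, path_tp: str) -> None:
    """Render the screening experiment: shrinkage scatter and TP curves.

    Writes two figures: per-test multiple- vs single-test log10 EBF10 at
    each mixture weight, and the proportion of true positives above each
    EBF threshold for the single- and multiple-test versions.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = result["log10_ebf10_single"]
    fig, ax = plt.subplots(figsize=(6, 5))
    markers = {1.0: "o", 0.1: "s", 0.01: "x"}
    for p, rec in result["multiple"].items():
        ax.scatter(
            s, rec["log10_ebf10"], s=8, marker=markers.get(p, "."),
            label=f"p_theta = {p}", alpha=0.6,
        )
    lim = [s.min(), s.max()]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel("single-test log10 EBF (for H1)")
    ax.set_ylabel("multiple-test log10 EBF (for H1)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path_scatter, dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 5))
    thr = result["thresholds"]
    ax.plot(np.log10(thr), result["tp_single"], "b--", label="single-test")
    first_p = next(iter(result["multiple"]))
    ax.plot(
        np.log10(thr), result["multiple"][first_p]["tp"], "k-",
        label=f"multiple-test (p_theta = {first_p})",
    )
    ax.set_xlabel("log10 EBF threshold")
    ax.set_ylabel("proportion of true positives")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path_tp, dpi=150)
    plt.close(fig)
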