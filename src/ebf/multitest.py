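"""Mixture-posterior EBFs for ensembles of normal-mean tests.

For m tests with estimates x_i and known standard errors sigma_i, the
posterior for each test's parameter is informed by the whole ensemble:
test i's alternative prior is a mixture of its own flat-prior posterior
and, with weight p_Theta, the posteriors of every other test.  The
posterior marginal likelihood for test i over a region Theta is

    [ e^{-bias} A_ii + p_Theta sum_{j != i} A_ij ]
    / [ W_ii + p_Theta sum_{j != i} W_ij ]

with A_ij = int_Theta phi(x_i; th, s_i^2) phi(th; x_j, s_j^2) dth and
W_ij = int_Theta phi(th; x_j, s_j^2) dth.  Only the own-data term A_ii is
bias-adjusted (the cross terms involve independent data); with one test
or p_Theta = 0 this reduces exactly to the single-test EBF.

Everything is a closed-form normal convolution times a normal-cdf region
factor; the m x m term matrices are accumulated blockwise in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, logsumexp
from scipy.stats import rankdata

from .core import (
    EvidenceResult,
    Hypothesis,
    HypothesisKind,
    normal_bias_rule,
)

__all__ = [
    "TestEnsemble",
    "mixture_posterior_ml",
    "ebf_multiple",
    "screen_report",
]

_BLOCK = 2048  # rows per block when accumulating the m x m term matrices


@dataclass(frozen=True)
class TestEnsemble:
    """m normal-mean tests sharing a hypothesis region and mixture weight."""

    __test__ = False  # data container, despite the Test* name

    estimates: np.ndarray
    ses: np.ndarray
    p_theta: float = 1.0
    hypothesis: Hypothesis = field(default_factory=Hypothesis.full)

    def __post_init__(self) -> None:
        est = np.atleast_1d(np.asarray(self.estimates, dtype=float))
        ses = np.atleast_1d(np.asarray(self.ses, dtype=float))
        if est.shape != ses.shape or est.ndim != 1:
            raise ValueError("estimates and ses must be 1-D arrays of equal length")
        if np.any(ses <= 0):
            raise ValueError("standard errors must be positive")
        if not 0.0 <= self.p_theta <= 1.0:
            raise ValueError("mixture weight p_theta must lie in [0, 1]")
        object.__setattr__(self, "estimates", est)
        object.__setattr__(self, "ses", ses)

    @property
    def m(self) -> int:
        return self.estimates.size


def _log_norm_mass(lo: float, hi: float, loc: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """log P[lo < N(loc, scale^2) < hi], elementwise, stable in the tails."""
    loc = np.asarray(loc, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if lo == -math.inf and hi == math.inf:
        return np.zeros(np.broadcast(loc, scale).shape)
    if lo == -math.inf:
        return log_ndtr((hi - loc) / scale)
    if hi == math.inf:
        return log_ndtr((loc - lo) / scale)
    la = log_ndtr((hi - loc) / scale)
    lb = log_ndtr((lo - loc) / scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = la + np.log1p(-np.exp(lb - la))
    return np.where(np.isfinite(out), out, -math.inf)


def _log_terms(
    ens: TestEnsemble, h: Hypothesis, rows: slice
) -> tuple[np.ndarray, np.ndarray]:
    """log A_ij and log W_ij for a block of rows i (all columns j).

    A_ij = phi(x_i; x_j, s_i^2 + s_j^2) * P[N(m_ij, v_ij) in Theta] with
    the usual product-of-normals combination m_ij, v_ij; W_ij is the
    posterior-j region mass.
    """
    x = ens.estimates
    s2 = ens.ses**2
    xi = x[rows, None]
    si2 = s2[rows, None]
    xj = x[None, :]
    sj2 = s2[None, :]
    tot = si2 + sj2
    log_conv = -0.5 * (math.log(2.0 * math.pi) + np.log(tot)) - 0.5 * (xi - xj) ** 2 / tot
    lo, hi = h.bounds()
    if h.kind is HypothesisKind.FULL:
        log_a = log_conv
        log_w = np.zeros_like(log_conv)
    else:
        v = si2 * sj2 / tot
        mid = (xi * sj2 + xj * si2) / tot
        log_a = log_conv + _log_norm_mass(lo, hi, mid, np.sqrt(v))
        log_w = _log_norm_mass(lo, hi, xj * np.ones_like(tot), np.sqrt(sj2) * np.ones_like(tot))
    return log_a, log_w


def mixture_posterior_ml(
    ens: TestEnsemble, h: Hypothesis | None = None, adjusted: bool = True
) -> np.ndarray:
    """Log mixture posterior marginal likelihood for every test.

    ``adjusted=False`` drops the own-term bias factor (the raw posterior
    marginal likelihood, used to study the bias itself).  Returns an
    array of length m; reduces to the single-test value for m = 1 or
    p_theta = 0.
    """
    h = ens.hypothesis if h is None else h
    if h.kind is HypothesisKind.POINT:
        raise ValueError("mixture posterior is defined for region hypotheses")
    m = ens.m
    bias = normal_bias_rule(h).value if adjusted else 0.0
    log_p = math.log(ens.p_theta) if ens.p_theta > 0 else -math.inf
    out = np.empty(m)
    for start in range(0, m, _BLOCK):
        rows = slice(start, min(start + _BLOCK, m))
        log_a, log_w = _log_terms(ens, h, rows)
        nrow = log_a.shape[0]
        idx = np.arange(start, rows.stop)
        local = np.arange(nrow)
        # weights: own term 1 (bias-adjusted), cross terms p_theta
        wts_a = np.full((nrow, m), log_p)
        wts_a[local, idx] = -bias
        wts_w = np.full((nrow, m), log_p)
        wts_w[local, idx] = 0.0
        num = logsumexp(log_a + wts_a, axis=1)
        den = logsumexp(log_w + wts_w, axis=1)
        out[rows] = num - den
    return out


def _log_point_likelihood(ens: TestEnsemble, h: Hypothesis) -> np.ndarray:
    z = (ens.estimates - h.value) / ens.ses
    return -0.5 * math.log(2.0 * math.pi) - np.log(ens.ses) - 0.5 * z**2


def ebf_multiple(
    ens: TestEnsemble, h0: Hypothesis, h1: Hypothesis
) -> list[EvidenceResult]:
    """Per-test EBFs between two hypotheses, using mixture posteriors.

    Point hypotheses use the plain likelihood (no mixture, no bias);
    region hypotheses the bias-adjusted mixture posterior marginal
    likelihood.  Deterministic given the ensemble.
    """
    def side(h: Hypothesis) -> np.ndarray:
        if h.kind is HypothesisKind.POINT:
            return _log_point_likelihood(ens, h)
        return mixture_posterior_ml(ens, h)

    log_m0 = side(h0)
    log_m1 = side(h1)
    return [EvidenceResult.from_log(float(v)) for v in log_m0 - log_m1]


def screen_report(
    ens: TestEnsemble,
    h0: Hypothesis,
    h1: Hypothesis,
    thresholds: np.ndarray | list[float] = (1.0, 3.73, 13.9, 52.0),
    labels: np.ndarray | None = None,
):
    """Screening table: counts above EBF10 thresholds and per-test ranks.

    EBFs are reported in favour of H1 (evidence against H0); rank 1 is
    the strongest such evidence, ties get average ranks.  With known
    non-null ``labels`` (simulation studies) the proportion of true
    positives above each threshold is included for both the single-test
    and mixture (multiple-test) EBFs.
    """
    import pandas as pd

    single = TestEnsemble(ens.estimates, ens.ses, 0.0, ens.hypothesis)
    res_multi = ebf_multiple(ens, h0, h1)
    res_single = ebf_multiple(single, h0, h1)
    log10_m = np.array([-r.log_ebf01 for r in res_multi]) / math.log(10.0)
    log10_s = np.array([-r.log_ebf01 for r in res_single]) / math.log(10.0)

    per_test = pd.DataFrame(
        {
            "log10_ebf10_single": log10_s,
            "log10_ebf10_multiple": log10_m,
            "rank_single": rankdata(-log10_s, method="average"),
            "rank_multiple": rankdata(-log10_m, method="average"),
        }
    )
    rows = []
    thr = np.asarray(thresholds, dtype=float)
    for t in thr:
        lt = math.log10(t)
        sel_s = log10_s > lt
        sel_m = log10_m > lt
        row = {
            "threshold": t,
            "n_single": int(sel_s.sum()),
            "n_multiple": int(sel_m.sum()),
        }
        if labels is not None:
            lab = np.asarray(labels, dtype=bool)
            row["tp_single"] = float(lab[sel_s].mean()) if sel_s.any() else math.nan
            row["tp_multiple"] = float(lab[sel_m].mean()) if sel_m.any() else math.nan
        rows.append(row)
    return per_test, pd.DataFrame(rows)
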