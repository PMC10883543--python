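"""Core machinery for empirical Bayes factors (EBFs).

An EBF is a posterior Bayes factor — the Bayes factor computed with the
posterior distribution from the data at hand standing in for the prior —
corrected for the bias incurred by using the data twice.  The calibration
target is the Bayes factor whose prior comes from hypothetical replicate
data of the same size, and the correction subtracts the expected excess
(in nats) of the log posterior marginal likelihood over that target.

This module holds the pieces shared by every test family:

* :class:`Hypothesis` — the parameter region under test,
* :class:`BiasSpec` — an expected bias attached to a hypothesis/family,
* :class:`EvidenceResult` — an assembled EBF with its interpretations,
* :func:`assemble_ebf` — the bias-corrected ratio,
* :func:`normal_bias_rule` — the regular-model bias (half the dimension,
  with directional/interval refinements),
* :func:`evidence_units` — logarithms in the base 2+sqrt(3) ≈ 3.73 that
  marks the sharpest transition between weaker and stronger belief.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "HypothesisKind",
    "Hypothesis",
    "EvidenceResult",
    "BiasSpec",
    "Family",
    "Favoured",
    "UndefinedEvidenceError",
    "assemble_ebf",
    "normal_bias_rule",
    "evidence_units",
    "evidence_base",
    "EVIDENCE_BASE",
]


class UndefinedEvidenceError(ValueError):
    """Both hypotheses have zero marginal likelihood: no evidence ratio exists."""


class HypothesisKind(str, enum.Enum):
    POINT = "point"
    LOWER_HALF = "lower_half"
    UPPER_HALF = "upper_half"
    INTERVAL = "interval"
    FULL = "full"


class Family(str, enum.Enum):
    NORMAL = "normal"
    T = "t"
    BINOMIAL = "binomial"
    NEGBINOMIAL = "negbinomial"
    F = "f"
    PVALUE = "pvalue"


class Favoured(str, enum.Enum):
    H0 = "H0"
    H1 = "H1"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class Hypothesis:
    """A region of parameter values.

    Scalar regions are a point, a half-line, a finite interval or the full
    line.  For vector parameters built from independent scalar components,
    ``d1`` counts one-sided components and ``d2`` two-sided (unrestricted)
    components; ``d1 + d2`` is the parameter dimension.

    ``opposite_sign_possible`` qualifies half-line hypotheses: if the
    excluded sign is impossible by definition (e.g. a variance ratio), the
    expected bias is that of the unrestricted hypothesis rather than half
    of it.
    """

    kind: HypothesisKind
    lower: float = -math.inf
    upper: float = math.inf
    value: float = 0.0
    d1: int = 0
    d2: int = 1
    opposite_sign_possible: bool = True

    def __post_init__(self) -> None:
        if self.kind is HypothesisKind.INTERVAL:
            if not self.lower < self.upper:
                raise ValueError("interval hypothesis requires lower < upper")
            if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
                raise ValueError(
                    "interval hypothesis requires finite bounds; use a half-line "
                    "or the full line for infinite regions"
                )
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("component counts d1, d2 must be non-negative")

    # -- constructors ------------------------------------------------------
    @classmethod
    def point(cls, value: float) -> "Hypothesis":
        return cls(HypothesisKind.POINT, value=value, d1=0, d2=0)

    @classmethod
    def greater(cls, cut: float = 0.0, *, opposite_sign_possible: bool = True) -> "Hypothesis":
        return cls(
            HypothesisKind.UPPER_HALF,
            lower=cut,
            d1=1,
            d2=0,
            opposite_sign_possible=opposite_sign_possible,
        )

    @classmethod
    def less(cls, cut: float = 0.0, *, opposite_sign_possible: bool = True) -> "Hypothesis":
        return cls(
            HypothesisKind.LOWER_HALF,
            upper=cut,
            d1=1,
            d2=0,
            opposite_sign_possible=opposite_sign_possible,
        )

    @classmethod
    def interval(cls, lower: float, upper: float) -> "Hypothesis":
        return cls(HypothesisKind.INTERVAL, lower=lower, upper=upper, d1=0, d2=0)

    @classmethod
    def full(cls, d: int = 1) -> "Hypothesis":
        return cls(HypothesisKind.FULL, d1=0, d2=d)

    @classmethod
    def vector(cls, d1: int, d2: int) -> "Hypothesis":
        """Independent scalar components: d1 one-sided, d2 two-sided."""
        return cls(HypothesisKind.FULL, d1=d1, d2=d2)

    # -- geometry ----------------------------------------------------------
    @property
    def dimension(self) -> int:
        if self.kind is HypothesisKind.POINT:
            return 0
        return max(self.d1 + self.d2, 1)

    def bounds(self) -> tuple[float, float]:
        """Scalar integration bounds of the region."""
        if self.kind is HypothesisKind.POINT:
            return (self.value, self.value)
        if self.kind is HypothesisKind.LOWER_HALF:
            return (-math.inf, self.upper)
        if self.kind is HypothesisKind.UPPER_HALF:
            return (self.lower, math.inf)
        if self.kind is HypothesisKind.INTERVAL:
            return (self.lower, self.upper)
        return (-math.inf, math.inf)


@dataclass(frozen=True)
class BiasSpec:
    """Expected bias E_Y b_H(Y) of the log posterior marginal likelihood, in nats."""

    value: float
    family: Family = Family.NORMAL
    hypothesis: Hypothesis | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("expected bias is non-negative for the implemented families")


#: Zero bias in the normal family (points and finite intervals).
NO_BIAS = BiasSpec(0.0)


@dataclass(frozen=True)
class EvidenceResult:
    """An EBF in favour of H0 over H1, with standard interpretations.

    ``ebf01`` may be 0 or +inf when one hypothesis is impossible; the log
    value is then -inf/+inf and the posterior probability 0/1.
    """

    ebf01: float
    log_ebf01: float
    units: float = field(default=math.nan)
    posterior_prob_h0: float = field(default=math.nan)
    favoured: Favoured = Favoured.NEUTRAL

    @classmethod
    def from_log(cls, log_ebf01: float) -> "EvidenceResult":
        if math.isnan(log_ebf01):
            raise UndefinedEvidenceError("log EBF is NaN: both hypotheses impossible?")
        try:
            ebf01 = math.exp(log_ebf01)
        except OverflowError:
            ebf01 = math.inf
        post = ebf01 / (1.0 + ebf01) if math.isfinite(ebf01) else 1.0
        if log_ebf01 > 0:
            fav = Favoured.H0
        elif log_ebf01 < 0:
            fav = Favoured.H1
        else:
            fav = Favoured.NEUTRAL
        units = log_ebf01 / math.log(evidence_base())
        return cls(
            ebf01=ebf01,
            log_ebf01=log_ebf01,
            units=units,
            posterior_prob_h0=post,
            favoured=fav,
        )

    @property
    def ebf10(self) -> float:
        if self.ebf01 == 0.0:
            return math.inf
        return 1.0 / self.ebf01

    def reciprocal(self) -> "EvidenceResult":
        """The same evidence with the hypotheses swapped."""
        return EvidenceResult.from_log(-self.log_ebf01)


def assemble_ebf(
    log_m0: float,
    bias0: BiasSpec | float,
    log_m1: float,
    bias1: BiasSpec | float,
) -> EvidenceResult:
    """Combine two log posterior marginal likelihoods into an EBF.

    The EBF in favour of H0 is the ratio of bias-corrected posterior
    marginal likelihoods::

        log EBF01 = (log M_H0 - bias0) - (log M_H1 - bias1)

    ``-inf`` encodes a hypothesis with zero marginal likelihood; both
    being ``-inf`` raises :class:`UndefinedEvidenceError`.
    """
    b0 = bias0.value if isinstance(bias0, BiasSpec) else float(bias0)
    b1 = bias1.value if isinstance(bias1, BiasSpec) else float(bias1)
    if log_m0 == -math.inf and log_m1 == -math.inf:
        raise UndefinedEvidenceError("both hypotheses have zero marginal likelihood")
    if math.isnan(log_m0) or math.isnan(log_m1):
        raise ValueError("log marginal likelihoods must not be NaN")
    log_ebf = (log_m0 - b0) - (log_m1 - b1)
    return EvidenceResult.from_log(log_ebf)


def normal_bias_rule(h: Hypothesis) -> BiasSpec:
    """Expected bias under regular normal theory.

    For a d-dimensional unrestricted hypothesis the expected bias is d/2.
    A half-line hypothesis has half that (1/4) when the opposite sign is a
    priori possible, but the full 1/2 when it is impossible by definition.
    Points and finite intervals carry no bias.  For vectors of independent
    components the biases add: (d1 + 2*d2)/4.
    """
    k = h.kind
    if k in (HypothesisKind.POINT, HypothesisKind.INTERVAL):
        return BiasSpec(0.0, Family.NORMAL, h)
    if k in (HypothesisKind.LOWER_HALF, HypothesisKind.UPPER_HALF):
        value = 0.25 if h.opposite_sign_possible else 0.5
        return BiasSpec(value, Family.NORMAL, h)
    # full / vector case
    return BiasSpec((h.d1 + 2 * h.d2) / 4.0, Family.NORMAL, h)


# ---------------------------------------------------------------------------
# Evidence units: base 2 + sqrt(3)
# ---------------------------------------------------------------------------

_EVIDENCE_BASE_CACHE: float | None = None


def _logistic_third_derivative_root() -> float:
    """Positive root x* of the third derivative of the logistic function.

    With s(x) = 1/(1+e^-x), s''' = s(1-s)(1 - 6s + 6s^2) vanishes where
    6s^2 - 6s + 1 = 0, i.e. s = (3+sqrt 3)/6 on the positive branch.  The
    root is located by bisection on s''' so the evidence base is derived,
    not hard-coded.
    """

    def d3(x: float) -> float:
        s = 1.0 / (1.0 + math.exp(-x))
        return s * (1.0 - s) * (1.0 - 6.0 * s + 6.0 * s * s)

    lo, hi = 0.5, 3.0  # d3(0.5) < 0 < d3(3.0)
    if not (d3(lo) < 0.0 < d3(hi)):
        raise ArithmeticError("bracketing failed for the logistic third derivative")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if d3(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def evidence_base() -> float:
    """The unit-of-evidence base exp(x*) = 2 + sqrt(3) ≈ 3.7321.

    One unit of evidence is the Bayes factor that moves any belief from
    the 'weaker' side of the logistic inflection structure to the
    'stronger' side.  Computed once by root-finding and cached; falls back
    to the closed form 2+sqrt(3) if bracketing fails.
    """
    global _EVIDENCE_BASE_CACHE
    if _EVIDENCE_BASE_CACHE is None:
        try:
            _EVIDENCE_BASE_CACHE = math.exp(_logistic_third_derivative_root())
        except ArithmeticError:
            _EVIDENCE_BASE_CACHE = 2.0 + math.sqrt(3.0)
    return _EVIDENCE_BASE_CACHE


def evidence_units(ebf: float) -> float:
    """Logarithm of a Bayes factor in base 2+sqrt(3); signed.

    Positive values favour the numerator hypothesis; one unit multiplies
    the odds by ≈3.73.
    """
    if not ebf > 0:
        raise ValueError("evidence units require a positive Bayes factor")
    return math.log(ebf) / math.log(evidence_base())


#: Convenience constant (computed at import through the cached root-finder).
EVIDENCE_BASE = evidence_base()
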