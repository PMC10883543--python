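"""Shared brute-force quadrature oracles used by the acceptance checks."""

import math

from scipy import integrate
from scipy.stats import f as f_dist


def f_quadrature_log_ml(x, nu1, nu2, lo, hi):
    """Direct quadrature of the F posterior-marginal-likelihood integrals."""
    num, _ = integrate.quad(
        lambda r: r * x * f_dist.pdf(r * x, nu1, nu2) ** 2, lo, hi, limit=200
    )
    den, _ = integrate.quad(
        lambda r: x * f_dist.pdf(r * x, nu1, nu2), lo, hi, limit=200
    )
    return math.log(num) - math.log(den)


def pvalue_quadrature_log_ml(p):
    """Direct quadrature of the two beta-integrals in a rescaled variable."""
    m = -math.log1p(-p)

    def b_of(t):
        return 1.0 + t / m

    num, _ = integrate.quad(
        lambda t: b_of(t) ** 2 * math.exp(-(2.0 * b_of(t) - 1.0) * m) / m,
        0.0, math.inf, limit=200,
    )
    den, _ = integrate.quad(
        lambda t: b_of(t) * math.exp(-b_of(t) * m) / m, 0.0, math.inf, limit=200
    )
    return math.log(num) - math.log(den)
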