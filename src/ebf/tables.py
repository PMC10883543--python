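"""Regeneration of the bias tables and the P-value calibration table.

The bias tables tabulate the expected bias E_Y b_H(Y) over degrees of
freedom (t, F) or trials (binomial); the calibration table inverts each
closed-form EBF to find the P-value at which the evidence in favour of
the alternative reaches a whole number of 3.73-units.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .binomial import binom_expected_bias
from .core import Hypothesis, evidence_base
from .fdist import f_expected_bias_value
from .student_t import t_expected_bias_value

__all__ = [
    "t_bias_table",
    "binomial_bias_table",
    "f_bias_table",
    "calibration_table",
]


def t_bias_table(nus=range(1, 11)) -> pd.DataFrame:
    """Expected bias for the t family, unrestricted hypothesis."""
    return pd.DataFrame(
        {"nu": list(nus), "expected_bias": [t_expected_bias_value(float(v)) for v in nus]}
    )


def binomial_bias_table(ns=range(1, 11), alpha: float = 1.0) -> pd.DataFrame:
    """Expected bias for the binomial, regions [0,1] and [0,0.5]."""
    full = Hypothesis.full()
    half = Hypothesis.less(0.5)
    return pd.DataFrame(
        {
            "n": list(ns),
            "bias_full": [binom_expected_bias(n, alpha, full).value for n in ns],
            "bias_half": [binom_expected_bias(n, alpha, half).value for n in ns],
        }
    )


def f_bias_table(dfs=(1, 5, 10, 20, 50)) -> pd.DataFrame:
    """Expected bias for the F family on a (nu1, nu2) grid."""
    rows = []
    for nu1 in dfs:
        row = {"nu1": nu1}
        for nu2 in dfs:
            row[f"nu2_{nu2}"] = f_expected_bias_value(float(nu1), float(nu2))
        rows.append(row)
    return pd.DataFrame(rows)


def pvalue_at_units_normal(units: float) -> float:
    """Two-sided normal P-value where the EBF for H1 reaches `units`."""
    e = evidence_base() ** units
    z2 = 1.0 + math.log(2.0) + 2.0 * math.log(e)
    return 2.0 * float(norm.sf(math.sqrt(z2)))


def pvalue_at_units_chisq(units: float, df: int) -> float:
    """Chi-squared P-value (df degrees of freedom) at `units` of evidence."""
    e = evidence_base() ** units
    q = df * (1.0 + math.log(2.0)) + 2.0 * math.log(e)
    return float(chi2.sf(q, df))


def pvalue_at_units_10p(units: float) -> float:
    """P-value whose 10p-rule EBF for H1 reaches `units`."""
    return 1.0 / (10.0 * evidence_base() ** units)


def calibration_table(units=(1.0, 2.0, 3.0, 4.0)) -> pd.DataFrame:
    """P-value calibrations for whole units of evidence in favour of H1.

    Columns mirror the tests with simple closed forms: the two-sided
    normal mean, chi-squared with 2 and 3 df, and the 10p rule.
    """
    rows = []
    for u in units:
        rows.append(
            {
                "units": u,
                "ebf10": evidence_base() ** u,
                "p_normal_2sided": pvalue_at_units_normal(u),
                "p_chisq_2df": pvalue_at_units_chisq(u, 2),
                "p_chisq_3df": pvalue_at_units_chisq(u, 3),
                "p_10p_rule": pvalue_at_units_10p(u),
            }
        )
    return pd.DataFrame(rows)
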