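"""Heterogeneity diagnostics and leave-one-out sensitivity analysis.

Cochran's Q measures the dispersion of per-variant Wald ratios around the
IVW estimate using the same first-order weights as IVW itself; under the
null of no heterogeneity it is approximately chi-square with k-1 degrees of
freedom.  I^2 = (Q - (k-1))/Q expresses the fraction of that dispersion
beyond chance, clipped at 0 and reported as a percentage; its confidence
interval uses the test-based method of Higgins & Thompson.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrEstimate, cochran_q, ivw, wald_ratio
from .exceptions import InsufficientVariantsError
from .harmonization import HarmonizedSet


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pvalue: float
    i2: float          # percent in [0, 100]
    i2_ci: tuple[float, float]

    def __post_init__(self):
        if self.q < 0 or self.df < 1:
            raise ValueError("Q must be >= 0 and df >= 1")
        if not (0 <= self.i2 <= 100):
            raise ValueError("I2 must lie in [0, 100]")


def _i2_ci_test_based(q: float, df: int) -> tuple[float, float]:
    """95% CI for I^2 via the test-based interval for H = sqrt(Q/df)."""
    if df < 2 or q <= 0:
        return (0.0, 100.0) if df < 2 else (0.0, 0.0) if q == 0 else (0.0, 100.0)
    ln_h = 0.5 * math.log(max(q / df, 1e-300))
    if q > df:
        se = (math.log(q) - math.log(df)) / (2 * (math.sqrt(2 * q) - math.sqrt(2 * df - 1)))
    else:
        se = math.sqrt(1 / (2 * (df - 1)) * (1 - 1 / (3 * (df - 1) ** 2)))
    z = stats.norm.ppf(0.975)
    lo_h = math.exp(ln_h - z * se)
    hi_h = math.exp(ln_h + z * se)

    def h_to_i2(h):
        return max(0.0, (h**2 - 1) / h**2 * 100) if h > 0 else 0.0

    return h_to_i2(lo_h), h_to_i2(hi_h)


def cochran_q_i2(h: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q and I^2 of the Wald ratios against the IVW estimate."""
    if h.k < 2:
        raise InsufficientVariantsError("cochran_q_i2: needs >= 2 variants")
    bx, _, by, sy = h.arrays()
    theta = ivw(h, model="fixed").beta
    q = cochran_q(bx, by, sy, theta)
    df = h.k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q * 100) if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, pvalue=p, i2=i2,
                               i2_ci=_i2_ci_test_based(q, df))


@dataclass
class LeaveOneOutResult:
    """Per-variant exclusion estimates plus the all-variant estimate."""

    method: str
    estimates: dict[str, MrEstimate]   # excluded rsid -> estimate on the rest
    full: MrEstimate

    def __post_init__(self):
        ks = {e.k for e in self.estimates.values()}
        if ks and ks != {self.full.k - 1}:
            raise ValueError("each leave-one-out estimate must use k-1 variants")

    def to_frame(self) -> pd.DataFrame:
        """Tabular forest-plot equivalent: one row per excluded variant."""
        rows = []
        for rsid, e in list(self.estimates.items()) + [("(none)", self.full)]:
            row = {"excluded": rsid, "k": e.k, "beta": e.beta, "se": e.se,
                   "ci_low": e.ci_low, "ci_high": e.ci_high, "pvalue": e.pvalue}
            if e.binary:
                row["or"] = e.odds_ratio
                row["or_ci_low"], row["or_ci_high"] = e.or_ci
            rows.append(row)
        return pd.DataFrame(rows)


def leave_one_out(h: HarmonizedSet, method: str = "ivw", **kwargs) -> LeaveOneOutResult:
    """Re-estimate with each variant removed in turn, preserving order.

    ``method`` is an estimator label (``ivw``, ``weighted_median``,
    ``mr_egger``); extra keyword arguments are passed through.  With k = 2
    each sub-estimate is the single remaining variant's Wald ratio (IVW
    degenerates to it).
    """
    from . import estimators as est

    if h.k < 2:
        raise InsufficientVariantsError("leave_one_out: needs >= 2 variants")
    fn = {"ivw": est.ivw, "weighted_median": est.weighted_median,
          "mr_egger": est.mr_egger}[method]
    full = fn(h, **kwargs)
    out: dict[str, MrEstimate] = {}
    for rsid in h.rsids:
        out[rsid] = fn(h.subset([rsid]), **kwargs)
    return LeaveOneOutResult(method=method, estimates=out, full=full)
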