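"""Causal estimators for two-sample summary-statistic MR.

All estimators consume a :class:`~tsmr.harmonization.HarmonizedSet` whose
exposure effects are oriented positive (exposure-raising allele).  The
per-variant building block is the Wald ratio beta_y / beta_x; the set-level
estimators differ in how they combine and robustify it:

* ``ivw`` — inverse-variance weighted meta-analysis of Wald ratios,
  equivalently weighted least squares of beta_y on beta_x through the origin
  with weights 1/se_y^2.  Consistent only when every instrument is valid.
* ``weighted_median`` — interpolated weighted median of Wald ratios;
  consistent when instruments carrying >= 50% of the weight are valid.
* ``mr_egger`` — weighted regression with an unconstrained intercept; the
  intercept estimates the average directional pleiotropic effect and the
  slope remains consistent under the InSIDE assumption.

For binary outcomes (log-odds effects) estimates exponentiate onto the
odds-ratio scale per 1 SD of exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    CollinearityError,
    DegenerateInstrumentError,
    EmptyInstrumentError,
    InsufficientVariantsError,
)
from .harmonization import HarmonizedPair, HarmonizedSet

Z975 = stats.norm.ppf(0.975)


@dataclass
class MrEstimate:
    """A causal-effect estimate, per 1 SD of exposure."""

    method: str
    k: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    binary: bool = False
    model: str | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_ci: tuple[float, float] | None = None
    intercept_pvalue: float | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError(
                f"{self.method}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"bracket the point estimate {self.beta}"
            )

    # --- odds-ratio scale (binary outcomes only) -------------------------
    @property
    def odds_ratio(self) -> float | None:
        return math.exp(self.beta) if self.binary else None

    @property
    def or_ci(self) -> tuple[float, float] | None:
        if not self.binary:
            return None
        return math.exp(self.ci_low), math.exp(self.ci_high)


def _normal_ci_p(beta: float, se: float) -> tuple[float, float, float]:
    p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else float("nan")
    return beta - Z975 * se, beta + Z975 * se, p


def wald_ratio(pair: HarmonizedPair, binary: bool = False,
               second_order: bool = False) -> MrEstimate:
    """Single-variant causal estimate beta_y / beta_x.

    The default SE is the first-order delta approximation se_y / |beta_x|;
    ``second_order`` adds the term propagating exposure uncertainty.
    """
    if pair.beta_x == 0:
        raise DegenerateInstrumentError(f"{pair.rsid}: exposure beta is zero")
    beta = pair.beta_y / pair.beta_x
    var = pair.se_y**2 / pair.beta_x**2
    if second_order:
        var += pair.beta_y**2 * pair.se_x**2 / pair.beta_x**4
    se = math.sqrt(var)
    lo, hi, p = _normal_ci_p(beta, se)
    return MrEstimate(method="wald_ratio", k=1, beta=beta, se=se,
                      ci_low=lo, ci_high=hi, pvalue=p, binary=binary)


def _check_k(h: HarmonizedSet, minimum: int, method: str) -> None:
    if h.k == 0:
        raise EmptyInstrumentError(f"{method}: no retained variants")
    if h.k < minimum:
        raise InsufficientVariantsError(
            f"{method}: needs >= {minimum} variants, got {h.k}"
        )


def cochran_q(bx, by, sy, theta) -> float:
    """Cochran's Q of Wald ratios around ``theta``, first-order weights."""
    w = bx**2 / sy**2
    return float(np.sum(w * (by / bx - theta) ** 2))


def ivw(h: HarmonizedSet, model: str = "multiplicative_re") -> MrEstimate:
    """Inverse-variance weighted estimate.

    The point estimate is weighted least squares of beta_y on beta_x through
    the origin with weights 1/se_y^2 — identical under both models.  The
    fixed model uses the analytic SE (sum of weights)^-1/2; the
    multiplicative random-effects model inflates it by max(1, sqrt(Q/(k-1)))
    so that under-dispersion never shrinks the SE.
    """
    if model not in ("fixed", "multiplicative_re"):
        raise ValueError(f"unknown IVW model {model!r}")
    _check_k(h, 1, "ivw")
    bx, _, by, sy = h.arrays()
    w = 1 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = math.sqrt(1 / denom)
    if model == "multiplicative_re" and h.k > 1:
        q = cochran_q(bx, by, sy, beta)
        se *= max(1.0, math.sqrt(q / (h.k - 1)))
    lo, hi, p = _normal_ci_p(beta, se)
    return MrEstimate(method="ivw", k=h.k, beta=beta, se=se, ci_low=lo,
                      ci_high=hi, pvalue=p, binary=h.binary, model=model)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (standardized cumulative weights)."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    p = (np.cumsum(w) - w / 2) / np.sum(w)
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MrEstimate:
    """Weighted median of Wald ratios with a parametric-bootstrap SE.

    Weights are first-order inverse ratio variances beta_x^2/se_y^2.  The SE
    resamples per-variant exposure and outcome effects from their sampling
    distributions (``n_boot`` replicates, mandatory ``seed`` for
    reproducibility) and takes the standard deviation of the re-estimated
    medians.
    """
    _check_k(h, 3, "weighted_median")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    bx, sx, by, sy = h.arrays()
    weights = bx**2 / sy**2
    beta = _weighted_median(by / bx, weights)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, h.k))
    by_b = rng.normal(by, sy, size=(n_boot, h.k))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        w = bx_b[i] ** 2 / sy**2
        boots[i] = _weighted_median(by_b[i] / bx_b[i], w)
    se = float(np.std(boots, ddof=1))
    lo, hi, p = _normal_ci_p(beta, se)
    return MrEstimate(method="weighted_median", k=h.k, beta=beta, se=se,
                      ci_low=lo, ci_high=hi, pvalue=p, binary=h.binary)


def mr_egger(h: HarmonizedSet, pvalue_dist: str = "normal") -> MrEstimate:
    """MR-Egger regression: slope (causal effect) and pleiotropy intercept.

    Weighted linear regression of beta_y on beta_x with an intercept and
    weights 1/se_y^2; exposure effects must be oriented positive (the
    estimator is orientation-sensitive).  SEs are scaled by
    max(1, residual standard error) — multiplicative random effects.
    ``pvalue_dist`` chooses normal (default) or t(k-2) reference quantiles.
    """
    _check_k(h, 3, "mr_egger")
    if pvalue_dist not in ("normal", "t"):
        raise ValueError(f"unknown pvalue_dist {pvalue_dist!r}")
    bx, _, by, sy = h.arrays()
    if np.ptp(bx) == 0:
        raise CollinearityError("mr_egger: no spread in exposure betas")
    w = 1 / sy**2
    # weighted least squares with intercept, closed form on the 2-column design
    X = np.column_stack([np.ones_like(bx), bx])
    wx = X * w[:, None]
    xtwx = X.T @ wx
    coef = np.linalg.solve(xtwx, wx.T @ by)
    resid = by - X @ coef
    dof = h.k - 2
    sigma2 = float(np.sum(w * resid**2) / dof)
    scale = max(1.0, math.sqrt(sigma2))
    cov_unit = np.linalg.inv(xtwx)  # covariance for unit residual variance
    se_int, se_slope = scale * np.sqrt(np.diag(cov_unit))
    intercept, slope = coef

    if pvalue_dist == "t":
        q = stats.t.ppf(0.975, dof)
        p_slope = 2 * stats.t.sf(abs(slope) / se_slope, dof)
        p_int = 2 * stats.t.sf(abs(intercept) / se_int, dof)
        lo, hi = slope - q * se_slope, slope + q * se_slope
        ilo, ihi = intercept - q * se_int, intercept + q * se_int
    else:
        lo, hi, p_slope = _normal_ci_p(slope, se_slope)
        ilo, ihi, p_int = _normal_ci_p(intercept, se_int)
    return MrEstimate(
        method="mr_egger", k=h.k, beta=float(slope), se=float(se_slope),
        ci_low=float(lo), ci_high=float(hi), pvalue=float(p_slope),
        binary=h.binary, model="multiplicative_re",
        intercept=float(intercept), intercept_se=float(se_int),
        intercept_ci=(float(ilo), float(ihi)), intercept_pvalue=float(p_int),
    )
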