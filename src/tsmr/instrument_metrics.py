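"""Instrument strength and statistical power.

Variance explained (R^2) by a set of instruments can be computed three ways:

``f_stat_approx`` (default)
    r^2_i = beta_i^2 / (beta_i^2 + N * se_i^2), the standard identity
    linking the per-variant F statistic to R^2.  This is the variant that
    reproduces the packaged study's per-variant R^2 column.
``printed_formula_1``
    r^2_i = beta_i^2 / (beta_i^2 + 2 * N * se_i^2) — the same expression
    with an extra factor 2 in the denominator, kept available because some
    sources print it this way; it roughly halves every value.
``formula_2``
    r^2_i = 2 * MAF_i * (1 - MAF_i) * beta_i^2, the allele-frequency form
    valid when the exposure is standardized.

Power for a binary outcome follows the non-centrality approximation used by
the mRnd calculator: power = Phi(sqrt(N * R^2 * K * (1-K)) * |ln OR| -
z_{1-alpha/2}) with K the case fraction; for continuous outcomes the
K(1-K) term is dropped and |ln OR| becomes |beta|.  The minimal detectable
effect inverts this in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .exceptions import InfeasiblePowerError, MissingFrequencyError
from .summary_data import InstrumentSet

FORMULAS = ("f_stat_approx", "printed_formula_1", "formula_2")


@dataclass
class VarianceExplained:
    formula: str
    per_variant: dict[str, float]   # rsid -> r^2 (fraction, not percent)
    n: int | None = None

    @property
    def total(self) -> float:
        return sum(self.per_variant.values())

    @property
    def total_percent(self) -> float:
        return 100 * self.total

    def per_variant_percent(self, ndigits: int = 2) -> dict[str, float]:
        """Per-variant r^2 in percent, rounded for table display."""
        return {r: round(100 * v, ndigits) for r, v in self.per_variant.items()}

    def total_percent_rounded(self, ndigits: int = 2) -> float:
        """Sum of the per-variant percentages after rounding each.

        Matches how a printed table column totals: round first, then add.
        """
        return round(sum(self.per_variant_percent(ndigits).values()), ndigits)


def variance_explained(
    instruments: InstrumentSet, n: int | None = None, formula: str = "f_stat_approx"
) -> VarianceExplained:
    """Per-variant and total exposure variance explained by the instruments."""
    if formula not in FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; choose from {FORMULAS}")
    per: dict[str, float] = {}
    for rec in instruments:
        b2 = rec.beta**2
        if formula == "formula_2":
            if rec.eaf is None:
                raise MissingFrequencyError(
                    f"{rec.rsid}: formula_2 needs the effect-allele frequency"
                )
            maf = rec.maf
            per[rec.rsid] = 2 * maf * (1 - maf) * b2
        else:
            n_i = n if n is not None else rec.n
            if n_i is None:
                raise ValueError(f"{rec.rsid}: sample size required for {formula}")
            factor = 2 if formula == "printed_formula_1" else 1
            per[rec.rsid] = b2 / (b2 + factor * n_i * rec.se**2)
    return VarianceExplained(formula=formula, per_variant=per, n=n)


def f_statistic(r2: float, n: int, k: int) -> float:
    """Instrument-strength F statistic: (N - K - 1)/K * R^2/(1 - R^2)."""
    return (n - k - 1) / k * r2 / (1 - r2)


@dataclass
class PowerSpec:
    """Inputs of an MR power calculation.

    ``effect`` is the true OR for a binary outcome (``case_fraction`` set)
    or the true beta in exposure-SD units for a continuous outcome
    (``case_fraction`` None).
    """

    n_total: int
    r2: float
    alpha: float = 0.05
    case_fraction: float | None = None
    effect: float | None = None

    def __post_init__(self):
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")

    @property
    def binary(self) -> bool:
        return self.case_fraction is not None

    def _ncp_scale(self) -> float:
        scale = self.n_total * self.r2
        if self.binary:
            scale *= self.case_fraction * (1 - self.case_fraction)
        return math.sqrt(scale)


def mr_power(spec: PowerSpec) -> float:
    """Achieved power at the spec's true effect (two-sided alpha)."""
    if spec.effect is None:
        raise ValueError("PowerSpec.effect is required for mr_power")
    magnitude = abs(math.log(spec.effect)) if spec.binary else abs(spec.effect)
    z = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(spec._ncp_scale() * magnitude - z))


def detectable_or(
    spec: PowerSpec, target_power: float = 0.80, direction: str = "protective"
) -> float:
    """Odds ratio closest to 1 detectable at ``target_power``.

    Closed-form inversion of the power approximation:
    |ln OR| = (z_{1-alpha/2} + z_{power}) / sqrt(N R^2 K (1-K)).
    For a continuous outcome this returns the detectable |beta| as
    exp-untransformed magnitude is meaningless; use ``detectable_beta``.
    """
    if direction not in ("protective", "risk"):
        raise ValueError("direction must be 'protective' or 'risk'")
    if not spec.binary:
        raise ValueError("detectable_or needs a binary-outcome spec; "
                         "use detectable_beta for continuous outcomes")
    magnitude = _detectable_magnitude(spec, target_power)
    return math.exp(-magnitude if direction == "protective" else magnitude)


def detectable_beta(spec: PowerSpec, target_power: float = 0.80) -> float:
    """Minimal |beta| (exposure-SD units) detectable for a continuous outcome."""
    if spec.binary:
        raise ValueError("detectable_beta needs a continuous-outcome spec")
    return _detectable_magnitude(spec, target_power)


def _detectable_magnitude(spec: PowerSpec, target_power: float) -> float:
    z_alpha = stats.norm.ppf(1 - spec.alpha / 2)
    lower = float(stats.norm.cdf(-z_alpha))  # power at a null effect
    if not (lower <= target_power < 1):
        raise InfeasiblePowerError(
            f"target power must lie in [{lower:.4g}, 1), got {target_power}"
        )
    z_power = stats.norm.ppf(target_power)
    return float((z_alpha + z_power) / spec._ncp_scale())
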