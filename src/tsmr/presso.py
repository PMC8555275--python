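"""MR-PRESSO: pleiotropy residual sum and outlier test.

The global test asks whether the observed dispersion of outcome effects
around the fitted no-pleiotropy model exceeds what sampling noise alone
produces.  It computes a leave-one-out residual sum of squares (each
variant's residual uses the slope fitted without it) and compares it with
the RSS distribution over parametric simulations of the summary statistics
under the fitted model.  The per-variant outlier test compares each
observed leave-one-out residual with its own simulated distribution
(Bonferroni-corrected across variants); if outliers are found the causal
effect is re-estimated without them and a distortion test measures how much
their removal moves the estimate.

Causal estimates here follow the MR-PRESSO convention: weighted regression
through the origin with weights 1/se_y^2 whose SE carries the empirical
residual scale (no flooring at 1), normal-theory 95% CI, and a t reference
distribution with k-1 (raw) or k-1-#outliers (corrected) degrees of freedom
for the p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MrEstimate
from .exceptions import InsufficientVariantsError
from .harmonization import HarmonizedSet


@dataclass
class PressoResult:
    global_rss: float
    global_p: float                     # resolution 1/n_sim; floored below
    global_p_floor: bool                # True when no simulated RSS reached observed
    outliers: list[str]                 # rsids flagged at the corrected threshold
    outlier_pvalues: dict[str, float]   # Bonferroni-adjusted, capped at 1
    raw_estimate: MrEstimate
    corrected_estimate: MrEstimate | None
    distortion_p: float | None
    n_sim: int
    seed: int

    def __post_init__(self):
        if not (0 < self.global_p <= 1):
            raise ValueError("global_p must lie in (0, 1]")
        if self.corrected_estimate is not None and not self.outliers:
            raise ValueError("corrected_estimate requires removed outliers")


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Slope of weighted origin regression with each observation left out."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def _loo_residuals(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted squared leave-one-out residuals (one per variant)."""
    theta = _loo_slopes(bx, by, w)
    return w * (by - theta * bx) ** 2


def _origin_estimate(bx, by, sy, binary: bool, df: int, label: str) -> MrEstimate:
    """Weighted origin regression with empirical residual scaling (lm-style)."""
    w = 1 / sy**2
    sxx = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / sxx
    resid2 = w * (by - beta * bx) ** 2
    sigma2 = float(np.sum(resid2)) / df
    se = math.sqrt(sigma2 / sxx)
    z = stats.norm.ppf(0.975)
    p = 2 * float(stats.t.sf(abs(beta) / se, df))
    return MrEstimate(method=label, k=len(bx), beta=beta, se=se,
                      ci_low=beta - z * se, ci_high=beta + z * se,
                      pvalue=p, binary=binary)


def presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    significance: float = 0.05,
    seed: int | None = None,
    distortion: bool = True,
) -> PressoResult:
    """Run the MR-PRESSO global, outlier and distortion tests.

    Parameters
    ----------
    h
        Harmonized set with k >= 4 retained variants (the leave-one-out
        regressions need at least 3 points each).
    n_sim
        Number of parametric simulations (>= 100) defining the null RSS
        distribution; the global p has resolution 1/n_sim.
    significance
        Per-variant outlier threshold applied to Bonferroni-adjusted
        outlier p-values.
    seed
        Mandatory RNG seed; identical seed and inputs give identical
        results.
    """
    if h.k < 4:
        raise InsufficientVariantsError("presso: needs >= 4 variants")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if seed is None:
        raise ValueError("presso requires an explicit seed")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = h.arrays()
    rsids = h.rsids
    k = h.k
    w = 1 / sy**2

    obs_resid = _loo_residuals(bx, by, w)
    obs_rss = float(np.sum(obs_resid))

    # expected outcome effect for each variant under its leave-one-out fit
    fitted = _loo_slopes(bx, by, w) * bx

    # parametric simulations under the fitted no-pleiotropy model
    sim_resid = np.empty((n_sim, k))
    for s in range(n_sim):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(fitted, sy)
        sim_resid[s] = _loo_residuals(bx_s, by_s, w)
    sim_rss = sim_resid.sum(axis=1)

    exceed = int(np.sum(sim_rss > obs_rss))
    global_p_floor = exceed == 0
    global_p = max(exceed, 1) / n_sim

    # per-variant outlier test, Bonferroni across k
    outlier_p: dict[str, float] = {}
    outliers: list[str] = []
    for j, rsid in enumerate(rsids):
        pj = float(np.sum(sim_resid[:, j] > obs_resid[j])) / n_sim
        adj = min(1.0, pj * k)
        outlier_p[rsid] = adj
        if adj < significance:
            outliers.append(rsid)

    raw = _origin_estimate(bx, by, sy, h.binary, df=k - 1, label="mr_presso_raw")

    corrected = None
    distortion_p = None
    if outliers:
        keep = np.array([r not in outliers for r in rsids])
        if keep.sum() >= 2:
            corrected = _origin_estimate(
                bx[keep], by[keep], sy[keep], h.binary,
                df=k - 1 - len(outliers), label="mr_presso_corrected",
            )
            if distortion and raw.beta != 0:
                obs_bias = 100 * (corrected.beta - raw.beta) / abs(raw.beta)
                idx_keep = np.flatnonzero(keep)
                biases = np.empty(n_sim)
                for s in range(n_sim):
                    idx = rng.choice(idx_keep, size=keep.sum(), replace=True)
                    wb = 1 / sy[idx] ** 2
                    theta = np.sum(wb * bx[idx] * by[idx]) / np.sum(wb * bx[idx] ** 2)
                    biases[s] = 100 * (theta - raw.beta) / abs(raw.beta)
                distortion_p = float(np.mean(np.abs(biases) >= abs(obs_bias)))

    return PressoResult(
        global_rss=obs_rss, global_p=global_p, global_p_floor=global_p_floor,
        outliers=outliers, outlier_pvalues=outlier_p,
        raw_estimate=raw, corrected_estimate=corrected,
        distortion_p=distortion_p, n_sim=n_sim, seed=seed,
    )
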