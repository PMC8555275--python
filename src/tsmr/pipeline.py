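"""Full-study orchestration: harmonize, estimate, diagnose, report.

``run_study`` executes the complete analysis grid — four causal estimators
per outcome, heterogeneity and pleiotropy diagnostics, leave-one-out
sensitivity, variance explained and power — and ``write_report`` emits a
machine-readable JSON report plus delimited tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import (
    HeterogeneityResult,
    LeaveOneOutResult,
    cochran_q_i2,
    leave_one_out,
)
from .estimators import MrEstimate, ivw, mr_egger, wald_ratio, weighted_median
from .exceptions import TsmrError
from .harmonization import HarmonizedSet, ProxyMap, harmonize_dataset
from .instrument_metrics import (
    PowerSpec,
    VarianceExplained,
    detectable_beta,
    detectable_or,
    variance_explained,
)
from .presso import PressoResult, presso
from .summary_data import InstrumentSet, OutcomeDataset

#: Bonferroni threshold across the four estimation methods
METHOD_SIGNIFICANCE = 0.05 / 4
SUGGESTIVE_SIGNIFICANCE = 0.05


@dataclass
class RunConfig:
    seed: int = 20210
    n_boot: int = 1000            # weighted-median bootstrap replicates
    n_sim: int = 1000             # MR-PRESSO simulations
    ivw_model: str = "multiplicative_re"
    palindrome_policy: str = "proxy_required"
    exclude: tuple[str, ...] = ()  # rsids removed before every analysis
    target_power: float = 0.80
    alpha: float = 0.05
    r2_formula: str = "f_stat_approx"


@dataclass
class OutcomeReport:
    name: str
    label: str
    binary: bool
    harmonized: HarmonizedSet | None
    estimates: dict[str, MrEstimate] = field(default_factory=dict)
    heterogeneity: HeterogeneityResult | None = None
    presso: PressoResult | None = None
    leave_one_out: LeaveOneOutResult | None = None
    variant_screen: dict[str, dict] | None = None
    detectable_effect: float | None = None
    not_applicable: dict[str, str] = field(default_factory=dict)
    failed: str | None = None

    def significance_calls(self) -> dict[str, str]:
        """'significant' (Bonferroni), 'suggestive', or 'ns' per method."""
        calls = {}
        for name, est in self.estimates.items():
            if est.pvalue < METHOD_SIGNIFICANCE:
                calls[name] = "significant"
            elif est.pvalue < SUGGESTIVE_SIGNIFICANCE:
                calls[name] = "suggestive"
            else:
                calls[name] = "ns"
        return calls


@dataclass
class StudyReport:
    exposure_name: str
    config: RunConfig
    outcomes: dict[str, OutcomeReport]
    variance_explained: VarianceExplained
    k: int


def _variant_screen(h: HarmonizedSet) -> dict[str, dict]:
    """Per-variant outcome association screen at the 0.05/k threshold."""
    threshold = 0.05 / h.k
    screen = {}
    for p in h.retained():
        z = abs(p.beta_y) / p.se_y
        pv = 2 * float(stats.norm.sf(z))
        screen[p.rsid] = {"pvalue": pv, "significant": pv < threshold,
                          "threshold": threshold}
    return screen


def run_study(
    exposure: InstrumentSet,
    outcomes: Mapping[str, OutcomeDataset],
    proxies: ProxyMap | None = None,
    config: RunConfig | None = None,
) -> StudyReport:
    """Run the full methods-by-outcomes grid.

    An outcome that cannot be harmonized or estimated at all is reported as
    failed and the run continues.  Estimators whose preconditions are not
    met on a given outcome (e.g. fewer than 3 variants for the weighted
    median) are recorded as not applicable rather than aborting the run.
    """
    cfg = config or RunConfig()
    if cfg.exclude:
        exposure = exposure.subset(exclude=cfg.exclude)
    ve = variance_explained(exposure, formula=cfg.r2_formula)

    reports: dict[str, OutcomeReport] = {}
    for name, outcome in outcomes.items():
        rep = OutcomeReport(name=name, label=outcome.label,
                            binary=outcome.binary, harmonized=None)
        reports[name] = rep
        try:
            h = harmonize_dataset(exposure, outcome, proxies=proxies,
                                  policy=cfg.palindrome_policy)
        except TsmrError as exc:
            rep.failed = f"harmonization failed: {exc}"
            continue
        rep.harmonized = h
        if h.k < 1:
            rep.failed = "no harmonized variants"
            continue
        rep.variant_screen = _variant_screen(h)

        if h.k == 1:
            rep.estimates["wald_ratio"] = wald_ratio(h.retained()[0], binary=h.binary)
            for m in ("ivw", "weighted_median", "mr_egger", "mr_presso"):
                rep.not_applicable[m] = "single-variant outcome: Wald ratio only"
        else:
            rep.estimates["ivw"] = ivw(h, model=cfg.ivw_model)
            for method, fn, minimum in (
                ("weighted_median",
                 lambda: weighted_median(h, n_boot=cfg.n_boot, seed=cfg.seed), 3),
                ("mr_egger", lambda: mr_egger(h), 3),
            ):
                if h.k < minimum:
                    rep.not_applicable[method] = f"needs >= {minimum} variants"
                else:
                    rep.estimates[method] = fn()
            if h.k >= 4:
                rep.presso = presso(h, n_sim=cfg.n_sim, seed=cfg.seed)
                rep.estimates["mr_presso"] = rep.presso.raw_estimate
            else:
                rep.not_applicable["mr_presso"] = "needs >= 4 variants"
            rep.heterogeneity = cochran_q_i2(h)
            rep.leave_one_out = leave_one_out(h, method="ivw", model=cfg.ivw_model)

        if outcome.n_total:
            spec = PowerSpec(n_total=outcome.n_total, r2=ve.total,
                             alpha=cfg.alpha,
                             case_fraction=outcome.case_fraction)
            rep.detectable_effect = (
                detectable_or(spec, cfg.target_power) if outcome.binary
                else detectable_beta(spec, cfg.target_power)
            )

    return StudyReport(exposure_name=exposure.exposure_name, config=cfg,
                       outcomes=reports, variance_explained=ve, k=len(exposure))


# --------------------------------------------------------------------------
# report serialization


def _estimate_dict(e: MrEstimate) -> dict:
    d = {"method": e.method, "k": e.k, "beta": e.beta, "se": e.se,
         "ci_low": e.ci_low, "ci_high": e.ci_high, "pvalue": e.pvalue,
         "model": e.model}
    if e.binary:
        d["or"] = e.odds_ratio
        d["or_ci_low"], d["or_ci_high"] = e.or_ci
    if e.intercept is not None:
        d["intercept"] = e.intercept
        d["intercept_se"] = e.intercept_se
        d["intercept_ci_low"], d["intercept_ci_high"] = e.intercept_ci
        d["intercept_pvalue"] = e.intercept_pvalue
    return d


def _fmt_effect(e: MrEstimate) -> dict:
    """Human-readable cell: OR (binary) or beta, 2 decimals, p in 2-sig sci."""
    if e.binary:
        lo, hi = e.or_ci
        return {"effect": f"{e.odds_ratio:.2f}", "ci": f"{lo:.2f}-{hi:.2f}",
                "pvalue": f"{e.pvalue:.2E}"}
    return {"effect": f"{e.beta:.3f}",
            "ci": f"[{e.ci_low:.3f}, {e.ci_high:.3f}]",
            "pvalue": f"{e.pvalue:.2E}"}


def report_to_dict(report: StudyReport) -> dict:
    out = {
        "exposure": report.exposure_name,
        "k_instruments": report.k,
        "config": {
            "seed": report.config.seed, "n_boot": report.config.n_boot,
            "n_sim": report.config.n_sim, "ivw_model": report.config.ivw_model,
            "palindrome_policy": report.config.palindrome_policy,
            "exclude": list(report.config.exclude),
            "suggestive_threshold": SUGGESTIVE_SIGNIFICANCE,
            "significant_threshold": METHOD_SIGNIFICANCE,
        },
        "variance_explained": {
            "formula": report.variance_explained.formula,
            "per_variant": report.variance_explained.per_variant,
            "total": report.variance_explained.total,
            "total_percent_rounded": report.variance_explained.total_percent_rounded(),
        },
        "outcomes": {},
    }
    for name, rep in report.outcomes.items():
        o = {"label": rep.label, "binary": rep.binary, "failed": rep.failed,
             "not_applicable": rep.not_applicable}
        if rep.harmonized is not None:
            o["k"] = rep.harmonized.k
            o["harmonization_log"] = rep.harmonized.log
        o["estimates"] = {m: _estimate_dict(e) for m, e in rep.estimates.items()}
        o["significance_calls"] = rep.significance_calls()
        if rep.heterogeneity is not None:
            het = rep.heterogeneity
            o["heterogeneity"] = {"q": het.q, "df": het.df, "pvalue": het.pvalue,
                                  "i2": het.i2, "i2_ci_low": het.i2_ci[0],
                                  "i2_ci_high": het.i2_ci[1]}
        if rep.presso is not None:
            pr = rep.presso
            o["mr_presso"] = {
                "global_rss": pr.global_rss, "global_p": pr.global_p,
                "global_p_floor": pr.global_p_floor, "outliers": pr.outliers,
                "outlier_pvalues": pr.outlier_pvalues,
                "distortion_p": pr.distortion_p, "n_sim": pr.n_sim,
                "corrected": (_estimate_dict(pr.corrected_estimate)
                              if pr.corrected_estimate else None),
            }
        if rep.leave_one_out is not None:
            o["leave_one_out"] = {
                rsid: _estimate_dict(e)
                for rsid, e in rep.leave_one_out.estimates.items()
            }
        if rep.variant_screen is not None:
            o["variant_screen"] = rep.variant_screen
        if rep.detectable_effect is not None:
            key = "detectable_or" if rep.binary else "detectable_beta"
            o[key] = rep.detectable_effect
            o["target_power"] = report.config.target_power
        out["outcomes"][name] = o
    return out


def write_report(report: StudyReport, out_dir: str | Path,
                 formats: set[str] = frozenset({"json", "tsv"})) -> list[Path]:
    """Write the structured report and delimited tables; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "json" in formats:
        p = out_dir / "report.json"
        p.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True))
        written.append(p)

    if "tsv" in formats:
        rows = []
        for name, rep in report.outcomes.items():
            for method, est in rep.estimates.items():
                rows.append({"outcome": name, "method": method,
                             **_fmt_effect(est), "k": est.k,
                             "call": rep.significance_calls()[method]})
        p = out_dir / "estimates.tsv"
        pd.DataFrame(rows, columns=["outcome", "method", "effect", "ci",
                                    "pvalue", "k", "call"]).to_csv(
            p, sep="\t", index=False)
        written.append(p)

        het_rows = []
        for name, rep in report.outcomes.items():
            row = {"outcome": name}
            eg = rep.estimates.get("mr_egger")
            if eg is not None:
                row.update(egger_intercept=f"{eg.intercept:.3f}",
                           egger_intercept_p=f"{eg.intercept_pvalue:.3f}")
            if rep.presso is not None:
                row["presso_global_p"] = (
                    f"<{1 / rep.presso.n_sim:g}" if rep.presso.global_p_floor
                    else f"{rep.presso.global_p:.4f}")
                row["presso_outliers"] = ",".join(rep.presso.outliers) or "-"
            if rep.heterogeneity is not None:
                het = rep.heterogeneity
                row.update(i2=f"{het.i2:.1f}%", q=f"{het.q:.3f}",
                           q_pvalue=f"{het.pvalue:.4f}")
            het_rows.append(row)
        p = out_dir / "diagnostics.tsv"
        pd.DataFrame(het_rows).to_csv(p, sep="\t", index=False)
        written.append(p)

        for name, rep in report.outcomes.items():
            if rep.leave_one_out is not None:
                p = out_dir / f"leave_one_out_{name}.tsv"
                rep.leave_one_out.to_frame().to_csv(p, sep="\t", index=False,
                                                    float_format="%.6g")
                written.append(p)
            if rep.harmonized is not None:
                p = out_dir / f"harmonization_{name}.tsv"
                pd.DataFrame(rep.harmonized.log).to_csv(p, sep="\t", index=False)
                written.append(p)
    return written
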