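"""Allele harmonization of outcome records against exposure instruments.

Two-sample MR requires the variant-outcome effect to be expressed for the
same allele as the variant-exposure effect (here, the exposure-raising
allele).  Non-palindromic variants can always be aligned by comparing allele
labels, flipping the outcome sign when the alleles are swapped.  Palindromic
variants (A/T or C/G) are strand-ambiguous: allele labels cannot distinguish
a swap from a strand difference.  The default policy replaces every
palindromic instrument by a high-LD proxy measured in the outcome GWAS,
keeping the exposure effect of the original instrument — the procedure used
for rs56738967 -> rs17689159 in the packaged study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, UnresolvedPalindromeError
from .summary_data import InstrumentSet, OutcomeDataset, VariantAssociation

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: statuses a variant can end harmonization with
STATUSES = ("direct", "flipped", "proxied", "dropped")

#: |eaf - 0.5| below which a palindromic variant counts as frequency-ambiguous
DEFAULT_AMBIGUITY_WINDOW = 0.08

#: minimum proxy r2 accepted for substitution
DEFAULT_MIN_PROXY_R2 = 0.8


def classify_palindromic(
    effect_allele: str,
    other_allele: str,
    eaf: float | None = None,
    ambiguity_window: float = DEFAULT_AMBIGUITY_WINDOW,
) -> tuple[bool, bool]:
    """Is an allele pair palindromic, and is it frequency-ambiguous?

    A pair is palindromic when it reads the same on both strands ({A,T} or
    {C,G}).  Ambiguity means allele frequency cannot resolve the strand:
    the variant is palindromic and either ``eaf`` is missing or it lies
    within ``ambiguity_window`` of 0.5.
    """
    pal = _COMPLEMENT[effect_allele] == other_allele
    if not pal:
        return False, False
    ambiguous = eaf is None or abs(eaf - 0.5) < ambiguity_window
    return True, ambiguous


@dataclass(frozen=True)
class HarmonizedPair:
    """One instrument's exposure and outcome effects on a common allele."""

    rsid: str
    beta_x: float
    se_x: float
    beta_y: float | None
    se_y: float | None
    status: str
    proxy_rsid: str | None = None
    reason: str | None = None

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status != "dropped":
            if not (self.se_x > 0 and self.se_y > 0):
                raise ValueError(f"{self.rsid}: SEs must be positive")
            if not (self.beta_x > 0):
                raise ValueError(
                    f"{self.rsid}: exposure beta must be positive "
                    "(exposure-raising orientation)"
                )


@dataclass
class ProxyMap:
    """LD proxies for instruments that cannot be used directly."""

    entries: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path, delimiter: str = "\t") -> "ProxyMap":
        df = pd.read_csv(path, sep=delimiter)
        required = {"target_rsid", "proxy_rsid", "r2", "d_prime", "target_ea", "proxy_ea"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"{path}: proxy map missing columns {sorted(missing)}")
        pm = cls()
        for row in df.itertuples(index=False):
            pm.add(row.target_rsid, row.proxy_rsid, row.r2, row.d_prime,
                   row.target_ea, row.proxy_ea)
        return pm

    def add(self, target_rsid, proxy_rsid, r2, d_prime, target_ea, proxy_ea):
        r2, d_prime = float(r2), float(d_prime)
        if not (0 <= r2 <= 1 and 0 <= d_prime <= 1):
            raise ValueError(f"{target_rsid}: r2 and D' must lie in [0, 1]")
        self.entries[str(target_rsid)] = {
            "proxy_rsid": str(proxy_rsid),
            "r2": r2,
            "d_prime": d_prime,
            "target_ea": str(target_ea).upper(),
            "proxy_ea": str(proxy_ea).upper(),
        }

    def get(self, rsid: str) -> dict | None:
        return self.entries.get(rsid)


@dataclass
class HarmonizedSet:
    """All instruments of one exposure-outcome analysis after harmonization."""

    exposure_name: str
    outcome_name: str
    pairs: list[HarmonizedPair]
    binary: bool = False
    log: list[dict] = field(default_factory=list)

    def retained(self) -> list[HarmonizedPair]:
        return [p for p in self.pairs if p.status != "dropped"]

    @property
    def k(self) -> int:
        return len(self.retained())

    def arrays(self):
        """(beta_x, se_x, beta_y, se_y) for retained pairs, in order."""
        r = self.retained()
        return (
            np.array([p.beta_x for p in r]),
            np.array([p.se_x for p in r]),
            np.array([p.beta_y for p in r]),
            np.array([p.se_y for p in r]),
        )

    @property
    def rsids(self) -> list[str]:
        return [p.rsid for p in self.retained()]

    def subset(self, exclude: Iterable[str]) -> "HarmonizedSet":
        exclude = set(exclude)
        return HarmonizedSet(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            pairs=[p for p in self.pairs if p.rsid not in exclude],
            binary=self.binary,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rsid": p.rsid, "beta_x": p.beta_x, "se_x": p.se_x,
                    "beta_y": p.beta_y, "se_y": p.se_y, "status": p.status,
                    "proxy_rsid": p.proxy_rsid, "reason": p.reason,
                }
                for p in self.pairs
            ]
        )


def harmonize_pair(
    exposure: VariantAssociation, outcome: VariantAssociation
) -> HarmonizedPair:
    """Align one outcome record to the exposure's effect allele.

    Assumes both records are reported on the same strand (palindromic
    variants must be resolved upstream).  Matching allele labels copy the
    outcome effect; swapped labels negate it; anything else is irreconcilable
    and the pair is dropped with a recorded reason.
    """
    if exposure.rsid != outcome.rsid and outcome.proxy_for != exposure.rsid:
        raise ValueError(f"rsid mismatch: {exposure.rsid} vs {outcome.rsid}")
    ea, oa = exposure.effect_allele, exposure.other_allele
    if (outcome.effect_allele, outcome.other_allele) == (ea, oa):
        return HarmonizedPair(
            rsid=exposure.rsid, beta_x=exposure.beta, se_x=exposure.se,
            beta_y=outcome.beta, se_y=outcome.se, status="direct",
        )
    if (outcome.effect_allele, outcome.other_allele) == (oa, ea):
        return HarmonizedPair(
            rsid=exposure.rsid, beta_x=exposure.beta, se_x=exposure.se,
            beta_y=-outcome.beta, se_y=outcome.se, status="flipped",
        )
    return HarmonizedPair(
        rsid=exposure.rsid, beta_x=exposure.beta, se_x=exposure.se,
        beta_y=None, se_y=None, status="dropped",
        reason=f"irreconcilable alleles {outcome.effect_allele}/{outcome.other_allele} "
               f"vs {ea}/{oa}",
    )


def _proxy_pair(
    instrument: VariantAssociation,
    entry: dict,
    outcome: OutcomeDataset,
    min_r2: float,
) -> HarmonizedPair:
    """Substitute an instrument by its LD proxy measured in the outcome GWAS.

    The exposure effect of the original instrument is retained; the outcome
    effect is taken at the proxy, sign-aligned through the allele
    correspondence of the proxy map (target EA corresponds to proxy EA).
    """
    proxy_rsid = entry["proxy_rsid"]
    rec = outcome.get(proxy_rsid)
    if rec is None:
        return HarmonizedPair(
            rsid=instrument.rsid, beta_x=instrument.beta, se_x=instrument.se,
            beta_y=None, se_y=None, status="dropped",
            reason=f"proxy {proxy_rsid} absent from outcome table",
        )
    if entry["r2"] < min_r2:
        return HarmonizedPair(
            rsid=instrument.rsid, beta_x=instrument.beta, se_x=instrument.se,
            beta_y=None, se_y=None, status="dropped",
            reason=f"proxy {proxy_rsid} r2={entry['r2']:g} below minimum {min_r2:g}",
        )
    # allele correspondence: the exposure effect allele maps to entry['proxy_ea']
    corresponding_ea = entry["proxy_ea"] if instrument.effect_allele == entry["target_ea"] else None
    if corresponding_ea is None:
        # instrument oriented to the other target allele -> proxy's other allele
        corresponding_ea = rec.other_allele if rec.effect_allele == entry["proxy_ea"] else rec.effect_allele
    if rec.effect_allele == corresponding_ea:
        beta_y = rec.beta
    elif rec.other_allele == corresponding_ea:
        beta_y = -rec.beta
    else:
        return HarmonizedPair(
            rsid=instrument.rsid, beta_x=instrument.beta, se_x=instrument.se,
            beta_y=None, se_y=None, status="dropped",
            reason=f"proxy {proxy_rsid} alleles do not match the proxy map",
        )
    return HarmonizedPair(
        rsid=instrument.rsid, beta_x=instrument.beta, se_x=instrument.se,
        beta_y=beta_y, se_y=rec.se, status="proxied", proxy_rsid=proxy_rsid,
    )


def harmonize_dataset(
    instruments: InstrumentSet,
    outcome: OutcomeDataset | Sequence[VariantAssociation],
    proxies: ProxyMap | None = None,
    policy: str = "proxy_required",
    ambiguity_window: float = DEFAULT_AMBIGUITY_WINDOW,
    min_proxy_r2: float = DEFAULT_MIN_PROXY_R2,
) -> HarmonizedSet:
    """Harmonize a whole outcome table against an instrument set.

    Every instrument leaves with exactly one terminal status (direct,
    flipped, proxied or dropped); nothing is silently lost.

    Palindrome policies:

    ``proxy_required``
        Every palindromic instrument is substituted by its proxy from
        ``proxies`` (the study's procedure); a palindromic instrument with
        no usable proxy raises :class:`UnresolvedPalindromeError`.
    ``infer_by_frequency``
        Palindromic but frequency-unambiguous variants (|eaf - 0.5| >=
        ``ambiguity_window`` in both GWAS) are aligned by frequency;
        ambiguous ones use a proxy when available, else are dropped.
    ``drop``
        All palindromic instruments are dropped.
    """
    if policy not in ("proxy_required", "infer_by_frequency", "drop"):
        raise ConfigurationError(f"unknown palindrome policy {policy!r}")
    if not isinstance(outcome, OutcomeDataset):
        outcome = OutcomeDataset(name="outcome", label="outcome",
                                 records=list(outcome), binary=False)

    pairs: list[HarmonizedPair] = []
    log: list[dict] = []
    unresolved: list[str] = []
    for inst in instruments:
        pal, ambiguous = classify_palindromic(
            inst.effect_allele, inst.other_allele, inst.eaf, ambiguity_window
        )
        entry = proxies.get(inst.rsid) if proxies is not None else None
        if pal and policy == "drop":
            pair = HarmonizedPair(
                rsid=inst.rsid, beta_x=inst.beta, se_x=inst.se,
                beta_y=None, se_y=None, status="dropped",
                reason="palindromic variant under policy 'drop'",
            )
        elif pal and policy == "proxy_required":
            if entry is None:
                unresolved.append(inst.rsid)
                continue
            pair = _proxy_pair(inst, entry, outcome, min_proxy_r2)
        elif pal and policy == "infer_by_frequency":
            rec = outcome.get(inst.rsid)
            if not ambiguous and rec is not None and rec.eaf is not None:
                # align by frequency: same minor allele side -> same strand sense
                same_side = (inst.eaf < 0.5) == (rec.eaf < 0.5)
                beta_y = rec.beta if same_side else -rec.beta
                pair = HarmonizedPair(
                    rsid=inst.rsid, beta_x=inst.beta, se_x=inst.se,
                    beta_y=beta_y, se_y=rec.se,
                    status="direct" if same_side else "flipped",
                )
            elif entry is not None:
                pair = _proxy_pair(inst, entry, outcome, min_proxy_r2)
            else:
                pair = HarmonizedPair(
                    rsid=inst.rsid, beta_x=inst.beta, se_x=inst.se,
                    beta_y=None, se_y=None, status="dropped",
                    reason="frequency-ambiguous palindromic variant without proxy",
                )
        else:
            rec = outcome.get(inst.rsid)
            if rec is None:
                pair = HarmonizedPair(
                    rsid=inst.rsid, beta_x=inst.beta, se_x=inst.se,
                    beta_y=None, se_y=None, status="dropped",
                    reason="absent from outcome table",
                )
            else:
                pair = harmonize_pair(inst, rec)
        pairs.append(pair)
        log.append({
            "rsid": inst.rsid, "palindromic": pal, "ambiguous": pal and ambiguous,
            "status": pair.status, "proxy_rsid": pair.proxy_rsid,
            "reason": pair.reason,
        })
    if unresolved:
        raise UnresolvedPalindromeError(unresolved)
    assert len(pairs) == len(instruments)
    return HarmonizedSet(
        exposure_name=instruments.exposure_name,
        outcome_name=outcome.name,
        pairs=pairs,
        binary=outcome.binary,
        log=log,
    )
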