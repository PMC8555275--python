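"""Variant-level GWAS summary statistics: data model, I/O and instrument selection.

A :class:`VariantAssociation` is one variant's association record in one GWAS.
An :class:`InstrumentSet` is an ordered collection of such records oriented to
the exposure-raising allele, ready to enter a Mendelian randomization analysis.

The packaged study fixtures hold the plasma vitamin C instrument table
(11 genome-wide significant variants, N = 52,018) and the matching outcome
summary statistics for five Alzheimer's disease / cognition GWAS datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyInstrumentError,
    RowParseError,
    UnknownFixtureError,
)

VALID_BASES = frozenset("ACGT")

#: canonical column order for reading and writing summary tables
REQUIRED_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se")
OPTIONAL_COLUMNS = ("chrom", "pos", "eaf", "pvalue", "n", "gene", "proxy_for")

FIXTURE_KEYS = (
    "vitamin_c_exposure",
    "igap",
    "ukb_proxy",
    "ukb_maternal",
    "ukb_paternal",
    "cognitive",
)


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary-statistic record in one GWAS."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None
    gene: str | None = None
    proxy_for: str | None = None

    def __post_init__(self):
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValueError(
                f"{self.rsid}: alleles must be single bases in A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not (self.se > 0):
            raise ValueError(f"{self.rsid}: se must be strictly positive, got {self.se}")
        if not (self.beta == self.beta and abs(self.beta) != float("inf")):
            raise ValueError(f"{self.rsid}: beta must be finite")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.rsid}: eaf must lie in (0, 1), got {self.eaf}")
        if self.pvalue is not None and not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.rsid}: pvalue must lie in (0, 1], got {self.pvalue}")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, if the effect-allele frequency is known."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1 - self.eaf)

    def flipped(self) -> "VariantAssociation":
        """The same association expressed on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1 - self.eaf,
        )


@dataclass
class InstrumentSet:
    """Exposure instruments oriented to the exposure-raising allele."""

    exposure_name: str
    records: list[VariantAssociation]
    sd_unit: str | None = None

    def __post_init__(self):
        rsids = [r.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValueError(f"duplicate instrument rsids: {', '.join(dupes)}")
        if any(r.beta <= 0 for r in self.records):
            bad = [r.rsid for r in self.records if r.beta <= 0]
            raise ValueError(
                "instrument betas must be positive after orientation to the "
                "exposure-raising allele; offending: " + ", ".join(bad)
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def get(self, rsid: str) -> VariantAssociation:
        for r in self.records:
            if r.rsid == rsid:
                return r
        raise KeyError(rsid)

    def subset(self, keep: Iterable[str] | None = None, exclude: Iterable[str] = ()) -> "InstrumentSet":
        """A new set restricted to ``keep`` (all by default) minus ``exclude``."""
        keep = set(self.rsids if keep is None else keep) - set(exclude)
        return InstrumentSet(
            exposure_name=self.exposure_name,
            records=[r for r in self.records if r.rsid in keep],
            sd_unit=self.sd_unit,
        )


@dataclass
class OutcomeDataset:
    """Outcome-GWAS association records for the instrument variants."""

    name: str
    label: str
    records: list[VariantAssociation]
    binary: bool
    n_total: int | None = None
    n_cases: int | None = None

    @property
    def case_fraction(self) -> float | None:
        if self.n_cases is None or not self.n_total:
            return None
        return self.n_cases / self.n_total

    def get(self, rsid: str) -> VariantAssociation | None:
        for r in self.records:
            if r.rsid == rsid:
                return r
        return None


def _coerce(value, kind, column, line):
    if value is None or (isinstance(value, str) and value.strip() == "") or value != value:
        return None
    try:
        if kind is int:
            return int(float(value))
        return kind(value)
    except (TypeError, ValueError) as exc:
        raise RowParseError(f"column '{column}': unparseable value {value!r}", line) from exc


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    on_error: str = "raise",
) -> list[VariantAssociation] | tuple[list[VariantAssociation], list[RowParseError]]:
    """Read a delimited summary-statistic table into association records.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from canonical field name (``rsid``, ``beta``, ...) to the
        column name used in the file.  Columns are never sniffed; fields not
        mentioned fall back to their canonical names.
    delimiter
        Field separator; inferred from the file extension when ``None``
        (``.csv`` -> comma, otherwise tab).
    on_error
        ``"raise"`` aborts on the first bad row; ``"collect"`` returns a
        ``(records, errors)`` pair so bad rows are reported, not dropped.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=delimiter, dtype=str)

    colmap = {name: name for name in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    if column_map:
        colmap.update(column_map)
    missing = [c for c in REQUIRED_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: required column(s) not resolvable: "
            + ", ".join(f"{c} (mapped to {colmap[c]!r})" for c in missing)
        )

    records: list[VariantAssociation] = []
    errors: list[RowParseError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        values = {c: (row[df.columns.get_loc(colmap[c])] if colmap[c] in df.columns else None)
                  for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
        try:
            rec = VariantAssociation(
                rsid=str(values["rsid"]).strip(),
                effect_allele=str(values["effect_allele"]).strip().upper(),
                other_allele=str(values["other_allele"]).strip().upper(),
                beta=_coerce(values["beta"], float, "beta", line),
                se=_coerce(values["se"], float, "se", line),
                chrom=None if values["chrom"] is None or values["chrom"] != values["chrom"] else str(values["chrom"]).strip(),
                pos=_coerce(values["pos"], int, "pos", line),
                eaf=_coerce(values["eaf"], float, "eaf", line),
                pvalue=_coerce(values["pvalue"], float, "pvalue", line),
                n=_coerce(values["n"], int, "n", line),
                gene=None if values["gene"] is None or values["gene"] != values["gene"] else str(values["gene"]).strip(),
                proxy_for=None if values["proxy_for"] is None or values["proxy_for"] != values["proxy_for"] else str(values["proxy_for"]).strip() or None,
            )
        except RowParseError as exc:
            if on_error == "raise":
                raise
            errors.append(exc)
            continue
        except (ValueError, TypeError) as exc:
            err = RowParseError(str(exc), line)
            if on_error == "raise":
                raise err from exc
            errors.append(err)
            continue
        records.append(rec)
    if on_error == "collect":
        return records, errors
    return records


def write_summary_table(
    records: Sequence[VariantAssociation], path: str | Path, delimiter: str | None = None
) -> None:
    """Write records as a delimited table that :func:`read_summary_table` round-trips."""
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    columns = REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in columns})
    df = pd.DataFrame(rows, columns=list(columns))
    df.to_csv(path, sep=delimiter, index=False)


def _data_path(filename: str):
    return resources.files("tsmr.data").joinpath(filename)


def load_study_fixture(name: str) -> InstrumentSet | OutcomeDataset:
    """Load one of the packaged study tables by key.

    ``vitamin_c_exposure`` returns the 11-variant plasma vitamin C
    :class:`InstrumentSet`; the outcome keys (``igap``, ``ukb_proxy``,
    ``ukb_maternal``, ``ukb_paternal``, ``cognitive``) return an
    :class:`OutcomeDataset` whose palindromic instrument rs56738967 is carried
    at its measured proxy rs17689159 (``proxy_for`` annotation).
    """
    if name == "vitamin_c_exposure":
        with resources.as_file(_data_path("vitamin_c_exposure.tsv")) as p:
            records = read_summary_table(p)
        return InstrumentSet(
            exposure_name="plasma vitamin C",
            sd_unit="20.2 μmol/l per SD",
            records=records,
        )
    meta = json.loads(_data_path("outcomes_meta.json").read_text())
    if name not in meta:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_KEYS)}"
        )
    entry = meta[name]
    with resources.as_file(_data_path(entry["file"])) as p:
        records = read_summary_table(p)
    return OutcomeDataset(
        name=name,
        label=entry["label"],
        records=records,
        binary=entry["binary"],
        n_total=entry["n_total"],
        n_cases=entry["n_cases"],
    )


def load_proxy_map():
    """The packaged proxy table (rs56738967 -> rs17689159, r2 = D' = 1)."""
    from .harmonization import ProxyMap

    with resources.as_file(_data_path("proxy_map.tsv")) as p:
        return ProxyMap.from_file(p)


def load_study() -> tuple[InstrumentSet, dict[str, OutcomeDataset], "ProxyMap"]:
    """Exposure instruments, all five outcome datasets, and the proxy map."""
    exposure = load_study_fixture("vitamin_c_exposure")
    outcomes = {k: load_study_fixture(k) for k in FIXTURE_KEYS if k != "vitamin_c_exposure"}
    return exposure, outcomes, load_proxy_map()


def _independent(records: list[VariantAssociation], ld_table, r2_cutoff, window) -> list[VariantAssociation]:
    """Greedy pruning: keep the smaller-p member of every dependent pair."""
    ld = {}
    if ld_table is not None:
        if isinstance(ld_table, pd.DataFrame):
            it = ld_table[["rsid1", "rsid2", "r2"]].itertuples(index=False)
        else:
            it = ld_table
        for a, b, r2 in it:
            ld[frozenset((a, b))] = float(r2)

    def dependent(a: VariantAssociation, b: VariantAssociation) -> bool:
        if ld:
            return ld.get(frozenset((a.rsid, b.rsid)), 0.0) >= r2_cutoff
        if a.chrom is None or b.chrom is None or a.pos is None or b.pos is None:
            return False
        return a.chrom == b.chrom and abs(a.pos - b.pos) < window

    ranked = sorted(records, key=lambda r: (r.pvalue if r.pvalue is not None else 1.0))
    kept: list[VariantAssociation] = []
    for rec in ranked:
        if all(not dependent(rec, k) for k in kept):
            kept.append(rec)
    order = {r.rsid: i for i, r in enumerate(records)}
    return sorted(kept, key=lambda r: order[r.rsid])


def select_instruments(
    assocs: Iterable[VariantAssociation],
    p_threshold: float = 5e-8,
    ld_table=None,
    r2_cutoff: float = 0.01,
    distance_window: float = 10e6,
    exposure_name: str = "exposure",
    sd_unit: str | None = None,
) -> InstrumentSet:
    """Select genome-wide-significant, mutually independent instruments.

    Variants must carry a p-value below ``p_threshold`` (genome-wide
    significance, 5e-8, by default).  Independence uses a pairwise LD table
    (``rsid1, rsid2, r2`` with ``r2_cutoff``) when supplied, otherwise a
    same-chromosome distance window (10 Mb).  Among dependent pairs the
    variant with the smaller p-value is kept.  Exposure effects are
    re-oriented so every retained beta is positive (allele flip).
    """
    candidates = [a for a in assocs if a.pvalue is not None and a.pvalue < p_threshold]
    kept = _independent(candidates, ld_table, r2_cutoff, distance_window)
    oriented = [r.flipped() if r.beta < 0 else r for r in kept]
    oriented = [r for r in oriented if r.beta > 0]
    if not oriented:
        raise EmptyInstrumentError(
            f"no variant passed p < {p_threshold:g} with a nonzero effect"
        )
    return InstrumentSet(exposure_name=exposure_name, records=oriented, sd_unit=sd_unit)
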