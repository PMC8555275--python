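"""Data model, summary-table I/O, fixtures and instrument selection."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tsmr
from tsmr.exceptions import (
    ConfigurationError,
    EmptyInstrumentError,
    RowParseError,
    UnknownFixtureError,
)
from tsmr.summary_data import VariantAssociation, read_summary_table, write_summary_table


def make_variant(**kw):
    base = dict(rsid="rs1", effect_allele="A", other_allele="G",
                beta=0.1, se=0.01)
    base.update(kw)
    return VariantAssociation(**base)


class TestVariantAssociation:
    @pytest.mark.parametrize("kw", [
        dict(se=0.0),
        dict(se=-1.0),
        dict(beta=float("nan")),
        dict(beta=float("inf")),
        dict(effect_allele="A", other_allele="A"),
        dict(effect_allele="N"),
        dict(eaf=0.0),
        dict(eaf=1.0),
        dict(pvalue=0.0),
    ])
    def test_invariants_rejected(self, kw):
        with pytest.raises(ValueError):
            make_variant(**kw)

    def test_flip_roundtrip(self):
        v = make_variant(eaf=0.3, beta=-0.2)
        back = v.flipped().flipped()
        assert back.beta == v.beta
        assert (back.effect_allele, back.other_allele) == ("A", "G")
        assert back.eaf == pytest.approx(v.eaf, abs=1e-15)
        f = v.flipped()
        assert f.beta == 0.2 and f.eaf == 0.7
        assert (f.effect_allele, f.other_allele) == ("G", "A")

    def test_maf(self):
        assert make_variant(eaf=0.968).maf == pytest.approx(0.032)
        assert make_variant().maf is None


class TestReadWrite:
    def test_fixture_table_values(self, exposure):
        """First packaged exposure row carries the printed values."""
        assert len(exposure) == 11
        first = exposure.records[0]
        assert first.rsid == "rs6693447"
        assert first.beta == 0.039 and first.se == 0.006
        assert (first.chrom, first.pos) == ("1", 2330190)

    def test_header_only_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("rsid\teffect_allele\tother_allele\tbeta\tse\n")
        assert read_summary_table(p) == []

    def test_zero_se_row_reported_with_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("rsid\teffect_allele\tother_allele\tbeta\tse\n"
                     "rs1\tA\tG\t0.1\t0.01\n"
                     "rs2\tA\tG\t0.1\t0\n")
        with pytest.raises(RowParseError, match="line 3"):
            read_summary_table(p)
        records, errors = read_summary_table(p, on_error="collect")
        assert [r.rsid for r in records] == ["rs1"]
        assert len(errors) == 1 and errors[0].line == 3

    def test_unparseable_numeric_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("rsid\teffect_allele\tother_allele\tbeta\tse\n"
                     "rs1\tA\tG\tnot_a_number\t0.01\n")
        with pytest.raises(RowParseError, match="beta"):
            read_summary_table(p)

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("rsid\tea\toa\tbeta\n" "rs1\tA\tG\t0.1\n")
        with pytest.raises(ConfigurationError, match="se"):
            read_summary_table(p, column_map={"effect_allele": "ea",
                                              "other_allele": "oa"})

    def test_column_map_resolves_renamed_columns(self, tmp_path):
        p = tmp_path / "renamed.csv"
        p.write_text("SNP,EA,NEA,b,stderr\nrs1,A,G,0.1,0.01\n")
        (rec,) = read_summary_table(p, column_map={
            "rsid": "SNP", "effect_allele": "EA", "other_allele": "NEA",
            "beta": "b", "se": "stderr"})
        assert rec.rsid == "rs1" and rec.beta == 0.1

    def test_roundtrip_bit_identical(self, tmp_path, exposure, outcomes):
        """read -> write -> read preserves every field of every fixture."""
        tables = [exposure.records] + [o.records for o in outcomes.values()]
        for i, records in enumerate(tables):
            p = tmp_path / f"t{i}.tsv"
            write_summary_table(records, p)
            assert read_summary_table(p) == records


class TestFixtures:
    def test_all_outcome_fixtures_load(self, outcomes):
        assert set(outcomes) == {"igap", "ukb_proxy", "ukb_maternal",
                                 "ukb_paternal", "cognitive"}
        for out in outcomes.values():
            assert len(out.records) == 11

    @pytest.mark.parametrize("name, rsid, beta, se", [
        ("vitamin_c_exposure", "rs33972313", 0.36, 0.018),
        ("ukb_maternal", "rs33972313", -0.05, 0.012),
        ("igap", "rs33972313", 0.0144, 0.0428),
        ("igap", "rs6693447", -0.0025, 0.0148),
        ("ukb_proxy", "rs6693447", 0.01, 0.01),
    ])
    def test_printed_values(self, name, rsid, beta, se):
        ds = tsmr.load_study_fixture(name)
        rec = ds.get(rsid)
        assert rec.beta == beta and rec.se == se

    def test_proxy_annotation_present(self, outcomes):
        for out in outcomes.values():
            rec = out.get("rs17689159")
            assert rec is not None and rec.proxy_for == "rs56738967"

    def test_unknown_key(self):
        with pytest.raises(UnknownFixtureError):
            tsmr.load_study_fixture("nope")

    def test_binary_flags_and_sizes(self, outcomes):
        assert outcomes["igap"].binary and outcomes["igap"].n_total == 63926
        assert outcomes["igap"].n_cases == 21982
        assert not outcomes["cognitive"].binary
        assert outcomes["cognitive"].n_total == 257841


class TestSelectInstruments:
    def test_fixture_all_retained_at_gws(self, exposure):
        """All 11 variants are genome-wide significant and mutually
        independent (published pairwise r2 < 0.01 for both same-chromosome
        pairs), so selection keeps every one."""
        ld = [("rs33972313", "rs10051765", 0.005),
              ("rs117885456", "rs2559850", 0.005)]
        sel = tsmr.select_instruments(exposure.records, p_threshold=5e-8,
                                      ld_table=ld)
        assert sel.rsids == exposure.rsids

    def test_fixture_distance_fallback_is_conservative(self, exposure):
        """Without LD information the 10 Mb same-chromosome window prunes
        the chr12 pair (5.8 Mb apart), keeping the smaller-p member."""
        sel = tsmr.select_instruments(exposure.records, p_threshold=5e-8)
        assert "rs2559850" in sel.rsids        # p = 6.3e-20
        assert "rs117885456" not in sel.rsids  # p = 1.7e-11, pruned
        assert len(sel) == 10

    def test_threshold_excludes(self):
        weak = make_variant(rsid="rs_weak", pvalue=1.0e-7, chrom="1", pos=1)
        strong = make_variant(rsid="rs_strong", pvalue=1.0e-9, chrom="2", pos=1)
        sel = tsmr.select_instruments([weak, strong])
        assert sel.rsids == ["rs_strong"]

    def test_ld_table_keeps_smaller_p(self):
        a = make_variant(rsid="rsA", pvalue=1e-20, chrom="1", pos=100_000)
        b = make_variant(rsid="rsB", pvalue=1e-9, chrom="1", pos=110_000)
        ld = [("rsA", "rsB", 0.5)]
        sel = tsmr.select_instruments([a, b], ld_table=ld, r2_cutoff=0.01)
        assert sel.rsids == ["rsA"]
        # below the cutoff both survive
        sel2 = tsmr.select_instruments([a, b], ld_table=[("rsA", "rsB", 0.005)])
        assert sel2.rsids == ["rsA", "rsB"]

    def test_distance_window_default(self):
        a = make_variant(rsid="rsA", pvalue=1e-20, chrom="1", pos=1_000_000)
        b = make_variant(rsid="rsB", pvalue=1e-9, chrom="1", pos=2_000_000)
        c = make_variant(rsid="rsC", pvalue=1e-9, chrom="1", pos=50_000_000)
        sel = tsmr.select_instruments([a, b, c])
        assert sel.rsids == ["rsA", "rsC"]

    def test_negative_beta_reoriented(self):
        v = make_variant(beta=-0.2, pvalue=1e-9, eaf=0.3)
        sel = tsmr.select_instruments([v])
        assert sel.records[0].beta == 0.2
        assert sel.records[0].effect_allele == "G"

    def test_empty_selection_raises(self):
        v = make_variant(pvalue=0.5)
        with pytest.raises(EmptyInstrumentError):
            tsmr.select_instruments([v])


@given(beta=st.floats(-1, 1, exclude_min=True, exclude_max=True).filter(lambda b: b != 0),
       eaf=st.floats(0.01, 0.99))
@settings(max_examples=50, deadline=None)
def test_orientation_involution(beta, eaf):
    """Flipping alleles and negating beta twice restores the record
    (allele-frequency complementation up to float roundoff)."""
    v = make_variant(beta=beta, eaf=eaf)
    back = v.flipped().flipped()
    assert back.beta == v.beta
    assert (back.effect_allele, back.other_allele) == \
        (v.effect_allele, v.other_allele)
    assert back.eaf == pytest.approx(v.eaf, abs=1e-12)
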