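"""Wald ratio, IVW, weighted median and MR-Egger.

Closed-form oracles (two-point weighted least squares, symmetric medians,
noise-free regression lines) are frozen alongside values recomputed from the
packaged study tables.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tsmr
from tsmr.estimators import _weighted_median
from tsmr.exceptions import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientVariantsError,
)
from tsmr.harmonization import HarmonizedPair, HarmonizedSet


def make_set(bx, by, sy, sx=None, binary=False):
    sx = sx if sx is not None else [0.01] * len(bx)
    pairs = [HarmonizedPair(rsid=f"rs{i}", beta_x=x, se_x=s,
                            beta_y=y, se_y=e, status="direct")
             for i, (x, s, y, e) in enumerate(zip(bx, sx, by, sy))]
    return HarmonizedSet(exposure_name="x", outcome_name="y",
                         pairs=pairs, binary=binary)


class TestWaldRatio:
    def test_table_values(self, harmonized):
        # rs33972313, maternal: -0.05 / 0.36
        (pair,) = [p for p in harmonized["ukb_maternal"].retained()
                   if p.rsid == "rs33972313"]
        est = tsmr.wald_ratio(pair, binary=True)
        assert est.beta == pytest.approx(-0.1389, abs=5e-5)
        assert est.odds_ratio == pytest.approx(0.870, abs=5e-4)
        assert est.se == pytest.approx(0.012 / 0.36, rel=1e-12)

    def test_null_effect(self):
        pair = HarmonizedPair(rsid="rs1", beta_x=0.5, se_x=0.01,
                              beta_y=0.0, se_y=0.1, status="direct")
        est = tsmr.wald_ratio(pair, binary=True)
        assert est.beta == 0.0 and est.odds_ratio == 1.0

    def test_zero_exposure_beta_degenerate(self):
        pair = HarmonizedPair(rsid="rs1", beta_x=0.5, se_x=0.01,
                              beta_y=0.1, se_y=0.1, status="direct")
        object.__setattr__(pair, "beta_x", 0.0)  # unreachable via constructors
        with pytest.raises(DegenerateInstrumentError):
            tsmr.wald_ratio(pair)

    def test_second_order_se_larger(self):
        pair = HarmonizedPair(rsid="rs1", beta_x=0.1, se_x=0.05,
                              beta_y=0.05, se_y=0.02, status="direct")
        assert tsmr.wald_ratio(pair, second_order=True).se > tsmr.wald_ratio(pair).se


class TestIvw:
    def test_two_point_closed_form(self):
        """WLS through the origin on two points: beta 0.2, fixed se 0.1789."""
        h = make_set([0.5, 0.25], [0.10, 0.05], [0.1, 0.1])
        est = tsmr.ivw(h, model="fixed")
        assert est.beta == pytest.approx(0.2, rel=1e-12)
        assert est.se == pytest.approx(0.1 / math.sqrt(0.5**2 + 0.25**2), rel=1e-4)
        assert est.se == pytest.approx(0.1789, abs=5e-5)

    def test_single_variant_equals_wald(self, harmonized):
        h = harmonized["igap"]
        one = HarmonizedSet("x", "y", pairs=h.retained()[:1], binary=True)
        est = tsmr.ivw(one)
        wald = tsmr.wald_ratio(h.retained()[0], binary=True)
        assert est.beta == pytest.approx(wald.beta, rel=1e-12)
        assert est.se == pytest.approx(wald.se, rel=1e-12)

    def test_ukb_proxy_or(self, harmonized):
        est = tsmr.ivw(harmonized["ukb_proxy"])
        assert round(est.odds_ratio, 2) == 0.93

    def test_wls_equals_weighted_mean_of_ratios(self, harmonized):
        """Internal oracle: the two IVW formulations agree to 1e-12."""
        for h in harmonized.values():
            bx, _, by, sy = h.arrays()
            ratios = by / bx
            w = bx**2 / sy**2
            oracle = float(np.sum(w * ratios) / np.sum(w))
            assert tsmr.ivw(h).beta == pytest.approx(oracle, abs=1e-12)

    def test_models_share_point_estimate(self, harmonized):
        for h in harmonized.values():
            fixed = tsmr.ivw(h, model="fixed")
            re = tsmr.ivw(h, model="multiplicative_re")
            assert fixed.beta == re.beta
            assert re.se >= fixed.se

    def test_empty_set(self):
        h = HarmonizedSet("x", "y", pairs=[])
        with pytest.raises(tsmr.exceptions.EmptyInstrumentError):
            tsmr.ivw(h)


class TestWeightedMedian:
    def test_symmetric_median(self):
        assert _weighted_median(np.array([1.0, 2.0, 3.0]),
                                np.ones(3)) == pytest.approx(2.0)

    def test_degenerate_distribution(self):
        r = np.full(5, 0.7)
        w = np.array([0.1, 5.0, 2.0, 0.3, 1.0])
        assert _weighted_median(r, w) == pytest.approx(0.7)

    def test_maternal_or(self, harmonized):
        est = tsmr.weighted_median(harmonized["ukb_maternal"], seed=7)
        assert round(est.odds_ratio, 2) == 0.87

    def test_requires_three_variants(self, harmonized):
        h = harmonized["igap"]
        small = HarmonizedSet("x", "y", pairs=h.retained()[:2], binary=True)
        with pytest.raises(InsufficientVariantsError):
            tsmr.weighted_median(small, seed=1)

    def test_seed_mandatory_and_reproducible(self, harmonized):
        h = harmonized["igap"]
        with pytest.raises(ValueError):
            tsmr.weighted_median(h)
        a = tsmr.weighted_median(h, seed=3)
        b = tsmr.weighted_median(h, seed=3)
        assert a == b

    @given(st.lists(st.tuples(st.floats(0.05, 1.0), st.floats(-1.0, 1.0),
                              st.floats(0.01, 0.5)), min_size=3, max_size=12))
    @settings(max_examples=40, deadline=None)
    def test_median_within_ratio_range(self, triples):
        bx = np.array([t[0] for t in triples])
        by = np.array([t[1] for t in triples])
        sy = np.array([t[2] for t in triples])
        ratios = by / bx
        m = _weighted_median(ratios, bx**2 / sy**2)
        assert ratios.min() - 1e-12 <= m <= ratios.max() + 1e-12

    def test_single_dominant_weight(self):
        r = np.array([1.0, 5.0, 9.0])
        w = np.array([0.0, 1.0, 0.0])
        # all weight on one ratio -> that ratio
        assert _weighted_median(r[w > 0], w[w > 0]) == pytest.approx(5.0)


class TestMrEgger:
    def test_noise_free_line(self):
        bx = [0.05, 0.1, 0.2, 0.4]
        by = [0.5 * x for x in bx]
        h = make_set(bx, by, [0.01] * 4)
        est = tsmr.mr_egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-10)

    def test_igap_intercept(self, harmonized):
        est = tsmr.mr_egger(harmonized["igap"])
        assert round(est.intercept, 3) == -0.013
        assert est.intercept_pvalue == pytest.approx(0.116, abs=5e-4)

    def test_maternal_slope_or(self, harmonized):
        est = tsmr.mr_egger(harmonized["ukb_maternal"])
        assert round(est.odds_ratio, 2) == 0.87

    def test_matches_statsmodels_wls(self, harmonized):
        """Independent cross-check of the closed-form fit."""
        import statsmodels.api as sm

        for h in harmonized.values():
            bx, _, by, sy = h.arrays()
            fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
            est = tsmr.mr_egger(h)
            assert est.intercept == pytest.approx(fit.params[0], rel=1e-10)
            assert est.beta == pytest.approx(fit.params[1], rel=1e-10)
            scale = max(1.0, math.sqrt(fit.scale))
            assert est.se == pytest.approx(
                fit.bse[1] / math.sqrt(fit.scale) * scale, rel=1e-8)

    def test_collinear_exposure(self):
        h = make_set([0.1, 0.1, 0.1], [0.05, 0.06, 0.04], [0.01] * 3)
        with pytest.raises(CollinearityError):
            tsmr.mr_egger(h)

    def test_requires_three(self):
        h = make_set([0.1, 0.2], [0.05, 0.06], [0.01] * 2)
        with pytest.raises(InsufficientVariantsError):
            tsmr.mr_egger(h)

    def test_t_reference_widens_ci(self, harmonized):
        n = tsmr.mr_egger(harmonized["igap"], pvalue_dist="normal")
        t = tsmr.mr_egger(harmonized["igap"], pvalue_dist="t")
        assert t.ci_high - t.ci_low > n.ci_high - n.ci_low
        assert t.beta == n.beta


class TestOrScale:
    def test_or_present_iff_binary(self, harmonized):
        binary = tsmr.ivw(harmonized["igap"])
        cont = tsmr.ivw(harmonized["cognitive"])
        assert binary.odds_ratio is not None and binary.or_ci is not None
        assert cont.odds_ratio is None and cont.or_ci is None

    def test_or_equals_exp_beta(self, harmonized):
        est = tsmr.ivw(harmonized["ukb_maternal"])
        assert est.odds_ratio == pytest.approx(math.exp(est.beta), rel=1e-12)
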