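"""Univariable MR estimators against closed forms and independent oracles."""

import numpy as np
import pytest
from scipy import stats

from netmr.gwas_io import HarmonizedSet
from netmr.mr_core import (InsufficientInstrumentsError, UndefinedRatioError,
                           _weighted_median_point, egger, ivw, reverse_mr,
                           simple_median, wald_ratio, weighted_median)
from netmr.synthetic import SimConfig, simulate_chain

from conftest import make_hset


class TestWaldRatio:
    def test_ratio_and_first_order_se(self):
        e = wald_ratio(0.5, 0.01, 0.1, 0.02)
        assert e.beta == pytest.approx(0.2)
        assert e.se == pytest.approx(0.04)

    def test_null_outcome_gives_or_one(self):
        e = wald_ratio(1.0, 0.01, 0.0, 0.02)
        assert e.beta == 0.0 and e.or_ == pytest.approx(1.0)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        h = make_hset([0.5], [0.01], [0.1], [0.02])
        e = ivw(h, "fixed")
        w = wald_ratio(0.5, 0.01, 0.1, 0.02)
        assert e.beta == pytest.approx(w.beta) and e.se == pytest.approx(w.se)

    def test_two_snp_closed_form(self):
        h = make_hset([1, 1], [0.01, 0.01], [0.1, 0.3], [0.1, 0.1])
        e = ivw(h, "fixed")
        assert e.beta == pytest.approx(0.2)
        assert e.se == pytest.approx(0.1 / np.sqrt(2))

    def test_mre_inflates_se_under_heterogeneity_only(self):
        homogeneous = make_hset([1, 1, 1], [0.01] * 3, [0.2, 0.2, 0.2], [0.1] * 3)
        assert ivw(homogeneous, "multiplicative_random").se == \
            pytest.approx(ivw(homogeneous, "fixed").se)
        heterogeneous = make_hset([1, 1, 1], [0.01] * 3, [-0.5, 0.2, 0.9], [0.1] * 3)
        assert ivw(heterogeneous, "multiplicative_random").se > \
            ivw(heterogeneous, "fixed").se

    def test_matches_weighted_mean_oracle(self, ten_snp_hset):
        h = ten_snp_hset
        w = (h.beta_exp / h.se_out) ** 2
        r = h.beta_out / h.beta_exp
        expected = np.sum(w * r) / np.sum(w)
        assert ivw(h, "fixed").beta == pytest.approx(expected, abs=1e-12)

    def test_zero_exposure_beta_names_snp(self):
        h = make_hset([0.5, 0.0], [0.01] * 2, [0.1] * 2, [0.02] * 2,
                      snp_ids=["ok", "bad"])
        with pytest.raises(UndefinedRatioError, match="bad"):
            ivw(h)

    def test_headline_reporting_consistency(self):
        # an estimate whose OR 95% CI is (0.876, 0.986) around OR 0.929 must
        # report a two-sided p of 0.015 — CI, SE and p are one consistent family
        beta = np.log(0.929)
        se = (np.log(0.986) - np.log(0.876)) / (2 * 1.96)
        p = 2 * stats.norm.sf(abs(beta / se))
        assert p == pytest.approx(0.015, abs=5e-4)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.2, 0.4, 0.6])
        by = 0.01 + 0.2 * bx
        h = make_hset(bx, [0.01] * 3, by, [0.05] * 3)
        slope, intercept = egger(h)
        assert slope.beta == pytest.approx(0.2, abs=1e-12)
        assert intercept.beta == pytest.approx(0.01, abs=1e-12)

    def test_flat_outcome_gives_zero_slope(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        h = make_hset(bx, [0.01] * 4, [0.3] * 4, [0.05] * 4)
        slope, intercept = egger(h)
        assert slope.beta == pytest.approx(0.0, abs=1e-12)
        assert intercept.beta == pytest.approx(0.3, abs=1e-12)

    def test_matches_statsmodels_wls_oracle(self, ten_snp_hset):
        sm = pytest.importorskip("statsmodels.api")
        h = ten_snp_hset
        x = np.abs(h.beta_exp)
        y = h.beta_out * np.sign(h.beta_exp)
        w = 1 / h.se_out ** 2
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        slope, intercept = egger(h)
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels always applies the dispersion scale; ours floors it at 1
        scale = max(1.0, np.sqrt(fit.scale))
        assert slope.se == pytest.approx(fit.bse[1] / np.sqrt(fit.scale) * scale,
                                         abs=1e-10)

    def test_orientation_invariance(self, ten_snp_hset):
        h = ten_snp_hset
        flipped = HarmonizedSet(h.snp_ids, -h.beta_exp, h.se_exp,
                                -h.beta_out, h.se_out)
        s1, i1 = egger(h)
        s2, i2 = egger(flipped)
        assert s1.beta == pytest.approx(s2.beta)
        assert i1.beta == pytest.approx(i2.beta)

    def test_needs_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hset([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.05] * 2))

    def test_ivw_fe_equals_intercept_constrained_egger(self, ten_snp_hset):
        # constrained WLS through the origin is exactly fixed-effect IVW
        h = ten_snp_hset
        w = 1 / h.se_out ** 2
        slope_c = np.sum(w * h.beta_exp * h.beta_out) / np.sum(w * h.beta_exp ** 2)
        assert ivw(h, "fixed").beta == pytest.approx(slope_c, abs=1e-12)


class TestMedians:
    def test_middle_element_equal_weights(self):
        h = make_hset([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.9], [0.05] * 3)
        assert simple_median(h, n_boot=50, seed=0).beta == pytest.approx(0.2)

    def test_even_n_interpolates_central_pair(self):
        h = make_hset([1, 1, 1, 1], [0.01] * 4, [0.1, 0.2, 0.4, 0.9], [0.05] * 4)
        assert simple_median(h, n_boot=50, seed=0).beta == pytest.approx(0.3)

    def test_dominant_weight_pulls_to_its_ratio(self):
        h = make_hset([1, 1, 1], [0.01] * 3, [0.1, 0.7, 0.9],
                      [0.5, 0.05, 0.5])  # middle SNP carries most weight
        est = weighted_median(h, n_boot=50, seed=0).beta
        assert 0.4 < est <= 0.8  # inside the bracket containing 0.7

    def test_interpolation_formula_stepwise_oracle(self):
        # 5 ratios with weights worked through the formula by hand:
        # ratios (0.1, 0.2, 0.3, 0.4, 0.5), weights (.1,.1,.2,.3,.3) normalized
        # s = (.05, .15, .3, .55, .85); 0.5 crossed between s3=.3 (r=.3) and
        # s4=.55 (r=.4): est = .3 + .1*(.5-.3)/(.55-.3) = 0.38
        r = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        w = np.array([0.1, 0.1, 0.2, 0.3, 0.3])
        assert _weighted_median_point(r, w) == pytest.approx(0.38)

    def test_weighted_equals_simple_under_equal_weights(self):
        h = make_hset([0.5] * 5, [0.01] * 5, [0.1, 0.15, 0.2, 0.3, 0.4],
                      [0.05] * 5)
        wm = weighted_median(h, n_boot=10, seed=1).beta
        sm_ = simple_median(h, n_boot=10, seed=1).beta
        assert wm == pytest.approx(sm_, abs=1e-12)

    def test_bootstrap_se_reproducible_for_seed(self, ten_snp_hset):
        a = weighted_median(ten_snp_hset, n_boot=200, seed=5)
        b = weighted_median(ten_snp_hset, n_boot=200, seed=5)
        assert a.se == b.se


class TestEstimatorProperties:
    def test_scale_equivariance(self, ten_snp_hset):
        h = ten_snp_hset
        c = 3.7
        scaled = HarmonizedSet(h.snp_ids, c * h.beta_exp, c * h.se_exp,
                               h.beta_out, h.se_out)
        assert ivw(scaled, "fixed").beta == pytest.approx(ivw(h, "fixed").beta / c)
        assert egger(scaled)[0].beta == pytest.approx(egger(h)[0].beta / c)
        assert weighted_median(scaled, 100, 0).beta == \
            pytest.approx(weighted_median(h, 100, 0).beta / c)

    def test_sign_equivariance(self, ten_snp_hset):
        h = ten_snp_hset
        neg = HarmonizedSet(h.snp_ids, h.beta_exp, h.se_exp, -h.beta_out, h.se_out)
        for est, mirrored in [(ivw(h, "fixed"), ivw(neg, "fixed")),
                              (egger(h)[0], egger(neg)[0])]:
            assert mirrored.beta == pytest.approx(-est.beta)
            assert mirrored.or_ == pytest.approx(1 / est.or_)

    def test_pvalue_ci_consistency(self):
        # |beta/se| = 1.96 <=> CI touching 0 <=> p = 0.05
        e = ivw(make_hset([1.0], [0.01], [1.96], [1.0]), "fixed")
        assert e.ci_low == pytest.approx(0.0, abs=1e-9)
        assert e.pval == pytest.approx(2 * stats.norm.sf(1.96), abs=1e-6)


class TestReverseMR:
    def test_no_reverse_path_yields_null(self):
        # forward effect theta with outcome-specific loci: reverse CI covers 0
        covered = 0
        for seed in range(20):
            cfg = SimConfig(n_snp=40, n_snp_out=30, theta_total=0.2,
                            n_exp=50_000, seed=seed)
            exp, _, out, ld, _ = simulate_chain(cfg)
            rev = reverse_mr(out, exp, ld)
            assert rev.direction == "reverse"
            covered += rev.ci_low <= 0 <= rev.ci_high
        assert covered >= 17  # ≈95% coverage, generous at 20 replicates

    def test_symmetric_null_both_directions_near_zero(self):
        from netmr import gwas_io, select_instruments
        cfg = SimConfig(n_snp=40, n_snp_out=40, theta_total=0.0,
                        n_exp=50_000, seed=1)
        exp, _, out, ld, _ = simulate_chain(cfg)
        inst = select_instruments(exp, ld)
        fwd = ivw(gwas_io.harmonize(inst.records, out))
        rev = reverse_mr(out, exp, ld)
        assert abs(fwd.beta) < 3 * fwd.se
        assert abs(rev.beta) < 3 * rev.se
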