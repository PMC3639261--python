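"""Allelic OR/CI, Cochran-Armitage trend test, HWE, Bonferroni, BP adjust."""

import math

import numpy as np
import pytest

from gwasprio.assoc import (
    adjust_bp_for_treatment,
    allelic_or,
    bonferroni,
    hwe_test,
    trend_test,
)
from gwasprio.io import format_p
from gwasprio.types import CaseControlTable, GenotypeCounts


def cc(case, ctrl, snp_id="snp", major="G", minor="A"):
    return CaseControlTable(snp_id, major, minor,
                            GenotypeCounts(*case), GenotypeCounts(*ctrl))


def swap_alleles(t: CaseControlTable) -> CaseControlTable:
    return CaseControlTable(
        t.snp_id, t.minor_allele, t.major_allele,
        GenotypeCounts(t.cases.n_hom_minor, t.cases.n_het, t.cases.n_hom_major),
        GenotypeCounts(t.controls.n_hom_minor, t.controls.n_het,
                       t.controls.n_hom_major),
    )


class TestAllelicOr:
    def test_published_protective_variant(self, replication_tables):
        res = allelic_or(replication_tables["rs10860812"])
        assert round(res.or_per_minor_allele, 2) == 0.93
        assert round(res.ci_low, 2) == 0.88
        assert round(res.ci_high, 2) == 0.98
        assert not res.continuity_corrected

    def test_identical_distributions_give_null_or(self):
        res = allelic_or(cc((50, 30, 20), (50, 30, 20)))
        assert res.or_per_minor_allele == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_forced_arithmetic(self):
        # case alleles 10 minor / 10 major, control alleles 5 minor / 15 major
        res = allelic_or(cc((0, 10, 0), (5, 5, 0)))
        assert res.or_per_minor_allele == pytest.approx(3.0)

    def test_zero_cell_applies_haldane_anscombe_and_flags(self):
        res = allelic_or(cc((10, 0, 0), (5, 4, 1)))
        assert res.continuity_corrected
        assert math.isfinite(res.or_per_minor_allele) and res.or_per_minor_allele > 0

    def test_monomorphic_table_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            allelic_or(cc((10, 0, 0), (20, 0, 0)))

    @pytest.mark.parametrize("seed", range(5))
    def test_allele_swap_inverts_or_and_flips_z(self, seed):
        rng = np.random.default_rng(seed)
        t = cc(tuple(rng.integers(5, 100, 3)), tuple(rng.integers(5, 100, 3)))
        res, res_sw = allelic_or(t), allelic_or(swap_alleles(t))
        assert res_sw.or_per_minor_allele == pytest.approx(1 / res.or_per_minor_allele)
        assert res_sw.ci_low == pytest.approx(1 / res.ci_high)
        assert res_sw.ci_high == pytest.approx(1 / res.ci_low)
        assert res_sw.z_trend == pytest.approx(-res.z_trend)
        assert res_sw.p_trend == pytest.approx(res.p_trend)

    @pytest.mark.parametrize("seed", range(3))
    def test_case_control_swap_inverts_or_preserves_p(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = tuple(rng.integers(5, 100, 3)), tuple(rng.integers(5, 100, 3))
        res, res_sw = allelic_or(cc(a, b)), allelic_or(cc(b, a))
        assert res_sw.or_per_minor_allele == pytest.approx(1 / res.or_per_minor_allele)
        assert res_sw.p_trend == pytest.approx(res.p_trend)


class TestTrendTest:
    @pytest.mark.parametrize(
        "source,snp_id,expected",
        [
            ("rep", "rs4981504", "4.6E-01"),
            ("rep", "rs4684243", "1.6E-01"),
            ("rep", "rs6891143", "2.7E-01"),
            ("rep", "rs2269772", "2.9E-01"),
            ("rep", "rs10860812", "7.8E-03"),
            ("rep", "rs893881", "9.9E-01"),
            ("wtccc", "rs4981504", "4.1E-04"),
            ("wtccc", "rs4684243", "8.1E-04"),
            ("wtccc", "rs6891143", "1.0E-03"),
            ("wtccc", "rs2269772", "1.5E-03"),
            ("wtccc", "rs10860812", "1.8E-03"),
            ("wtccc", "rs893881", "1.5E-05"),
        ],
    )
    def test_reproduces_published_p_add(
        self, source, snp_id, expected, replication_tables, wtccc_tables
    ):
        tables = replication_tables if source == "rep" else wtccc_tables
        _, p = trend_test(tables[snp_id])
        assert format_p(p) == expected

    def test_proportional_rows_give_null(self):
        z, p = trend_test(cc((100, 60, 40), (50, 30, 20)))
        assert z == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_monomorphic_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            z, p = trend_test(cc((10, 0, 0), (20, 0, 0)))
        assert (z, p) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_logistic_regression_score_test(self, seed):
        """CA trend z^2 equals the score test of per-allele logistic
        regression without covariates (independent statsmodels oracle)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        case = tuple(int(x) for x in rng.integers(10, 200, 3))
        ctrl = tuple(int(x) for x in rng.integers(10, 200, 3))
        z, p = trend_test(cc(case, ctrl))
        y = np.concatenate([np.ones(sum(case)), np.zeros(sum(ctrl))])
        x = np.concatenate(
            [np.repeat([0, 1, 2], case), np.repeat([0, 1, 2], ctrl)]
        ).astype(float)
        null = sm.GLM(y, np.ones_like(y), family=sm.families.Binomial()).fit()
        stat, p_score, _ = null.model.score_test(null.params, exog_extra=x[:, None])
        assert z**2 == pytest.approx(float(np.squeeze(stat)), rel=1e-8)
        assert p == pytest.approx(float(np.squeeze(p_score)), rel=1e-8)


class TestHwe:
    def test_exact_hwe_proportions_give_chi2_zero(self):
        res = hwe_test(GenotypeCounts(2500, 5000, 2500), "chi2_asymptotic")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_published_control_group_satisfies_hwe(self, replication_tables):
        g = replication_tables["rs10860812"].controls
        assert hwe_test(g, "chi2_asymptotic").p > 0.15
        assert hwe_test(g, "levene_exact").p > 0.15

    def test_exact_matches_enumeration_oracle_small_counts(self):
        g = GenotypeCounts(2, 2, 2)
        res = hwe_test(g, "levene_exact")
        n, n_minor = 6, 6
        # enumerate all heterozygote counts of matching parity directly
        probs = {}
        for h in range(0, min(n_minor, 2 * n - n_minor) + 1, 2):
            hom_min = (n_minor - h) // 2
            hom_maj = n - h - hom_min
            probs[h] = (
                math.factorial(n)
                / (math.factorial(hom_maj) * math.factorial(h) * math.factorial(hom_min))
                * 2**h
                * math.factorial(n_minor)
                * math.factorial(2 * n - n_minor)
                / math.factorial(2 * n)
            )
        total = sum(probs.values())
        assert total == pytest.approx(1.0)
        expected = sum(p for p in probs.values() if p <= probs[2] * (1 + 1e-7))
        assert res.p == pytest.approx(expected)

    def test_exact_converges_to_chi2_for_large_counts(self):
        g = GenotypeCounts(2000, 2500, 800)
        p_exact = hwe_test(g, "levene_exact").p
        p_chi2 = hwe_test(g, "chi2_asymptotic").p
        assert abs(p_exact - p_chi2) < 0.01

    def test_monomorphic_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_test(GenotypeCounts(10, 0, 0), "levene_exact").p == 1.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(GenotypeCounts(1, 1, 1), "parametric_bootstrap")


class TestBonferroni:
    def test_six_locus_correction_keeps_significance(self, replication_tables):
        _, p = trend_test(replication_tables["rs10860812"])
        adjusted = bonferroni(p, 6)
        assert round(adjusted, 3) == 0.047
        assert adjusted < 0.05

    def test_capped_at_one(self):
        assert bonferroni(0.5, 6) == 1.0

    def test_single_test_is_identity(self):
        assert bonferroni(0.123, 1) == 0.123

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.1, 0)


class TestBpAdjustment:
    def test_treated_subject_offsets(self):
        assert adjust_bp_for_treatment(140, 85, treated=True) == (155, 95)

    def test_untreated_subject_unchanged(self):
        assert adjust_bp_for_treatment(140, 85, treated=False) == (140, 85)

    @pytest.mark.parametrize("sbp,dbp,treated", [(120, 80, True), (160, 95, False)])
    def test_additivity(self, sbp, dbp, treated):
        out = adjust_bp_for_treatment(sbp, dbp, treated)
        delta = (out[0] - sbp, out[1] - dbp)
        assert delta in {(0, 0), (15, 10)}

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            adjust_bp_for_treatment(0, 80, True)
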