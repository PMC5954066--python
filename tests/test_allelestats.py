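"""Exact 2x2 inference, expansion cutoff, heritability, onset-age analyses."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abca7vntr.allelestats import (
    HeritabilityInputs,
    VntrGenotype,
    aao_expanded_mwu,
    aao_regression,
    carrier_table,
    expansion_cutoff,
    filter_included,
    fisher_or,
    length_by_genotype_kw,
    liability_variance_explained,
    snp_allelic_fisher,
)
from conftest import make_subjects


def alleles_df(ids, long, short):
    return pd.DataFrame({"id": ids, "allele_long": long, "allele_short": short})


class TestVntrGenotype:
    def test_derived_fields(self):
        g = VntrGenotype(5000, 300)
        assert g.sum == 5300
        assert g.expanded(4999) and not g.expanded(5000)  # strict inequality

    def test_order_enforced(self):
        with pytest.raises(ValueError):
            VntrGenotype(300, 5000)


class TestFisherExact:
    def test_printed_carrier_table(self):
        """The cohort's carrier table: OR 4.5 (1.3-24.2), p = 0.008."""
        res = fisher_or(20, 255, 3, 174)
        # Frozen from exact conditional inference (R 4.3.3 fisher.test):
        assert res.odds_ratio == pytest.approx(4.537202, abs=1e-4)
        assert res.ci95[0] == pytest.approx(1.315971, abs=1e-4)
        assert res.ci95[1] == pytest.approx(24.203102, rel=1e-4)
        assert res.p_two_sided == pytest.approx(0.00789107, abs=1e-7)
        assert res.sample_odds_ratio == pytest.approx(4.549, abs=1e-3)

    @pytest.mark.parametrize(
        "table, p, or_, lo, hi",
        [
            # Frozen from R 4.3.3 fisher.test on random small tables.
            ((8, 3, 6, 0), 0.5147059, 0.0, 0.0, 4.428773),
            ((1, 6, 1, 2), 1.0, 0.3779644, 0.003660373, 39.14262),
            ((0, 4, 4, 5), 0.227972, 0.0, 0.0, 3.313209),
            ((6, 8, 4, 4), 1.0, 0.7599449, 0.09444431, 6.005512),
            ((8, 8, 4, 4), 1.0, 1.0, 0.1323862, 7.553659),
        ],
    )
    def test_matches_exact_reference_software(self, table, p, or_, lo, hi):
        res = fisher_or(*table)
        assert res.p_two_sided == pytest.approx(p, abs=1e-6)
        if math.isfinite(or_):
            assert res.odds_ratio == pytest.approx(or_, abs=1e-4)
        assert res.ci95[0] == pytest.approx(lo, abs=2e-4)
        assert res.ci95[1] == pytest.approx(hi, rel=2e-3)

    def test_symmetric_table_is_null(self):
        res = fisher_or(10, 190, 10, 190)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-9)
        assert res.p_two_sided == 1.0

    def test_zero_margin(self):
        res = fisher_or(0, 10, 0, 10)
        assert res.p_two_sided == 1.0
        assert math.isnan(res.odds_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_or(-1, 2, 3, 4)

    def test_two_sided_p_matches_enumeration_oracle(self, rng):
        """Full enumeration of the conditional support reproduces p."""
        for _ in range(25):
            a, b, c, d = rng.integers(0, 12, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            res = fisher_or(int(a), int(b), int(c), int(d))
            n, row1, col1 = a + b + c + d, a + b, a + c
            lo, hi = max(0, col1 - (c + d)), min(row1, col1)
            pmf = {k: stats.hypergeom.pmf(k, n, row1, col1) for k in range(lo, hi + 1)}
            p_obs = pmf[a]
            oracle = sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-7))
            assert res.p_two_sided == pytest.approx(oracle, abs=1e-9)

    def test_row_swap_inverts_odds_ratio(self, rng):
        for _ in range(10):
            a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
            r1 = fisher_or(a, b, c, d)
            r2 = fisher_or(c, d, a, b)
            assert r1.odds_ratio == pytest.approx(1 / r2.odds_ratio, rel=1e-6)
            assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-10)


class TestSnpAllelicFisher:
    def test_allele_counting(self):
        subjects = make_subjects(
            ["p1", "p2", "c1", "c2"],
            ["patient", "patient", "control", "control"],
            rs3764650=[2, 1, 0, 1],
        )
        res = snp_allelic_fisher(subjects, "rs3764650")
        assert (res.a, res.b, res.c, res.d) == (3, 1, 1, 3)

    def test_excluded_subjects_do_not_count(self):
        subjects = make_subjects(
            ["p1", "p2", "c1"],
            ["patient", "patient", "control"],
            rs3764650=[2, 2, 1],
            excluded_reason=["none", "ptc_carrier", "none"],
        )
        res = snp_allelic_fisher(subjects, "rs3764650")
        assert res.a + res.b == 2  # one included patient -> two alleles

    def test_null_frequencies_rarely_significant(self):
        """MAF ~0.13 vs ~0.12 at n~450 is underpowered (cohort null finding)."""
        rng = np.random.default_rng(5)
        sig = 0
        for _ in range(40):
            gp = rng.binomial(2, 0.134, 275)
            gc = rng.binomial(2, 0.121, 177)
            subjects = make_subjects(
                [f"s{i}" for i in range(452)],
                ["patient"] * 275 + ["control"] * 177,
                rs3764650=np.concatenate([gp, gc]),
            )
            sig += snp_allelic_fisher(subjects, "rs3764650").p_two_sided < 0.05
        assert sig <= 8  # large majority nonsignificant


class TestExpansionCutoff:
    def test_max_over_qualifying_controls(self):
        subjects = make_subjects(
            ["c1", "c2", "c3", "p1"],
            ["control", "control", "control", "patient"],
            rs3764650=[0, 0, 1, 0],
        )
        alle = alleles_df(
            ["c1", "c2", "c3", "p1"], [2000, 5500, 8000, 9000], [1200, 3100, 900, 500]
        )
        assert expansion_cutoff(subjects, alle) == 5500

    def test_single_qualifying_control(self):
        subjects = make_subjects(["c1"], ["control"], rs3764650=[0])
        alle = alleles_df(["c1"], [4200], [300])
        assert expansion_cutoff(subjects, alle) == 4200

    def test_no_qualifying_control_errors(self):
        subjects = make_subjects(["c1"], ["control"], rs3764650=[2])
        alle = alleles_df(["c1"], [4200], [300])
        with pytest.raises(ValueError, match="qualifying"):
            expansion_cutoff(subjects, alle)

    def test_estimated_cutoff_within_generator_band(self, small_cohort):
        """The rule recovers the truth cutoff up to the expansion tail."""
        est = expansion_cutoff(small_cohort.subjects, small_cohort.alleles)
        truth = small_cohort.truth["expansion_cutoff"]
        assert est <= truth + 6 * 1500  # tail allowance
        assert est >= 0.6 * truth

    def test_ties_at_cutoff_are_wild_type(self):
        subjects = make_subjects(
            ["c1", "p1"], ["control", "patient"], rs3764650=[0, 0]
        )
        alle = alleles_df(["c1", "p1"], [5000, 5000], [300, 300])
        cutoff = expansion_cutoff(subjects, alle)
        a, b, c, d = carrier_table(subjects, alle, cutoff)
        assert (a, c) == (0, 0)  # the tied patient allele is not expanded


class TestLengthByGenotypeKw:
    def test_identical_lengths_p_one(self):
        subjects = make_subjects(
            ["a", "b", "c", "d"],
            ["patient"] * 4,
            rs3764650=[0, 1, 2, 1],
        )
        alle = alleles_df(["a", "b", "c", "d"], [2000] * 4, [1000] * 4)
        assert length_by_genotype_kw(subjects, alle, "rs3764650").p == 1.0

    def test_ld_detected_at_cohort_scale(self, cohort):
        res = length_by_genotype_kw(
            cohort.subjects, cohort.alleles, "rs3764650", "longest"
        )
        assert res.p < 0.05


class TestLiabilityVarianceExplained:
    def test_null_odds_ratio_explains_nothing(self):
        res = liability_variance_explained(
            HeritabilityInputs(risk_freq=0.05, odds_ratio=1.0)
        )
        assert res.variance_liability == pytest.approx(0.0, abs=1e-12)

    def test_small_effect_limit_matches_probit_linearization(self):
        """As OR -> 1+, variance -> p(1-p) * ((f1-f0)/phi(t))^2 (carrier model)."""
        K, p, OR = 0.13, 0.2, 1.001
        res = liability_variance_explained(
            HeritabilityInputs(K=K, risk_freq=p, odds_ratio=OR, model="carrier")
        )
        rr = OR / (1 - K + K * OR)
        f0 = K / (1 - p + p * rr)
        f1 = f0 * rr
        t = stats.norm.isf(K)
        d = (f1 - f0) / stats.norm.pdf(t)
        assert res.variance_liability == pytest.approx(p * (1 - p) * d * d, rel=1e-3)

    def test_monotone_in_or_and_frequency(self):
        grid_or = [1.5, 2.5, 4.0, 8.0]
        vals = [
            liability_variance_explained(
                HeritabilityInputs(risk_freq=0.05, odds_ratio=o)
            ).variance_liability
            for o in grid_or
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        grid_p = [0.01, 0.05, 0.2, 0.4]
        vals = [
            liability_variance_explained(
                HeritabilityInputs(risk_freq=p, odds_ratio=4.5)
            ).variance_liability
            for p in grid_p
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_or_to_rr_conversion_prevents_saturation(self):
        """The prevalence-anchored OR->RR conversion keeps group risks < 1
        even for extreme odds ratios (the risk-scale model would saturate)."""
        res = liability_variance_explained(
            HeritabilityInputs(K=0.4, risk_freq=0.3, odds_ratio=500.0)
        )
        assert all(r < 1.0 for r in res.group_risks)
        assert 0 < res.variance_liability < 1

    def test_share_is_variance_over_h2(self):
        res = liability_variance_explained(
            HeritabilityInputs(risk_freq=0.02, odds_ratio=4.5)
        )
        assert res.as_share_of_h2 == pytest.approx(res.variance_liability / 0.79)
        assert 0 <= res.variance_liability <= 0.79


class TestOnsetAge:
    def make_patients(self, rng, n=60, slope=0.0):
        long = rng.uniform(500, 8000, n)
        short = rng.uniform(300, 4000, n)
        long, short = np.maximum(long, short), np.minimum(long, short)
        aao = 73 + slope * (long + short) + rng.normal(0, 5, n)
        subjects = make_subjects(
            [f"p{i}" for i in range(n)],
            ["patient"] * n,
            aao=np.round(aao, 1),
            gender=rng.choice(["M", "F"], n),
            apoe_e4=rng.integers(0, 3, n),
        )
        return subjects, alleles_df([f"p{i}" for i in range(n)], long, short)

    def test_recovers_planted_slope(self, rng):
        hits = 0
        for _ in range(20):
            subjects, alle = self.make_patients(rng, n=275, slope=-0.001)
            res = aao_regression(subjects, alle, "sum")
            hits += abs(res.beta - (-0.001)) < 2 * res.se
        assert hits >= 17  # ~95% nominal coverage

    def test_constant_aao_errors(self, rng):
        subjects, alle = self.make_patients(rng, n=20)
        subjects["aao"] = 70.0
        with pytest.raises(ValueError, match="constant"):
            aao_regression(subjects, alle)

    def test_too_few_patients_errors(self, rng):
        subjects, alle = self.make_patients(rng, n=5)
        with pytest.raises(ValueError, match="10 patients"):
            aao_regression(subjects, alle)

    def test_mwu_identical_groups(self):
        subjects = make_subjects(
            ["a", "b", "c", "d"], ["patient"] * 4, aao=[70.0] * 4
        )
        alle = alleles_df(["a", "b", "c", "d"], [9000, 9000, 2000, 2000], [300] * 4)
        assert aao_expanded_mwu(subjects, alle, 5720).p == 1.0

    def test_mwu_single_member_group(self):
        subjects = make_subjects(
            ["a", "b", "c"], ["patient"] * 3, aao=[60.0, 75.0, 80.0]
        )
        alle = alleles_df(["a", "b", "c"], [9000, 2000, 2000], [300] * 3)
        res = aao_expanded_mwu(subjects, alle, 5720)
        assert res.n1 == 1 and 0 < res.p <= 1

    def test_mwu_agrees_with_permutation_oracle(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(1.0, 1, 15)
        n = len(x)
        subjects = make_subjects(
            [f"s{i}" for i in range(27)], ["patient"] * 27,
            aao=np.concatenate([x, y]),
        )
        alle = alleles_df(
            [f"s{i}" for i in range(27)],
            [9000] * n + [2000] * 15,
            [300] * 27,
        )
        res = aao_expanded_mwu(subjects, alle, 5720)
        # permutation distribution of |U - n1 n2 / 2|
        pooled = np.concatenate([x, y])
        obs = abs(res.u - n * 15 / 2)
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            u = stats.mannwhitneyu(perm[:n], perm[n:]).statistic
            count += abs(u - n * 15 / 2) >= obs - 1e-9
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert res.p == pytest.approx(p_perm, abs=max(5 * se, 0.01))


class TestExclusions:
    def test_unknown_reason_rejected(self):
        subjects = make_subjects(["a"], ["patient"], excluded_reason=["who_knows"])
        with pytest.raises(ValueError, match="unknown exclusion"):
            filter_included(subjects)

    def test_all_reasons_filtered(self):
        subjects = make_subjects(
            ["a", "b", "c", "d"],
            ["patient"] * 4,
            excluded_reason=["none", "single_band", "ptc_carrier", "mendelian_mutation"],
        )
        assert filter_included(subjects)["id"].tolist() == ["a"]
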