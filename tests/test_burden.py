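import math
from fractions import Fraction

import numpy as np
import pytest

from rarefam.burden import (
    aggregate_gene_carriers,
    burden_test,
    compare_to_reference_af,
    fisher_one_sided,
    odds_ratio_cmle,
    odds_ratio_wald,
    per_variant_test,
    run_burden_scan,
)
from rarefam.simulate import SimConfig, rng_streams, simulate_cohort
from rarefam.types import (
    AnnotatedVariant,
    ContingencyTable,
    FilterConfig,
    FilterMode,
    FunctionalClass,
    GenotypeTable,
)

RARE = FilterConfig(mode=FilterMode.RARE)


def enumerate_upper_tail(a, b, c, d) -> Fraction:
    """Independent oracle: exact hypergeometric tail by direct enumeration
    over all tables compatible with the margins."""
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, K + n - N), min(K, n)
    total = Fraction(math.comb(N, n))
    return sum(
        (Fraction(math.comb(K, x) * math.comb(N - K, n - x)) / total
         for x in range(a, hi + 1)),
        Fraction(0),
    )


class TestFisher:
    def test_matches_enumeration_on_small_margins(self):
        for n1 in range(0, 7):
            for n2 in range(0, 7):
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        t = ContingencyTable(a, n1 - a, c, n2 - c)
                        expected = float(enumerate_upper_tail(a, n1 - a, c, n2 - c)) if n1 + n2 else 1.0
                        assert fisher_one_sided(t) == pytest.approx(
                            expected, abs=1e-12
                        )

    def test_no_carriers_gives_one(self):
        assert fisher_one_sided(ContingencyTable(0, 10, 0, 10)) == 1.0
        assert fisher_one_sided(ContingencyTable(0, 0, 0, 0)) == 1.0

    def test_monotone_decreasing_in_case_carriers(self):
        """With margins fixed, moving carriers from controls to cases can
        only make the upper-tail p smaller."""
        previous = 1.1
        for a in range(0, 11):
            p = fisher_one_sided(ContingencyTable(a, 50 - a, 10 - a, 40 + a))
            assert p < previous
            previous = p


class TestOddsRatio:
    # frozen from R 4.3.3 fisher.test (conditional MLE + exact conditional CI)
    R_ORACLE = {
        (18, 986, 2, 1125): (10.26024, 2.44665, 91.41893),
        (12, 992, 1, 1126): (13.6041, 2.007016, 581.237359),
    }

    @pytest.mark.parametrize("cells", sorted(R_ORACLE))
    def test_cmle_and_ci_match_independent_implementation(self, cells):
        est_ref, lo_ref, hi_ref = self.R_ORACLE[cells]
        est, (lo, hi) = odds_ratio_cmle(ContingencyTable(*cells))
        assert est == pytest.approx(est_ref, rel=1e-3)
        assert lo == pytest.approx(lo_ref, rel=1e-3)
        assert hi == pytest.approx(hi_ref, rel=5e-3)

    def test_symmetric_table_is_one(self):
        est, (lo, hi) = odds_ratio_cmle(ContingencyTable(5, 5, 5, 5))
        assert est == pytest.approx(1.0, abs=1e-9)
        assert lo < 1.0 < hi

    def test_estimate_inside_ci(self):
        for cells in [(3, 7, 1, 9), (8, 2, 2, 8), (1, 1, 1, 1)]:
            est, (lo, hi) = odds_ratio_cmle(ContingencyTable(*cells))
            assert lo <= est <= hi

    def test_no_carriers_undefined(self):
        est, (lo, hi) = odds_ratio_cmle(ContingencyTable(0, 10, 0, 10))
        assert math.isnan(est)
        assert (lo, hi) == (0.0, math.inf)

    def test_zero_cells_give_one_sided_infinite_bounds(self):
        est, (lo, hi) = odds_ratio_cmle(ContingencyTable(5, 5, 0, 10))
        assert est == math.inf and hi == math.inf and lo > 0
        est, (lo, hi) = odds_ratio_cmle(ContingencyTable(0, 10, 5, 5))
        assert est == 0.0 and lo == 0.0 and hi < math.inf

    def test_wald_matches_direct_formula(self):
        a, b, c, d = 18, 986, 2, 1125
        est, (lo, hi) = odds_ratio_wald(ContingencyTable(a, b, c, d))
        assert est == pytest.approx(a * d / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert lo == pytest.approx(est * math.exp(-1.959964 * se), rel=1e-5)
        assert hi == pytest.approx(est * math.exp(1.959964 * se), rel=1e-5)

    def test_conditional_estimate_shrinks_relative_to_sample_or(self):
        # conditional MLE is pulled toward 1 relative to the cross-product
        t = ContingencyTable(18, 986, 2, 1125)
        cmle, _ = odds_ratio_cmle(t)
        wald, _ = odds_ratio_wald(t)
        assert 1.0 < cmle < wald


class TestAggregation:
    def test_worked_example_carrier_counts(self, cep41_panel):
        variants, gt, cases, controls, _ = cep41_panel
        table = aggregate_gene_carriers("CEP41", variants, gt, cases,
                                        controls, RARE)
        assert (table.a, table.c) == (18, 2)
        assert (table.n_cases, table.n_controls) == (1004, 1127)

    def test_gene_without_qualifying_variants(self, cep41_panel):
        variants, gt, cases, controls, _ = cep41_panel
        table = aggregate_gene_carriers("NOSUCH", variants, gt, cases,
                                        controls, RARE)
        assert (table.a, table.c) == (0, 0)

    def test_individual_with_two_variants_counts_once(self):
        v1 = AnnotatedVariant("1", 100, "A", "G", "G1",
                              FunctionalClass.NONSYNONYMOUS)
        v2 = AnnotatedVariant("1", 200, "C", "T", "G1",
                              FunctionalClass.NONSYNONYMOUS)
        gt = GenotypeTable(
            [v1.key, v2.key], ["case1", "case2", "ctrl1"],
            np.array([[1, 0, 0], [1, 0, 0]], dtype=float),
        )
        table = aggregate_gene_carriers("G1", [v1, v2], gt, ["case1", "case2"],
                                        ["ctrl1"], RARE)
        assert (table.a, table.b, table.c, table.d) == (1, 1, 0, 1)

    def test_overlapping_case_control_ids_rejected(self, cep41_panel):
        variants, gt, cases, controls, _ = cep41_panel
        with pytest.raises(ValueError, match="both case and control"):
            aggregate_gene_carriers("CEP41", variants, gt, cases,
                                    controls + [cases[0]], RARE)

    def test_counting_invariant_to_variant_order(self, cep41_panel):
        variants, gt, cases, controls, _ = cep41_panel
        fwd = aggregate_gene_carriers("CEP41", variants, gt, cases, controls,
                                      RARE)
        rev = aggregate_gene_carriers("CEP41", variants[::-1], gt, cases,
                                      controls, RARE)
        assert fwd == rev


class TestPerVariant:
    def test_p206a_worked_example(self, cep41_panel):
        variants, gt, cases, controls, by_aa = cep41_panel
        res = per_variant_test(by_aa["P206A"], gt, cases, controls)
        assert (res.table.a, res.table.c) == (12, 1)
        assert res.p_one_sided == pytest.approx(8.5272e-4, rel=1e-4)

    def test_absent_variant_gives_p_one(self, cep41_panel):
        variants, gt, cases, controls, _ = cep41_panel
        ghost = AnnotatedVariant("9", 1, "A", "T", "CEP41",
                                 FunctionalClass.NONSYNONYMOUS)
        res = per_variant_test(ghost, gt, cases, controls)
        assert res.p_one_sided == 1.0

    def test_agrees_with_aggregate_for_single_variant_gene(self):
        v = AnnotatedVariant("2", 50, "G", "C", "SOLO",
                             FunctionalClass.SPLICE)
        gt = GenotypeTable(
            [v.key], [f"s{i}" for i in range(8)],
            np.array([[1, 1, 0, 0, 0, 0, 1, 0]], dtype=float),
        )
        cases, controls = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        single = per_variant_test(v, gt, cases, controls)
        table = aggregate_gene_carriers("SOLO", [v], gt, cases, controls, RARE)
        assert single.table == table
        assert single.p_one_sided == fisher_one_sided(table)


class TestReferenceComparison:
    def test_reconstruction_matches_direct_fisher(self):
        res = compare_to_reference_af(12, 1004, ref_af=0.005,
                                      ref_n_alleles=10000)
        direct = burden_test(ContingencyTable(12, 2 * 1004 - 12, 50, 9950))
        assert res.table == direct.table
        assert res.p_one_sided == direct.p_one_sided

    def test_zero_reference_af(self):
        res = compare_to_reference_af(12, 1004, ref_af=0.0, ref_n_alleles=10000)
        assert res.or_cmle == math.inf
        assert res.p_one_sided < 1e-6

    def test_no_case_carriers_gives_p_one(self):
        res = compare_to_reference_af(0, 1004, ref_af=0.005,
                                      ref_n_alleles=10000)
        assert res.p_one_sided == 1.0

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError, match="frequency"):
            compare_to_reference_af(1, 10, ref_af=1.5, ref_n_alleles=100)


class TestScan:
    def test_single_gene_bonferroni_is_identity(self, cep41_panel):
        variants, gt, cases, controls, _ = cep41_panel
        (res,) = run_burden_scan(["CEP41"], variants, gt, cases, controls, RARE)
        assert res.p_bonferroni == res.p_one_sided
        assert res.n_variants == 8

    def test_planted_gene_ranks_first(self):
        cfg = SimConfig(seed=42)
        variants, gt, cases, controls, truth = simulate_cohort(
            cfg, rng_streams(cfg.seed)["cohort"]
        )
        results = run_burden_scan(list(cfg.genes), variants, gt, cases,
                                  controls, RARE)
        assert results[0].gene == truth.planted_gene
        assert results[0].table.a == len(truth.case_carriers)
        assert results[0].table.c == len(truth.control_carriers)

    def test_allele_mode_counts_alleles(self):
        v = AnnotatedVariant("1", 10, "A", "G", "G1",
                             FunctionalClass.NONSYNONYMOUS)
        gt = GenotypeTable([v.key], ["a", "b", "c", "d"],
                           np.array([[2, 1, 0, 0]], dtype=float))
        (res,) = run_burden_scan(["G1"], [v], gt, ["a", "b"], ["c", "d"],
                                 RARE, count_mode="allele")
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (3, 1, 0, 4)
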