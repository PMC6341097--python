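import itertools
import math

import numpy as np
import pytest

from rarefam.enrichment import (
    bh_fdr,
    default_universe,
    filter_sets_by_size,
    ora_test,
    run_enrichment,
)
from rarefam.simulate import simulate_enrichment_input, simulate_gene_sets
from rarefam.types import EnrichmentConfig, GeneSet


def make_set(set_id, members):
    return GeneSet(set_id=set_id, name=set_id, members=frozenset(members))


class TestOra:
    def test_matches_exhaustive_enumeration(self):
        """Universe of 20 genes, category of 8; p for an input of 6 genes
        equals the exact tail computed by enumerating all C(20,6) draws."""
        universe = {f"G{i:02d}" for i in range(20)}
        category = {f"G{i:02d}" for i in range(8)}
        input_genes = {"G00", "G01", "G02", "G10", "G11", "G12"}
        res = ora_test(input_genes, make_set("S", category), universe)
        assert res.O == 3

        hits = total = 0
        for draw in itertools.combinations(sorted(universe), 6):
            total += 1
            if len(set(draw) & category) >= res.O:
                hits += 1
        assert res.p == pytest.approx(hits / total, rel=1e-10)

    def test_expected_and_ratio(self):
        universe = {f"G{i}" for i in range(100)}
        category = {f"G{i}" for i in range(20)}
        input_genes = {f"G{i}" for i in range(15, 25)}  # k=10, O=5
        res = ora_test(input_genes, make_set("S", category), universe)
        assert res.E == pytest.approx(20 * 10 / 100)
        assert res.R == pytest.approx(5 / 2.0)
        assert res.overlap_genes == tuple(sorted(category & input_genes))

    def test_saturated_input(self):
        universe = {f"G{i}" for i in range(30)}
        category = {f"G{i}" for i in range(10)}
        res = ora_test(universe, make_set("S", category), universe)
        assert res.O == res.C == 10
        assert res.p == pytest.approx(1.0)

    def test_empty_expected_is_nan(self):
        universe = {"A", "B"}
        res = ora_test({"A"}, make_set("S", {"Z"}), universe)
        assert res.C == 0 and math.isnan(res.R)
        assert res.p == 1.0

    def test_case_insensitive_matching(self):
        universe = {"ABC", "DEF", "GHI"}
        res = ora_test({"abc"}, make_set("S", {"Abc", "DEF"}), universe)
        assert res.O == 1

    def test_p_monotone_in_overlap(self):
        """For fixed N, C, k the tail probability falls as O grows."""
        from scipy.stats import hypergeom

        N, C, k = 1000, 100, 50
        ps = [float(hypergeom.sf(O - 1, N, C, k)) for O in range(0, 20)]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))


class TestSizeFilter:
    cfg = EnrichmentConfig()

    def test_window_bounds(self):
        universe = {f"G{i}" for i in range(3000)}
        small = make_set("small", {f"G{i}" for i in range(400)})
        edge = make_set("edge", {f"G{i}" for i in range(1489)})
        big = make_set("big", {f"G{i}" for i in range(1501)})
        kept = filter_sets_by_size([small, edge, big], self.cfg, universe)
        assert [s.set_id for s in kept] == ["edge"]

    def test_size_counts_only_universe_members(self):
        universe = {f"G{i}" for i in range(600)}
        # 700 members but only 550 inside the universe
        gs = make_set("S", {f"G{i}" for i in range(550)} | {f"X{i}" for i in range(150)})
        assert filter_sets_by_size([gs], self.cfg, universe) == [gs]

    def test_unbounded_window_is_identity(self):
        cfg = EnrichmentConfig(min_set_size=1, max_set_size=10 ** 9)
        universe = {f"G{i}" for i in range(10)}
        sets = [make_set("A", {"G1"}), make_set("B", {f"G{i}" for i in range(10)})]
        assert filter_sets_by_size(sets, cfg, universe) == sets


def step_up_oracle(pvalues):
    """Literal BH definition: sort ascending, adj_(i) = min over j >= i of
    p_(j) * m / j, capped at 1, mapped back to input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.04]) == [0.04]

    def test_hand_computed_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_empty_list(self):
        assert bh_fdr([]) == []

    def test_matches_step_up_definition_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 9))
            ps = rng.uniform(1e-6, 1.0, size=m).tolist()
            assert bh_fdr(ps) == pytest.approx(step_up_oracle(ps))

    def test_order_invariance_and_bounds(self, rng):
        ps = rng.uniform(0.001, 1.0, size=20)
        fwd = bh_fdr(ps.tolist())
        rev = bh_fdr(ps[::-1].tolist())
        assert fwd == pytest.approx(rev[::-1])
        assert all(0 < q <= 1 for q in fwd)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])


class TestRunEnrichment:
    def test_planted_set_has_smallest_p(self, rng):
        """An input list drawn with 3x over-representation of one set's
        members puts that set at the top in nearly every replicate."""
        sets = simulate_gene_sets(rng, n_sets=40, universe_size=3000,
                                  size_range=(300, 900))
        cfg = EnrichmentConfig(min_set_size=1, max_set_size=10 ** 9)
        wins = 0
        n_reps = 200
        for _ in range(n_reps):
            genes = simulate_enrichment_input(sets, "SET0001", 150, rng)
            results = run_enrichment(genes, sets, cfg)
            wins += results[0].set_id == "SET0001"
        assert wins / n_reps >= 0.90

    def test_disjoint_input_all_null(self):
        sets = [make_set("A", {"G1", "G2"}), make_set("B", {"G3"})]
        universe = {"G1", "G2", "G3", "X1", "X2"}
        cfg = EnrichmentConfig(min_set_size=1, max_set_size=100)
        results = run_enrichment({"X1", "X2"}, sets, cfg, universe=universe)
        assert all(r.O == 0 and r.p == 1.0 for r in results)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_enrichment([], [make_set("A", {"G1"})])

    def test_universe_choice_changes_every_p(self):
        sets = [make_set("A", {f"G{i}" for i in range(10)}),
                make_set("B", {f"G{i}" for i in range(5, 20)})]
        cfg = EnrichmentConfig(min_set_size=1, max_set_size=100)
        genes = [f"G{i}" for i in range(8)]  # overlaps both sets
        base_universe = {f"G{i}" for i in range(20)}
        padded = base_universe | {f"DUMMY{i}" for i in range(20)}
        base = run_enrichment(genes, sets, cfg, universe=base_universe)
        wide = run_enrichment(genes, sets, cfg, universe=padded)
        for r1, r2 in zip(sorted(base, key=lambda r: r.set_id),
                          sorted(wide, key=lambda r: r.set_id)):
            assert r1.p != r2.p

    def test_overlap_count_conservation(self, rng):
        """Sum of O over sets equals the sum over input genes of their
        set-membership counts (bipartite edge count)."""
        sets = simulate_gene_sets(rng, n_sets=25, universe_size=500,
                                  size_range=(20, 200))
        universe = default_universe(sets)
        genes = list(universe)[:50]
        cfg = EnrichmentConfig(min_set_size=1, max_set_size=10 ** 9)
        results = run_enrichment(genes, sets, cfg)
        total_O = sum(r.O for r in results)
        memberships = sum(
            sum(1 for gs in sets if g.upper() in {m.upper() for m in gs.members})
            for g in genes
        )
        assert total_O == memberships

    def test_fdr_attached_and_sorted(self, rng):
        sets = simulate_gene_sets(rng, n_sets=15, universe_size=400,
                                  size_range=(20, 100))
        cfg = EnrichmentConfig(min_set_size=1, max_set_size=10 ** 9)
        genes = list(default_universe(sets))[:30]
        results = run_enrichment(genes, sets, cfg)
        assert [r.p for r in results] == sorted(r.p for r in results)
        assert bh_fdr([r.p for r in results]) == pytest.approx(
            [r.fdr for r in results]
        )
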