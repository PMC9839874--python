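"""Fisher enrichment, BH adjustment, chemical screening, fingerprint rule."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aopfinger.enrich import (
    GeneUniverse,
    aop_fingerprint,
    aop_gene_sets,
    default_universe,
    fisher_enrich,
    pool_moa,
    screen_chemicals,
)
from aopfinger.grouping import group_identical
from aopfinger.io import AOP, ChemicalProfile, DEGTable, KEGeneSet
from aopfinger.simulate import (
    FixtureConfig,
    simulate_aop_structure,
    simulate_chemicals,
    simulate_moa,
)


def hypergeom_tail_oracle(M: int, K: int, N: int, k: int) -> float:
    """P(X >= k) by exhaustive summation of the hypergeometric pmf."""
    total = comb(M, N)
    return sum(comb(K, x) * comb(M - K, N - x) for x in range(k, min(K, N) + 1)) / total


def bh_oracle(ps: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up computed from the definition."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        running = min(running, ps[i] * m / rank_from_end)
        adj[i] = running
    return adj


class TestFisherEnrich:
    UNIVERSE = GeneUniverse(frozenset(f"g{i}" for i in range(20)))

    def test_worked_example_tail_sum(self):
        # universe 20, set 5, query 5, overlap 3 -> 1126/15504
        sets = [("S", frozenset(f"g{i}" for i in range(5)))]
        query = {"g0", "g1", "g2", "g10", "g11"}
        res = fisher_enrich(query, sets, self.UNIVERSE)
        assert res.loc[0, "overlap"] == 3
        assert res.loc[0, "p"] == pytest.approx(1126 / 15504, rel=1e-12)

    def test_query_equal_to_set_degenerate(self):
        genes = frozenset(f"g{i}" for i in range(20))
        res = fisher_enrich(set(genes), [("S", genes)], self.UNIVERSE)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_set_gets_p_one(self):
        res = fisher_enrich({"g0"}, [("S", frozenset())], self.UNIVERSE)
        assert res.loc[0, "p"] == 1.0

    def test_empty_query_is_error(self):
        with pytest.raises(ValueError, match="empty query"):
            fisher_enrich({"not-in-universe"}, [("S", frozenset({"g1"}))], self.UNIVERSE)

    def test_bh_worked_example(self):
        # p-values 0.01..0.04 over 4 sets -> all fdr = 0.04
        universe = GeneUniverse(frozenset(f"g{i}" for i in range(400)))
        # craft sets with increasing p by shrinking overlap
        query = set(f"g{i}" for i in range(40))
        sets = [
            (f"S{j}", frozenset(f"g{i}" for i in range(j * 3, j * 3 + 40)))
            for j in range(4)
        ]
        res = fisher_enrich(query, sets, universe)
        assert np.allclose(
            np.sort(res["fdr"].to_numpy()),
            np.sort(bh_oracle(list(res["p"]))),
        )

    def test_matches_exhaustive_oracle_small_universes(self):
        rng = np.random.default_rng(17)
        for M in (8, 15, 30):
            genes = [f"g{i}" for i in range(M)]
            universe = GeneUniverse(frozenset(genes))
            for _ in range(20):
                K = int(rng.integers(1, M + 1))
                N = int(rng.integers(1, M + 1))
                s = frozenset(rng.choice(genes, size=K, replace=False))
                q = set(rng.choice(genes, size=N, replace=False))
                res = fisher_enrich(q, [("S", s)], universe)
                k = len(q & s)
                assert res.loc[0, "p"] == pytest.approx(
                    hypergeom_tail_oracle(M, K, N, k), rel=1e-10
                )

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_bh_properties(self, ps):
        from scipy.stats import false_discovery_control

        adj = false_discovery_control(ps, method="bh")
        oracle = bh_oracle(ps)
        assert np.allclose(adj, oracle, atol=1e-12)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        # monotone non-decreasing in raw-p order
        order = np.argsort(ps, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestScreenChemicals:
    def _fixture(self):
        sets = {
            "A1": frozenset(f"a{i}" for i in range(60)),
            "A2": frozenset(f"b{i}" for i in range(60)),
            "A3": frozenset(f"c{i}" for i in range(60)),
        }
        universe = GeneUniverse(frozenset().union(*sets.values()))
        return list(sets.items()), universe

    def test_exact_match_ranks_first_and_flags_relevant(self):
        aop_sets, universe = self._fixture()
        chem = ChemicalProfile("C1", "x", None, aop_sets[0][1])
        report, proportions = screen_chemicals(
            [chem], aop_sets, universe, relevance={"A1": ["hepatotoxic"]}
        )
        assert report.iloc[0]["aop_id"] == "A1"
        assert report.iloc[0]["rank"] == 1
        assert proportions.loc[0, "proportion_flagged"] == 1.0

    def test_size_filter_excludes_small_chemical(self):
        aop_sets, universe = self._fixture()
        small = ChemicalProfile("C2", "y", None, frozenset(f"a{i}" for i in range(30)))
        report, _ = screen_chemicals([small], aop_sets, universe)
        assert report.empty

    def test_planted_signal_flagged_above_80_percent(self):
        cfg = FixtureConfig(seed=0)
        aops, _, ke_sets, _ = simulate_aop_structure(cfg)
        aop_sets = aop_gene_sets(aops, {s.ke_id: s.genes for s in ke_sets})
        universe = default_universe(ke_sets)
        chems, targets, relevance = simulate_chemicals(cfg, aop_sets)
        _, proportions = screen_chemicals(chems, aop_sets, universe, relevance=relevance)
        assert proportions.loc[0, "proportion_flagged"] >= 0.8

    def test_invariant_to_input_order(self):
        cfg = FixtureConfig(seed=1, n_chemicals=5)
        aops, _, ke_sets, _ = simulate_aop_structure(cfg)
        aop_sets = aop_gene_sets(aops, {s.ke_id: s.genes for s in ke_sets})
        universe = default_universe(ke_sets)
        chems, _, relevance = simulate_chemicals(cfg, aop_sets)
        r1, p1 = screen_chemicals(chems, aop_sets, universe, relevance=relevance)
        r2, p2 = screen_chemicals(
            list(reversed(chems)), list(reversed(aop_sets)), universe, relevance=relevance
        )
        assert r1.equals(r2)
        assert p1.equals(p2)


class TestPoolMoa:
    def test_union_over_comparisons(self):
        t1 = DEGTable("c1", pd.DataFrame(
            {"gene": ["A", "B"], "log2fc": [2.0, 2.0], "adj_p": [0.01, 0.01]}))
        t2 = DEGTable("c2", pd.DataFrame(
            {"gene": ["B", "C"], "log2fc": [2.0, -2.0], "adj_p": [0.01, 0.01]}))
        assert pool_moa([t1, t2]) == {"A", "B", "C"}

    def test_single_table_equals_filter(self, deg_table):
        from aopfinger.io import filter_degs

        with pytest.warns(UserWarning):
            assert pool_moa([deg_table]) == filter_degs(deg_table)

    def test_hand_filtered_three_comparisons(self):
        frames = [
            pd.DataFrame({"gene": ["A", "B"], "log2fc": [1.0, 0.1], "adj_p": [0.01, 0.01]}),
            pd.DataFrame({"gene": ["C"], "log2fc": [-1.0], "adj_p": [0.04]}),
            pd.DataFrame({"gene": ["D"], "log2fc": [3.0], "adj_p": [0.06]}),
        ]
        tables = [DEGTable(f"c{i}", f) for i, f in enumerate(frames)]
        # hand filtering: A and C pass, B fails FC, D fails p
        assert pool_moa(tables) == {"A", "C"}


class TestAopFingerprint:
    def _setup(self, n_kes, n_enriched_groups, planted_frac=1.0):
        """AOP whose first n_enriched KEs carry planted genes."""
        genes_per_ke = 30
        kes, sets = [], []
        for i in range(n_kes):
            ke = f"Ke{i:02d}"
            kes.append(ke)
            sets.append(KEGeneSet(ke, frozenset(f"g{i}_{j}" for j in range(genes_per_ke))))
        aop = AOP("A1", "t", tuple(kes), tuple(zip(kes[:-1], kes[1:])))
        # background AOP so BH has a family and universe is wider
        bg = [KEGeneSet(f"Kb{i:02d}", frozenset(f"b{i}_{j}" for j in range(30)))
              for i in range(6)]
        bg_aop = AOP("A0", "bg", tuple(s.ke_id for s in bg))
        all_sets = sets + bg
        ke_map = {s.ke_id: s.genes for s in all_sets}
        universe = default_universe(all_sets)
        groups = group_identical(all_sets)
        moa = set()
        for s in sets[:n_enriched_groups]:
            take = int(planted_frac * len(s.genes))
            moa |= set(sorted(s.genes)[:take])
        moa |= set(sorted(bg[0].genes)[:2])  # sprinkle of background
        return moa, [aop, bg_aop], ke_map, groups, universe

    @pytest.mark.parametrize(
        "n_kes,n_enriched,expect_pass",
        [
            (8, 7, True),   # in vivo style: 7 of 8 enriched
            (8, 3, True),   # in vitro style: 3 of 8 = 0.375 >= 1/3
            (8, 2, False),  # 0.25 < 1/3 and AOP length >= 6
            (5, 2, True),   # min-2 rule for short AOPs
            (5, 1, False),  # 1 enriched is never enough
        ],
    )
    def test_coverage_rule_truth_table(self, n_kes, n_enriched, expect_pass):
        moa, aops, ke_map, groups, universe = self._setup(n_kes, n_enriched)
        fp = aop_fingerprint(moa, aops, ke_map, groups, universe)
        row = fp[fp["aop_id"] == "A1"].iloc[0]
        assert row["n_ke_total"] == n_kes
        assert row["n_enriched_kes"] == n_enriched
        assert bool(row["passed"]) is expect_pass

    def test_grouped_kes_inherit_group_verdict(self):
        # two KEs with identical sets are tested once; both inherit the verdict
        shared = frozenset(f"s{j}" for j in range(30))
        sets = [
            KEGeneSet("Ke01", shared),
            KEGeneSet("Ke02", shared),
            KEGeneSet("Ke03", frozenset(f"o{j}" for j in range(30))),
        ]
        bg = [KEGeneSet(f"Kb{i}", frozenset(f"b{i}_{j}" for j in range(30)))
              for i in range(4)]
        aop = AOP("A1", "t", ("Ke01", "Ke02", "Ke03"))
        bg_aop = AOP("A0", "bg", tuple(s.ke_id for s in bg))
        all_sets = sets + bg
        fp = aop_fingerprint(
            set(shared),
            [aop, bg_aop],
            {s.ke_id: s.genes for s in all_sets},
            group_identical(all_sets),
            default_universe(all_sets),
        )
        row = fp[fp["aop_id"] == "A1"].iloc[0]
        assert row["n_ke_groups"] == 2
        assert row["n_enriched_kes"] == 2  # both members of the enriched group
        assert row["passed"]  # fdr tiny, 2/3 coverage

    def test_monotone_in_enriched_kes(self):
        # flipping a KE group to enriched never turns pass into fail
        for n_enriched in range(0, 8):
            moa_lo, aops, ke_map, groups, universe = self._setup(8, n_enriched)
            moa_hi, *_ = self._setup(8, n_enriched + 1)
            fp_lo = aop_fingerprint(moa_lo, aops, ke_map, groups, universe)
            fp_hi = aop_fingerprint(moa_hi, aops, ke_map, groups, universe)
            lo = bool(fp_lo[fp_lo["aop_id"] == "A1"]["passed"].iloc[0])
            hi = bool(fp_hi[fp_hi["aop_id"] == "A1"]["passed"].iloc[0])
            assert hi >= lo

    def test_planted_aops_recovered_and_top_ranked(self):
        cfg = FixtureConfig(seed=0, ke_duplication_rate=0.0)
        aops, _, ke_sets, truth = simulate_aop_structure(cfg)
        targets = [a for a in aops if a.aop_id in ("Aop001", "Aop002", "Aop003")]
        tables, _ = simulate_moa(cfg, ke_sets, targets)
        moa = pool_moa(tables)
        fp = aop_fingerprint(
            moa,
            aops,
            {s.ke_id: s.genes for s in ke_sets},
            group_identical(ke_sets),
            default_universe(ke_sets),
        )
        target_ids = {a.aop_id for a in targets}
        assert set(fp[fp["passed"]]["aop_id"]) == target_ids
        assert set(fp.head(3)["aop_id"]) == target_ids  # sorted by fdr
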