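"""Robust-network filter, centralities vs brute-force oracles, Borda, specificity."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from aopfinger.io import SourcedEdge
from aopfinger.ranking import (
    borda,
    borda_order,
    build_network,
    centrality_profile,
    density_from_counts,
    graph_stats,
    pf_rank,
    rank_by,
    robustify,
    select_candidates,
    specificity,
)
from aopfinger.simulate import FixtureConfig, simulate_edges


# ---------------------------------------------------------------------------
# brute-force centrality oracles (exhaustive path enumeration, graphs <= 8 nodes)


def _all_shortest_paths(g):
    """{(s, t): (distance, [paths])} via exhaustive simple-path enumeration."""
    out = {}
    for s, t in itertools.permutations(g.nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        dmin = min(len(p) - 1 for p in paths)
        out[(s, t)] = (dmin, [p for p in paths if len(p) - 1 == dmin])
    return out


def oracle_betweenness(g):
    sp = _all_shortest_paths(g)
    n = g.number_of_nodes()
    acc = {v: 0.0 for v in g.nodes}
    for (s, t), (_, paths) in sp.items():
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            acc[v] += through / len(paths)
    if g.is_directed():
        scale = 1.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    else:
        # undirected pairs counted twice in the permutation loop
        scale = 1.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
        for v in acc:
            acc[v] /= 2.0
        scale *= 2.0  # networkx normalization for undirected: 2/((n-1)(n-2))
    return {v: acc[v] * scale for v in acc}


def oracle_closeness(g):
    """Wasserman-Faust closeness on the incoming-distance convention."""
    sp = _all_shortest_paths(g)
    n = g.number_of_nodes()
    out = {}
    for v in g.nodes:
        dists = [d for (s, t), (d, _) in sp.items() if t == v]
        if not dists:
            out[v] = 0.0
            continue
        r = len(dists)  # nodes that can reach v
        out[v] = (r / sum(dists)) * (r / (n - 1))
    return out


def oracle_eigenvector(g):
    """Leading eigenvector from a full symmetric eigendecomposition."""
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    lead = np.abs(v[:, np.argmax(w)])
    lead /= np.linalg.norm(lead)
    return dict(zip(nodes, lead))


class TestRobustify:
    def test_triangle_worked_example(self):
        edges = [
            SourcedEdge.make("A", "B", 5),
            SourcedEdge.make("A", "C", 1),
            SourcedEdge.make("B", "C", 3),
        ]
        kept = {(e.gene_a, e.gene_b) for e in robustify(edges)}
        assert kept == {("A", "B"), ("B", "C")}

    def test_equal_sources_nothing_dropped(self):
        edges = [SourcedEdge.make(a, b, 4) for a, b in [("A", "B"), ("B", "C"), ("A", "C")]]
        assert robustify(edges) == edges

    def test_no_node_isolated_and_output_subset(self):
        rng = np.random.default_rng(23)
        genes = [f"N{i}" for i in range(15)]
        edges = []
        seen = set()
        for _ in range(40):
            a, b = rng.choice(genes, size=2, replace=False)
            key = tuple(sorted((a, b)))
            if key in seen:
                continue
            seen.add(key)
            edges.append(SourcedEdge.make(a, b, int(rng.integers(1, 10))))
        kept = robustify(edges)
        assert set(kept) <= set(edges)
        nodes_before = {n for e in edges for n in (e.gene_a, e.gene_b)}
        nodes_after = {n for e in kept for n in (e.gene_a, e.gene_b)}
        assert nodes_before == nodes_after

    def test_bypass_keeps_everything(self):
        edges = [SourcedEdge("A", "B", 1, directed=True)]
        assert robustify(edges, bypass=True) == edges

    def test_planted_robust_subgraph_recovered(self):
        edges, truth = simulate_edges(FixtureConfig(seed=0))
        kept = {(e.gene_a, e.gene_b) for e in robustify(edges)}
        assert kept == truth["kept_edges"]


class TestCentralities:
    def test_star_center(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        prof = centrality_profile(g)
        assert prof.loc[0, "degree"] == 4
        assert all(prof.loc[i, "degree"] == 1 for i in range(1, 5))
        # all shortest leaf-leaf paths pass the center
        assert prof.loc[0, "betweenness"] == pytest.approx(1.0)

    def test_path_middle_betweenness(self):
        g = nx.path_graph(["A", "B", "C"])
        prof = centrality_profile(g)
        assert prof.loc["B", "betweenness"] == pytest.approx(1.0)  # 1 pair, normalized

    @pytest.mark.parametrize("directed", [False, True])
    def test_matches_exhaustive_oracles_small_graphs(self, directed):
        rng = np.random.default_rng(31)
        for trial in range(6):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e6)), directed=directed)
            if g.number_of_edges() == 0:
                continue
            prof = centrality_profile(g)
            bet = oracle_betweenness(g)
            clo = oracle_closeness(g)
            for v in g.nodes:
                assert prof.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-9)
                assert prof.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-9)
            if not directed and nx.is_connected(g):
                eig = oracle_eigenvector(g)
                for v in g.nodes:
                    assert prof.loc[v, "eigenvector"] == pytest.approx(eig[v], abs=1e-6)


class TestBorda:
    def test_hand_example(self):
        l1 = pd.Series({"a": 1, "b": 2, "c": 3})
        l2 = pd.Series({"c": 1, "a": 2, "b": 3})
        combined = borda([l1, l2])
        assert borda_order(combined) == ["a", "c", "b"]

    def test_identical_lists_identity(self):
        l1 = pd.Series({"a": 1, "b": 2, "c": 3})
        assert borda_order(borda([l1, l1, l1])) == ["a", "b", "c"]

    def test_single_list_identity(self):
        l1 = pd.Series({"x": 1, "y": 2})
        assert borda_order(borda([l1])) == ["x", "y"]

    def test_missing_genes_get_worst_rank_plus_one(self):
        l1 = pd.Series({"a": 1, "b": 2})
        l2 = pd.Series({"a": 1, "b": 2, "c": 3})
        combined = borda([l1, l2])
        # c gets rank 3 in l1's slot (len+1) -> mean 3; b -> 2; a -> 1
        assert borda_order(combined) == ["a", "b", "c"]

    def test_invariant_to_list_permutation(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(12)]
        lists = [
            pd.Series(rng.permutation(len(genes)) + 1.0, index=genes) for _ in range(4)
        ]
        c1 = borda(lists)
        c2 = borda(list(reversed(lists)))
        shuffled = [s.sample(frac=1.0, random_state=7) for s in lists]
        c3 = borda(shuffled)
        assert c1.sort_index().equals(c2.sort_index())
        assert c1.sort_index().equals(c3.sort_index())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            borda([])

    def test_alternative_statistics_agree_on_unanimous_lists(self):
        l1 = pd.Series({"a": 1, "b": 2, "c": 3})
        for method in ("mean", "median", "geometric", "l2"):
            assert borda_order(borda([l1, l1], method)) == ["a", "b", "c"]

    def test_median_variant_resists_one_outlier_list(self):
        lists = [pd.Series({"a": 1, "b": 2, "c": 3})] * 2 + [
            pd.Series({"a": 3, "b": 1, "c": 2})
        ]
        assert borda_order(borda(lists, "median")) == ["a", "b", "c"]


class TestSpecificity:
    SETS = {
        **{f"T{i}": frozenset({"X", "Y"}) for i in range(4)},
        **{f"O{i}": frozenset({"X"}) for i in range(8)},
        "O8": frozenset({"Z"}),
    }

    def test_ratio(self):
        df = specificity(self.SETS, {f"T{i}" for i in range(4)}).set_index("gene")
        assert df.loc["X", "score"] == pytest.approx(4 / 8)

    def test_infinite_specificity_ranks_first(self):
        df = specificity(self.SETS, {f"T{i}" for i in range(4)})
        assert np.isinf(df.set_index("gene").loc["Y", "score"])
        assert df.iloc[0]["gene"] == "Y"

    def test_full_ranking_matches_counting_oracle(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(30)]
        sets = {
            f"K{i}": frozenset(rng.choice(genes, size=8, replace=False))
            for i in range(12)
        }
        targets = {"K0", "K1", "K2"}
        df = specificity(sets, targets)
        for row in df.itertuples(index=False):
            t = sum(1 for k in targets if row.gene in sets[k])
            o = sum(1 for k in sets if k not in targets and row.gene in sets[k])
            assert row.n_target == t
            assert row.n_other == o
        keys = [(-row.score, -row.n_target, row.gene) for row in df.itertuples(index=False)]
        assert keys == sorted(keys)


class TestPfRank:
    def _profiles(self):
        g = nx.Graph()
        g.add_edges_from(
            [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("D", "E"), ("E", "F")]
        )
        return {"ppi": centrality_profile(g)}

    def test_single_ke_single_network_reduces_to_centrality_borda(self):
        profiles = self._profiles()
        genes = frozenset({"A", "B", "E"})
        got = pf_rank({"Ke1": genes}, profiles)
        prof = profiles["ppi"].loc[sorted(genes)]
        lists = [rank_by(prof[c]) for c in ("degree", "betweenness", "closeness", "eigenvector")]
        expected = borda([borda(lists)])
        assert got.sort_index().equals(expected.sort_index())

    def test_gene_top_in_every_ke_is_global_rank_one(self):
        profiles = self._profiles()
        kes = {
            "Ke1": frozenset({"A", "E", "F"}),
            "Ke2": frozenset({"A", "B", "F"}),
            "Ke3": frozenset({"A", "D", "F"}),
        }
        got = pf_rank(kes, profiles)
        assert borda_order(got)[0] == "A"  # hub dominates every centrality

    def test_three_ke_manual_aggregation(self):
        profiles = self._profiles()
        kes = {"Ke1": frozenset({"A", "B"}), "Ke2": frozenset({"B", "E"})}
        got = pf_rank(kes, profiles)
        per_ke = []
        for ke in sorted(kes):
            genes = sorted(kes[ke])
            lists = [
                rank_by(profiles["ppi"].loc[genes, c])
                for c in ("degree", "betweenness", "closeness", "eigenvector")
            ]
            per_ke.append(borda([borda(lists)]))
        expected = borda(per_ke)
        assert got.sort_index().equals(expected.sort_index())

    def test_deterministic_across_runs(self):
        profiles = self._profiles()
        kes = {"Ke1": frozenset({"A", "B", "C"}), "Ke2": frozenset({"D", "E", "F"})}
        spec = {"ke": specificity({**kes, "Other": frozenset({"A", "F"})}, set(kes))}
        r1 = pf_rank(kes, profiles, spec)
        r2 = pf_rank(dict(reversed(list(kes.items()))), profiles, spec)
        assert r1.sort_index().equals(r2.sort_index())


class TestSelectCandidates:
    def _rank(self):
        return pd.Series({f"g{i}": float(i + 1) for i in range(20)})

    def test_full_evidence_is_tier_one(self):
        ev = pd.DataFrame(
            {
                "deg_in_vivo": [True],
                "deg_in_vitro": [True],
                "dose_dep_in_vivo": [True],
                "dose_dep_in_vitro": [True],
            },
            index=["g0"],
        )
        out = select_candidates(self._rank(), ev)
        assert out.loc["g0", "tier"] == 1
        assert out.loc["g0", "selected"]

    def test_no_evidence_pure_rank_order_nothing_selected(self):
        ev = pd.DataFrame(
            columns=["deg_in_vivo", "deg_in_vitro", "dose_dep_in_vivo", "dose_dep_in_vitro"]
        )
        out = select_candidates(self._rank(), ev)
        assert not out["selected"].any()
        assert list(out.index) == [f"g{i}" for i in range(20)]

    def test_tier_rule_table(self):
        ev = pd.DataFrame(
            {
                "deg_in_vivo": [True, False, False, False],
                "deg_in_vitro": [True, True, False, False],
                "dose_dep_in_vivo": [False, False, True, False],
                "dose_dep_in_vitro": [False, False, False, False],
            },
            index=["g0", "g1", "g2", "g3"],
        )
        out = select_candidates(self._rank(), ev)
        assert out.loc["g0", "tier"] == 1  # both deregulated
        assert out.loc["g1", "tier"] == 2  # in vitro only
        assert out.loc["g2", "tier"] == 3  # dose-dependent only
        assert out.loc["g3", "tier"] == 0

    def test_coverage_tier_admits_low_ranked_specific_gene(self):
        ev = pd.DataFrame(
            {
                "deg_in_vivo": [True],
                "deg_in_vitro": [True],
                "dose_dep_in_vivo": [False],
                "dose_dep_in_vitro": [False],
            },
            index=["g0"],
        )
        coverage = {
            "Ke1": frozenset({"g0"}),
            "Ke2": frozenset({"g19"}),  # only coverable by the worst-ranked gene
        }
        out = select_candidates(self._rank(), ev, coverage)
        assert out.loc["g19", "selected"]
        assert out.loc["g19", "tier"] == 4


class TestGraphStats:
    def test_printed_density_examples(self):
        assert round(density_from_counts(20260, 806250), 4) == 0.0039
        assert round(density_from_counts(18754, 363649, directed=True), 3) == 0.001

    def test_complete_graph_density_one(self):
        assert graph_stats(nx.complete_graph(5))["density"] == pytest.approx(1.0)

    def test_tiny_graph_density_zero_with_warning(self):
        g = nx.Graph()
        g.add_node("A")
        assert graph_stats(g)["density"] == 0.0
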