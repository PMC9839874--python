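"""Robust network construction, centrality profiling, Borda aggregation and
specificity scoring for AOP-driven biomarker prioritization.

The robust gene-gene network keeps an edge when its source count reaches the
local mean source count of at least one of its endpoints; this retains edges
of sparsely studied genes instead of imposing one global support threshold.
Genes are then ranked per key event by four centralities (degree,
betweenness, closeness, eigenvector), the rank lists are combined with the
Borda method (arithmetic mean of ranks), combined again with KE- and
AOP-level specificity ranks, and finally aggregated across the target KEs
into one global rank for the adverse outcome of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import SourcedEdge

logger = logging.getLogger(__name__)

__all__ = [
    "robustify",
    "build_network",
    "centrality_profile",
    "rank_by",
    "borda",
    "specificity",
    "pf_rank",
    "select_candidates",
    "graph_stats",
    "density_from_counts",
]

CENTRALITIES = ("degree", "betweenness", "closeness", "eigenvector")


def robustify(edges: list[SourcedEdge], bypass: bool = False) -> list[SourcedEdge]:
    """Local-mean source-count filter for undirected sourced edges.

    For each node v, m(v) is the arithmetic mean of n_sources over v's
    incident edges; edge (u, v) is kept iff n_sources >= m(u) OR
    n_sources >= m(v). With ``bypass=True`` (used for the sparsely sourced
    directed TF network) all edges are kept.
    """
    if bypass:
        return list(edges)
    total: dict[str, float] = {}
    count: dict[str, int] = {}
    for e in edges:
        for node in (e.gene_a, e.gene_b):
            total[node] = total.get(node, 0.0) + e.n_sources
            count[node] = count.get(node, 0) + 1
    mean = {node: total[node] / count[node] for node in total}
    return [
        e for e in edges if e.n_sources >= mean[e.gene_a] or e.n_sources >= mean[e.gene_b]
    ]


def build_network(edges: list[SourcedEdge], directed: bool = False) -> nx.Graph | nx.DiGraph:
    g = nx.DiGraph() if directed else nx.Graph()
    for e in edges:
        g.add_edge(e.gene_a, e.gene_b, n_sources=e.n_sources)
    return g


def centrality_profile(g: nx.Graph | nx.DiGraph) -> pd.DataFrame:
    """Degree, betweenness, closeness and eigenvector centrality per node.

    Directed graphs use total (in+out) degree and directed betweenness and
    closeness. Closeness follows the Wasserman-Faust convention: computed
    within each node's reachable set and scaled by (reachable-1)/(N-1), so
    values are comparable across components. If eigenvector power iteration
    fails to converge on a directed graph, the undirected view is used
    (logged).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=True)
    try:
        eigen = nx.eigenvector_centrality(g, max_iter=1000, tol=1e-10)
    except nx.PowerIterationFailedConvergence:
        logger.warning("eigenvector centrality failed to converge; using undirected view")
        eigen = nx.eigenvector_centrality(g.to_undirected(), max_iter=1000, tol=1e-10)
    df = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=float),
            "betweenness": pd.Series(betweenness, dtype=float),
            "closeness": pd.Series(closeness, dtype=float),
            "eigenvector": pd.Series(eigen, dtype=float),
        }
    )
    df.index.name = "gene"
    return df.sort_index()


def rank_by(scores: pd.Series, descending: bool = True) -> pd.Series:
    """Ranks 1..n (ties share the mean rank); by default high score = rank 1."""
    return scores.rank(ascending=not descending, method="average")


def borda(lists: list[pd.Series], method: str = "mean") -> pd.Series:
    """Borda aggregation of per-list ranks (arithmetic mean by default).

    Each input is a Series of ranks indexed by gene. Genes missing from a
    list receive that list's worst rank + 1 (logged). ``method`` selects the
    rank-combination statistic: "mean", "median", "geometric" or "l2".
    The output is a rank Series over the union of genes, ties re-ranked by
    the combined statistic and broken by gene symbol when ordering.
    """
    if not lists:
        raise ValueError("no rank lists to combine")
    genes = sorted(set().union(*(set(s.index) for s in lists)))
    mat = np.empty((len(genes), len(lists)))
    for j, s in enumerate(lists):
        worst = len(s) + 1
        missing = len(genes) - len(s.index.intersection(genes))
        if missing:
            logger.debug("borda: %d gene(s) missing from list %d get rank %d", missing, j, worst)
        mat[:, j] = s.reindex(genes).fillna(worst).to_numpy()
    if method == "mean":
        combined = mat.mean(axis=1)
    elif method == "median":
        combined = np.median(mat, axis=1)
    elif method == "geometric":
        combined = np.exp(np.log(mat).mean(axis=1))
    elif method == "l2":
        combined = np.sqrt((mat**2).mean(axis=1))
    else:
        raise ValueError(f"unknown borda method {method!r}")
    return pd.Series(combined, index=genes).rank(method="average")


def borda_order(combined: pd.Series) -> list[str]:
    """Gene order implied by a combined rank Series; ties broken by symbol."""
    return sorted(combined.index, key=lambda g: (combined[g], g))


@dataclass(frozen=True)
class SpecificityScore:
    gene: str
    n_target: int
    n_other: int

    @property
    def score(self) -> float:
        if self.n_other == 0:
            return float("inf")
        return self.n_target / self.n_other


def specificity(
    gene_sets: dict[str, frozenset[str]],
    target_ids: set[str],
) -> pd.DataFrame:
    """Occurrence-ratio specificity of each gene for the target KEs (or AOPs).

    n_target counts distinct target sets containing the gene; n_other counts
    the remaining sets. score = n_target/n_other (inf when n_other = 0).
    Genes absent from every set are excluded; ranking is by score descending
    (inf first), then n_target descending, then symbol.
    """
    counts: dict[str, list[int]] = {}
    for set_id, genes in gene_sets.items():
        is_target = set_id in target_ids
        for gene in genes:
            rec = counts.setdefault(gene, [0, 0])
            rec[0 if is_target else 1] += 1
    rows = [
        (gene, t, o, float("inf") if o == 0 else t / o)
        for gene, (t, o) in counts.items()
        if t + o > 0
    ]
    df = pd.DataFrame(rows, columns=["gene", "n_target", "n_other", "score"])
    df = df.sort_values(
        ["score", "n_target", "gene"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def _centrality_ranks(profile: pd.DataFrame, genes: list[str]) -> list[pd.Series]:
    """Four rank lists over ``genes`` from one network's centrality profile.

    Genes absent from the network sit below every present gene (worst rank).
    """
    present = [g for g in genes if g in profile.index]
    ranks = []
    for col in CENTRALITIES:
        scores = profile.loc[present, col]
        r = rank_by(scores)
        worst = len(r) + 1
        full = r.reindex(genes).fillna(worst)
        ranks.append(full)
    return ranks


def pf_rank(
    ke_sets: dict[str, frozenset[str]],
    profiles: dict[str, pd.DataFrame],
    spec_tables: dict[str, pd.DataFrame] | None = None,
    combine: str = "per-network",
) -> pd.Series:
    """Global biomarker rank for the target adverse outcome.

    Per KE: each network contributes four centrality rank lists over the KE's
    genes; with ``combine="per-network"`` (default) the four lists are
    Borda-combined per network and the per-network ranks combined across
    networks; ``combine="pooled"`` pools all lists at once. The per-KE
    centrality rank is then Borda-combined with the specificity rank lists,
    and a final Borda across the target KEs (genes absent from a KE get the
    worst rank + 1) yields the global rank Series (indexed by gene).
    """
    spec_tables = spec_tables or {}
    per_ke_lists: list[pd.Series] = []
    for ke_id in sorted(ke_sets):
        genes = sorted(ke_sets[ke_id])
        if combine == "per-network":
            net_ranks = []
            for name in sorted(profiles):
                lists = _centrality_ranks(profiles[name], genes)
                net_ranks.append(borda(lists))
            cent = borda(net_ranks)
        elif combine == "pooled":
            lists = [
                r for name in sorted(profiles) for r in _centrality_ranks(profiles[name], genes)
            ]
            cent = borda(lists)
        else:
            raise ValueError(f"unknown combine mode {combine!r}")
        to_combine = [cent]
        for level in sorted(spec_tables):
            table = spec_tables[level].set_index("gene")
            scores = table["score"].reindex(genes)
            # inf-specific genes rank first; genes without a score rank last
            filled = scores.fillna(-np.inf)
            to_combine.append(rank_by(filled))
        per_ke_lists.append(borda(to_combine))
    return borda(per_ke_lists)


def select_candidates(
    rank: pd.Series,
    evidence: pd.DataFrame,
    ke_coverage_map: dict[str, frozenset[str]] | None = None,
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """Tiered candidate selection from the global rank plus experimental flags.

    ``evidence`` is indexed by gene with boolean columns deg_in_vivo,
    deg_in_vitro, dose_dep_in_vivo, dose_dep_in_vitro. Tiers follow the
    stated priority: 1) deregulated in vivo AND in vitro (dose-dependency
    emphasized within the tier); 2) deregulated in vitro; 3) not
    differentially expressed but dose-dependent. Tiered genes within the top
    ``top_fraction`` of the global rank are selected; a trailing "coverage"
    tier admits the best-ranked gene of any target KE left uncovered.
    """
    flags = evidence.reindex(rank.index).astype("boolean").fillna(False).astype(bool)
    n_dose = flags[["dose_dep_in_vivo", "dose_dep_in_vitro"]].sum(axis=1)
    tier = pd.Series(0, index=rank.index)
    tier[(~flags["deg_in_vivo"]) & (~flags["deg_in_vitro"]) & (n_dose > 0)] = 3
    tier[flags["deg_in_vitro"]] = 2
    tier[flags["deg_in_vivo"] & flags["deg_in_vitro"]] = 1

    cutoff = max(1, int(np.ceil(top_fraction * len(rank))))
    order = rank.sort_values(kind="mergesort").index
    in_top = pd.Series(False, index=rank.index)
    in_top[order[:cutoff]] = True

    df = pd.DataFrame(
        {"rank": rank, "tier": tier, "n_dose_dep": n_dose, "in_top": in_top}
    )
    df["selected"] = (df["tier"] > 0) & df["in_top"]
    df = df.sort_values(
        ["tier", "n_dose_dep", "rank"],
        ascending=[True, False, True],
        kind="mergesort",
    )

    if ke_coverage_map:
        covered: set[str] = set()
        selected_genes = set(df.index[df["selected"]])
        for ke_id, genes in ke_coverage_map.items():
            if genes & selected_genes:
                covered.add(ke_id)
        extra: set[str] = set()
        for ke_id in sorted(set(ke_coverage_map) - covered):
            genes = [g for g in ke_coverage_map[ke_id] if g in rank.index]
            if not genes:
                continue
            best = min(genes, key=lambda g: (rank[g], g))
            extra.add(best)
        df.loc[sorted(extra - selected_genes), "selected"] = True
        df.loc[sorted(extra - selected_genes), "tier"] = 4  # coverage tier
    df.index.name = "gene"
    return df


def density_from_counts(n_nodes: int, n_edges: int, directed: bool = False) -> float:
    """Graph density from node/edge counts; 0 with a warning when N < 2."""
    if n_nodes < 2:
        logger.warning("density undefined for N < 2; reporting 0")
        return 0.0
    pairs = n_nodes * (n_nodes - 1)
    return n_edges / pairs if directed else 2 * n_edges / pairs


def graph_stats(g: nx.Graph | nx.DiGraph) -> dict[str, float]:
    n, e = g.number_of_nodes(), g.number_of_edges()
    return {
        "n_nodes": n,
        "n_edges": e,
        "density": density_from_counts(n, e, directed=g.is_directed()),
    }
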