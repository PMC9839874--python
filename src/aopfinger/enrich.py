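"""Fisher-exact gene-set over-representation and the AOP fingerprint rule.

Enrichment of a query gene set against a collection of sets is tested with
the one-sided (upper-tail) hypergeometric probability

    p = P(X >= overlap),  X ~ Hypergeom(universe_size, set_size, query_size)

with Benjamini-Hochberg adjustment across all sets tested in one call.

An exposure's mechanism of action (MOA) is the pooled union of filtered DEGs
over all comparisons. Its AOP fingerprint is the set of AOPs that are
themselves enriched (FDR < 0.05) AND whose KE-level coverage passes the rule:
at least 33% of the AOP's KEs enriched, or at least 2 KEs when the AOP has
fewer than six KEs. KEs sharing an identical gene set are tested once as a
group and every member KE inherits the group verdict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grouping import KEGroupTable
from .io import AOP, ChemicalProfile, DEGTable, KEGeneSet, filter_degs

logger = logging.getLogger(__name__)

__all__ = [
    "GeneUniverse",
    "fisher_enrich",
    "screen_chemicals",
    "pool_moa",
    "aop_fingerprint",
    "aop_gene_sets",
    "default_universe",
]


@dataclass(frozen=True)
class GeneUniverse:
    """Background gene population; queries and sets are intersected with it."""

    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def default_universe(ke_sets: list[KEGeneSet]) -> GeneUniverse:
    """Default background: the union of all genes across all KE gene sets."""
    genes: set[str] = set()
    for s in ke_sets:
        genes |= s.genes
    return GeneUniverse(frozenset(genes))


def _bh(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def fisher_enrich(
    query: set[str],
    sets: list[tuple[str, frozenset[str] | set[str]]],
    universe: GeneUniverse,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``query`` against each set.

    Returns a DataFrame with columns set_id, overlap, set_size, query_size,
    universe_size, p, fdr (BH across the sets tested in this call). Empty
    sets get p = 1; an empty query after universe intersection is an error.
    """
    q = set(query) & universe.genes
    if not q:
        raise ValueError("empty query after intersection with the universe")
    M, N = len(universe), len(q)
    rows = []
    for set_id, genes in sets:
        s = set(genes) & universe.genes
        K = len(s)
        k = len(q & s)
        p = 1.0 if K == 0 else float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append((set_id, k, K, N, M, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["set_id", "overlap", "set_size", "query_size", "universe_size", "p"]
    )
    df["fdr"] = _bh(df["p"].to_numpy()) if len(df) else []
    return df


def aop_gene_sets(aops: list[AOP], ke_sets: dict[str, frozenset[str]]) -> list[tuple[str, frozenset[str]]]:
    """Per-AOP gene set: union of the gene sets of its KEs (KEs without a set skipped)."""
    out = []
    for aop in aops:
        genes: set[str] = set()
        for ke_id in aop.ke_ids:
            genes |= ke_sets.get(ke_id, frozenset())
        if genes:
            out.append((aop.aop_id, frozenset(genes)))
        else:
            logger.info("AOP %s excluded: no surviving KE gene sets", aop.aop_id)
    return out


def screen_chemicals(
    chemicals: list[ChemicalProfile],
    aop_sets: list[tuple[str, frozenset[str]]],
    universe: GeneUniverse,
    fdr_cut: float = 0.01,
    top_k: int = 5,
    relevance: dict[str, list[str]] | None = None,
    min_genes: int = 50,
    max_genes: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chemical top-k enriched AOPs and per-category relevance proportions.

    Chemicals outside the gene-count window [min_genes, max_genes] are
    excluded (logged). Significant AOPs (fdr < fdr_cut) are ranked by fdr,
    then raw p, then aop_id; only significant AOPs enter the top-k.
    """
    relevance = relevance or {}
    per_rows = []
    flags: dict[str, tuple[str | None, bool]] = {}
    for chem in sorted(chemicals, key=lambda c: c.chemical_id):
        n = len(chem.genes)
        if not (min_genes <= n <= max_genes):
            logger.info("chemical %s excluded: %d genes outside [%d, %d]",
                        chem.chemical_id, n, min_genes, max_genes)
            continue
        res = fisher_enrich(set(chem.genes), list(aop_sets), universe)
        sig = res[res["fdr"] < fdr_cut].sort_values(
            ["fdr", "p", "set_id"], kind="mergesort"
        )
        top = sig.head(top_k)
        hit = False
        for rank, row in enumerate(top.itertuples(index=False), start=1):
            labels = relevance.get(row.set_id, [])
            per_rows.append(
                (chem.chemical_id, rank, row.set_id, row.p, row.fdr, ";".join(labels))
            )
            if labels:
                hit = True
        category = getattr(chem, "category", None)
        flags[chem.chemical_id] = (category, hit)
    report = pd.DataFrame(
        per_rows, columns=["chemical_id", "rank", "aop_id", "p", "fdr", "labels"]
    )
    cat_rows: dict[str, list[bool]] = {}
    for _, (category, hit) in flags.items():
        cat_rows.setdefault(category or "all", []).append(hit)
    proportions = pd.DataFrame(
        [(cat, float(np.mean(hits)), len(hits)) for cat, hits in sorted(cat_rows.items())],
        columns=["category", "proportion_flagged", "n_chemicals"],
    )
    return report, proportions


def pool_moa(deg_tables: list[DEGTable], fc: float = 1.5, p: float = 0.05) -> set[str]:
    """Pooled MOA: union of filtered DEGs over all comparisons."""
    if not deg_tables:
        raise ValueError("at least one DEG table is required")
    moa: set[str] = set()
    for table in deg_tables:
        moa |= filter_degs(table, fc, p)
    return moa


def aop_fingerprint(
    moa: set[str],
    aops: list[AOP],
    ke_sets: dict[str, frozenset[str]],
    groups: KEGroupTable,
    universe: GeneUniverse,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Two-level enrichment fingerprint of an exposure's pooled MOA.

    AOP-level enrichment runs on union-of-KE-genes sets; KE-level enrichment
    runs once per identical-gene-set group, and every original KE inherits its
    group's verdict. Coverage counts original KEs. The pass rule is:
    AOP fdr < fdr_cut AND (coverage >= 1/3 OR (n_ke_total < 6 AND
    n_enriched_kes >= 2)). Sorted by AOP fdr ascending.
    """
    a_sets = aop_gene_sets(aops, ke_sets)
    kept_aops = {aid for aid, _ in a_sets}
    aop_res = fisher_enrich(moa, a_sets, universe).set_index("set_id")

    # KE-level pass: one test per distinct gene-set group among surviving KEs
    group_ids = sorted(
        {groups.ke_to_group[ke] for ke in ke_sets if ke in groups.ke_to_group}
    )
    g_sets = [(gid, groups.group_sets[gid]) for gid in group_ids]
    ke_res = fisher_enrich(moa, g_sets, universe).set_index("set_id")
    group_enriched = {gid: bool(ke_res.loc[gid, "fdr"] < fdr_cut) for gid in group_ids}

    rows = []
    for aop in aops:
        if aop.aop_id not in kept_aops:
            continue
        n_total = len(aop.ke_ids)
        gids = {
            groups.ke_to_group[ke]
            for ke in aop.ke_ids
            if ke in groups.ke_to_group and ke in ke_sets
        }
        enriched = 0
        for ke_id in aop.ke_ids:
            gid = groups.ke_to_group.get(ke_id)
            if gid is not None and group_enriched.get(gid, False):
                enriched += 1
        coverage = enriched / n_total
        fdr = float(aop_res.loc[aop.aop_id, "fdr"])
        passed = fdr < fdr_cut and (
            coverage >= 1 / 3 or (n_total < 6 and enriched >= 2)
        )
        rows.append((aop.aop_id, float(aop_res.loc[aop.aop_id, "p"]), fdr,
                     len(gids), n_total, enriched, coverage, passed))
    out = pd.DataFrame(
        rows,
        columns=["aop_id", "p", "fdr", "n_ke_groups", "n_ke_total",
                 "n_enriched_kes", "coverage", "passed"],
    )
    return out.sort_values(["fdr", "p", "aop_id"], kind="mergesort").reset_index(drop=True)
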