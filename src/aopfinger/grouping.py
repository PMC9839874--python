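"""Gene-set similarity between KEs, identical-set grouping, AOP network merging.

KEs annotated to identical gene sets (Jaccard index = 1) are grouped; the
grouping drives both enrichment (one test per distinct set) and merging of
redundant nodes in the AOP network. Grouping is implemented by hashing frozen
gene sets; a complete-linkage hierarchical clustering path cut at distance 0
is provided as an equivalent alternative (set equality is transitive, so both
partitions coincide).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import AOP, KEGeneSet, KeyEvent

__all__ = [
    "SimilarityMatrix",
    "KEGroupTable",
    "jaccard",
    "jaccard_matrix",
    "group_identical",
    "build_aop_graph",
    "merge_graph",
    "write_graphml",
]


@dataclass
class SimilarityMatrix:
    ke_ids: list[str]
    values: np.ndarray  # symmetric, diagonal 1, entries in [0, 1]


@dataclass
class KEGroupTable:
    """Partition of KEs by exact gene-set equality.

    group_id is the lexicographically smallest member ke_id.
    """

    ke_to_group: dict[str, str]
    group_sets: dict[str, frozenset[str]]

    @property
    def n_groups(self) -> int:
        return len(self.group_sets)


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def jaccard_matrix(ke_sets: list[KEGeneSet]) -> SimilarityMatrix:
    """Pairwise Jaccard indices between KE gene sets (all sets non-empty)."""
    for s in ke_sets:
        if not s.genes:
            raise ValueError(f"KE {s.ke_id!r} has an empty gene set")
    n = len(ke_sets)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = jaccard(ke_sets[i].genes, ke_sets[j].genes)
    return SimilarityMatrix([s.ke_id for s in ke_sets], values)


def group_identical(ke_sets: list[KEGeneSet], method: str = "hash") -> KEGroupTable:
    """Group KEs whose gene sets are exactly equal (JI = 1).

    method="hash" groups on frozen sets directly; method="linkage" runs
    complete-linkage hierarchical clustering on 1 - JI and cuts at height 0.
    The two paths produce the same partition.
    """
    if method == "hash":
        by_set: dict[frozenset[str], list[str]] = {}
        for s in ke_sets:
            by_set.setdefault(s.genes, []).append(s.ke_id)
        members = list(by_set.items())
    elif method == "linkage":
        if len(ke_sets) == 1:
            members = [(ke_sets[0].genes, [ke_sets[0].ke_id])]
        else:
            sim = jaccard_matrix(ke_sets)
            dist = 1.0 - sim.values
            np.fill_diagonal(dist, 0.0)
            Z = linkage(squareform(dist, checks=False), method="complete")
            labels = fcluster(Z, t=1e-9, criterion="distance")
            clusters: dict[int, list[int]] = {}
            for idx, lab in enumerate(labels):
                clusters.setdefault(int(lab), []).append(idx)
            members = [
                (ke_sets[idxs[0]].genes, [ke_sets[i].ke_id for i in idxs])
                for idxs in clusters.values()
            ]
    else:
        raise ValueError(f"unknown grouping method {method!r}")

    ke_to_group: dict[str, str] = {}
    group_sets: dict[str, frozenset[str]] = {}
    for genes, ids in members:
        gid = min(ids)
        group_sets[gid] = genes
        for ke_id in ids:
            ke_to_group[ke_id] = gid
    return KEGroupTable(ke_to_group, group_sets)


def build_aop_graph(aops: list[AOP], kes: list[KeyEvent] | None = None) -> nx.DiGraph:
    """Directed KE graph over the selected AOPs (unmerged).

    One node per distinct ke_id, annotated with the sorted list of member
    AOPs and the KE role; KER edges carry the list of supporting AOPs.
    """
    roles = {k.ke_id: k.role for k in (kes or [])}
    g = nx.DiGraph(merged=False)
    for aop in aops:
        for ke_id in aop.ke_ids:
            if ke_id not in g:
                g.add_node(ke_id, aop_ids=[], role=roles.get(ke_id, "KE"))
            if aop.aop_id not in g.nodes[ke_id]["aop_ids"]:
                g.nodes[ke_id]["aop_ids"].append(aop.aop_id)
        for up, down in aop.ker_edges:
            if g.has_edge(up, down):
                if aop.aop_id not in g.edges[up, down]["aop_ids"]:
                    g.edges[up, down]["aop_ids"].append(aop.aop_id)
            else:
                g.add_edge(up, down, aop_ids=[aop.aop_id])
    for node in g.nodes:
        g.nodes[node]["aop_ids"] = sorted(g.nodes[node]["aop_ids"])
    for e in g.edges:
        g.edges[e]["aop_ids"] = sorted(g.edges[e]["aop_ids"])
    return g


def merge_graph(g: nx.DiGraph, groups: KEGroupTable) -> tuple[nx.DiGraph, list[str]]:
    """Collapse nodes by gene-set group; report AOPs fully contained in the rest.

    Node attributes are unioned, self-loops dropped, parallel edges collapsed.
    The containment report lists every AOP whose merged node and edge sets are
    subsets of the union over all other AOPs.
    """
    for node in g.nodes:
        if node not in groups.ke_to_group:
            raise ValueError(f"node {node!r} has no gene-set group")
    merged = nx.DiGraph(merged=True)
    for node, data in g.nodes(data=True):
        gid = groups.ke_to_group[node]
        if gid not in merged:
            merged.add_node(gid, aop_ids=[], role=data.get("role", "KE"), members=[])
        nd = merged.nodes[gid]
        nd["aop_ids"] = sorted(set(nd["aop_ids"]) | set(data.get("aop_ids", [])))
        nd["members"] = sorted(set(nd["members"]) | {node})
        if data.get("role") == "AO":
            nd["role"] = "AO"
    for u, v, data in g.edges(data=True):
        gu, gv = groups.ke_to_group[u], groups.ke_to_group[v]
        if gu == gv:
            continue  # self-loop after merging
        if merged.has_edge(gu, gv):
            merged.edges[gu, gv]["aop_ids"] = sorted(
                set(merged.edges[gu, gv]["aop_ids"]) | set(data.get("aop_ids", []))
            )
        else:
            merged.add_edge(gu, gv, aop_ids=sorted(data.get("aop_ids", [])))

    # containment: an AOP adds nothing beyond the union of the others
    aop_nodes: dict[str, set[str]] = {}
    aop_edges: dict[str, set[tuple[str, str]]] = {}
    for node, data in merged.nodes(data=True):
        for aop_id in data["aop_ids"]:
            aop_nodes.setdefault(aop_id, set()).add(node)
    for u, v, data in merged.edges(data=True):
        for aop_id in data["aop_ids"]:
            aop_edges.setdefault(aop_id, set()).add((u, v))
    contained = []
    for aop_id in sorted(aop_nodes):
        other_nodes = set().union(*(aop_nodes[a] for a in aop_nodes if a != aop_id)) if len(aop_nodes) > 1 else set()
        other_edges = set().union(*(aop_edges.get(a, set()) for a in aop_nodes if a != aop_id)) if len(aop_nodes) > 1 else set()
        if aop_nodes[aop_id] <= other_nodes and aop_edges.get(aop_id, set()) <= other_edges:
            contained.append(aop_id)
    return merged, contained


def write_graphml(g: nx.DiGraph, path) -> None:
    """GraphML export; list attributes are serialized as ';'-joined strings."""
    out = g.copy()
    for node, data in out.nodes(data=True):
        for key, val in list(data.items()):
            if isinstance(val, (list, tuple, set)):
                data[key] = ";".join(map(str, sorted(val)))
    for u, v, data in out.edges(data=True):
        for key, val in list(data.items()):
            if isinstance(val, (list, tuple, set)):
                data[key] = ";".join(map(str, sorted(val)))
    nx.write_graphml(out, path)
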