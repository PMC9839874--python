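"""Domain types and tabular readers/writers for the AOP fingerprinting pipeline.

The pipeline consumes flat, AOP-Wiki-style tables:

* ``kes.tsv``        -- ke_id, title, description
* ``aops.tsv``       -- aop_id, title, ke_id, position, role (one row per AOP-KE pair)
* ``ker.tsv``        -- aop_id, upstream_ke, downstream_ke
* ``chemicals.tsv``  -- chemical_id, name, cas, gene (one row per chemical-gene link)
* ``degs.tsv``       -- comparison_id, gene, log2fc, adj_p
* ``edges.tsv``      -- gene_a, gene_b, n_sources, directed
* GMT files for gene-set terms and assembled KE gene sets

All TSVs are UTF-8, tab-separated, header mandatory; empty string means missing.
Gene identity is an opaque upper-case symbol throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "IntegrityError",
    "KeyEvent",
    "AOP",
    "GeneSetTerm",
    "AnnotationMatch",
    "KEGeneSet",
    "ChemicalProfile",
    "DEGTable",
    "SourcedEdge",
    "read_aop_tables",
    "write_aop_tables",
    "read_gmt",
    "write_gmt",
    "read_chemicals",
    "write_chemicals",
    "read_degs",
    "write_degs",
    "read_edges",
    "write_edges",
    "filter_degs",
]

TERM_SOURCES = frozenset(
    {"GO_BP", "GO_MF", "GO_CC", "HPO", "KEGG", "REACTOME", "WIKIPATHWAYS", "GENE"}
)
KE_ROLES = frozenset({"MIE", "KE", "AO"})
MATCH_STATUSES = frozenset({"candidate", "accepted", "rejected", "manual"})


class FormatError(ValueError):
    """A file does not follow the declared tabular format."""


class IntegrityError(ValueError):
    """Cross-references between tables are inconsistent (dangling ids)."""


@dataclass(frozen=True)
class KeyEvent:
    """A key event: one node of an adverse outcome pathway."""

    ke_id: str
    title: str
    description: str = ""
    role: str = "KE"

    def __post_init__(self) -> None:
        if not self.title:
            raise ValueError(f"key event {self.ke_id!r} has an empty title")
        if self.role not in KE_ROLES:
            raise ValueError(f"unknown KE role {self.role!r}")


@dataclass(frozen=True)
class AOP:
    """An adverse outcome pathway: an ordered set of KEs plus KER edges."""

    aop_id: str
    title: str
    ke_ids: tuple[str, ...]
    ker_edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.ke_ids:
            raise ValueError(f"AOP {self.aop_id!r} has no key events")
        members = set(self.ke_ids)
        for up, down in self.ker_edges:
            if up not in members or down not in members:
                raise IntegrityError(
                    f"AOP {self.aop_id!r}: KER edge ({up!r}, {down!r}) references "
                    "a KE outside the AOP"
                )


@dataclass(frozen=True)
class GeneSetTerm:
    """A gene-set term (GO/HPO/KEGG/Reactome/WikiPathways/single-gene style).

    ``genes`` holds human symbols; ``nonhuman_genes`` holds mouse/rat symbols
    used only for the ortholog fallback when ``genes`` is empty.
    """

    term_id: str
    source: str
    name: str
    description: str = ""
    genes: frozenset[str] = frozenset()
    nonhuman_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.source not in TERM_SOURCES:
            raise ValueError(f"unknown term source {self.source!r}")


@dataclass(frozen=True)
class AnnotationMatch:
    """A scored KE-to-term match, NLP-proposed or manually curated."""

    ke_id: str
    term_id: str
    score: float
    rank: int
    status: str = "candidate"

    def __post_init__(self) -> None:
        if self.status not in MATCH_STATUSES:
            raise ValueError(f"unknown match status {self.status!r}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"match score {self.score} outside [0, 1]")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass(frozen=True)
class KEGeneSet:
    """The union of genes over a KE's accepted term matches."""

    ke_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"KE gene set {self.ke_id!r} is empty")


@dataclass(frozen=True)
class ChemicalProfile:
    """A chemical with its associated gene set (CTD-style)."""

    chemical_id: str
    name: str
    cas: str | None = None
    genes: frozenset[str] = frozenset()


@dataclass
class DEGTable:
    """Differential-expression results for one comparison.

    ``frame`` has columns gene, log2fc, adj_p with one row per gene.
    """

    comparison_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"gene", "log2fc", "adj_p"} - set(self.frame.columns)
        if missing:
            raise FormatError(f"DEG table missing columns: {sorted(missing)}")
        if self.frame["gene"].duplicated().any():
            dup = self.frame.loc[self.frame["gene"].duplicated(), "gene"].iloc[0]
            raise IntegrityError(
                f"comparison {self.comparison_id!r}: duplicate gene row {dup!r}"
            )


@dataclass(frozen=True)
class SourcedEdge:
    """A gene-gene edge with the number of supporting data sources.

    Undirected edges are stored with gene_a < gene_b.
    """

    gene_a: str
    gene_b: str
    n_sources: int
    directed: bool = False

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if not self.directed and self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    @staticmethod
    def make(gene_a: str, gene_b: str, n_sources: int, directed: bool = False) -> "SourcedEdge":
        if not directed and gene_a > gene_b:
            gene_a, gene_b = gene_b, gene_a
        return SourcedEdge(gene_a, gene_b, int(n_sources), directed)


# ---------------------------------------------------------------------------
# TSV plumbing


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_aop_tables(aops_path, kes_path, ker_path=None) -> tuple[list[AOP], list[KeyEvent]]:
    """Read the AOP scaffold tables into cross-referenced records.

    Any AOP row or KER edge naming an unknown ke_id raises :class:`IntegrityError`.
    """
    kes_df = _read_tsv(kes_path, ["ke_id", "title", "description"])
    aops_df = _read_tsv(aops_path, ["aop_id", "title", "ke_id", "position", "role"])
    known = set(kes_df["ke_id"])
    if len(known) != len(kes_df):
        raise IntegrityError(f"{kes_path}: duplicate ke_id rows")

    # role is carried per AOP membership row; a KE keeps the single role its
    # memberships agree on, otherwise falls back to the generic "KE"
    roles: dict[str, set[str]] = {}
    aop_rows: dict[str, list] = {}
    aop_titles: dict[str, str] = {}
    for row in aops_df.itertuples(index=False):
        if row.ke_id not in known:
            raise IntegrityError(f"{aops_path}: AOP {row.aop_id!r} references unknown KE {row.ke_id!r}")
        if row.role not in KE_ROLES:
            raise FormatError(f"{aops_path}: unknown role {row.role!r}")
        roles.setdefault(row.ke_id, set()).add(row.role)
        aop_rows.setdefault(row.aop_id, []).append((int(row.position), row.ke_id))
        aop_titles[row.aop_id] = row.title

    ker: dict[str, list[tuple[str, str]]] = {}
    if ker_path is not None:
        ker_df = _read_tsv(ker_path, ["aop_id", "upstream_ke", "downstream_ke"])
        for row in ker_df.itertuples(index=False):
            if row.aop_id not in aop_rows:
                raise IntegrityError(f"{ker_path}: KER for unknown AOP {row.aop_id!r}")
            for endpoint in (row.upstream_ke, row.downstream_ke):
                if endpoint not in known:
                    raise IntegrityError(f"{ker_path}: KER edge to unknown KE {endpoint!r}")
            ker.setdefault(row.aop_id, []).append((row.upstream_ke, row.downstream_ke))

    kes = []
    for row in kes_df.itertuples(index=False):
        role_set = roles.get(row.ke_id, set())
        role = next(iter(role_set)) if len(role_set) == 1 else "KE"
        kes.append(KeyEvent(row.ke_id, row.title, row.description, role))

    aops = []
    for aop_id in sorted(aop_rows):
        ordered = tuple(ke for _, ke in sorted(aop_rows[aop_id]))
        aops.append(AOP(aop_id, aop_titles[aop_id], ordered, tuple(ker.get(aop_id, ()))))
    return aops, kes


def write_aop_tables(aops: list[AOP], kes: list[KeyEvent], aops_path, kes_path, ker_path) -> None:
    roles = {}
    for aop in aops:
        for ke in aop.ke_ids:
            roles.setdefault(ke, None)
    ke_rows = [(k.ke_id, k.title, k.description) for k in kes]
    pd.DataFrame(ke_rows, columns=["ke_id", "title", "description"]).to_csv(
        kes_path, sep="\t", index=False
    )
    role_of = {k.ke_id: k.role for k in kes}
    aop_rows = [
        (a.aop_id, a.title, ke, pos, role_of.get(ke, "KE"))
        for a in aops
        for pos, ke in enumerate(a.ke_ids)
    ]
    pd.DataFrame(aop_rows, columns=["aop_id", "title", "ke_id", "position", "role"]).to_csv(
        aops_path, sep="\t", index=False
    )
    ker_rows = [(a.aop_id, up, down) for a in aops for up, down in a.ker_edges]
    pd.DataFrame(ker_rows, columns=["aop_id", "upstream_ke", "downstream_ke"]).to_csv(
        ker_path, sep="\t", index=False
    )


def read_gmt(path) -> list[GeneSetTerm]:
    """Read a GMT file (name, description, genes...); duplicates deduplicated.

    Term source is not encoded by GMT; terms read this way get source "GENE"
    unless the name carries a ``SOURCE|name`` prefix.
    """
    terms: list[GeneSetTerm] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 2 fields")
            name, description = fields[0], fields[1]
            source = "GENE"
            if "|" in name:
                maybe, rest = name.split("|", 1)
                if maybe in TERM_SOURCES:
                    source, name = maybe, rest
            genes = frozenset(g for g in fields[2:] if g)
            terms.append(GeneSetTerm(name, source, name, description, genes))
    return terms


def write_gmt(sets, path) -> None:
    """Write GeneSetTerm or KEGeneSet records as GMT (genes sorted for stability)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            if isinstance(s, KEGeneSet):
                name, desc, genes = s.ke_id, "", s.genes
            else:
                name = s.term_id if s.source == "GENE" else f"{s.source}|{s.term_id}"
                desc, genes = s.description, s.genes
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_chemicals(path) -> list[ChemicalProfile]:
    df = _read_tsv(path, ["chemical_id", "name", "cas", "gene"])
    out = []
    for cid, grp in df.groupby("chemical_id", sort=True):
        out.append(
            ChemicalProfile(
                chemical_id=cid,
                name=grp["name"].iloc[0],
                cas=grp["cas"].iloc[0] or None,
                genes=frozenset(g for g in grp["gene"] if g),
            )
        )
    return out


def write_chemicals(chemicals: list[ChemicalProfile], path) -> None:
    rows = [
        (c.chemical_id, c.name, c.cas or "", g)
        for c in chemicals
        for g in sorted(c.genes)
    ]
    pd.DataFrame(rows, columns=["chemical_id", "name", "cas", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_degs(path) -> list[DEGTable]:
    df = _read_tsv(path, ["comparison_id", "gene", "log2fc", "adj_p"])
    df = df.assign(
        log2fc=pd.to_numeric(df["log2fc"], errors="coerce"),
        adj_p=pd.to_numeric(df["adj_p"], errors="coerce"),
    )
    return [
        DEGTable(cid, grp[["gene", "log2fc", "adj_p"]].reset_index(drop=True))
        for cid, grp in df.groupby("comparison_id", sort=True)
    ]


def write_degs(tables: list[DEGTable], path) -> None:
    frames = [t.frame.assign(comparison_id=t.comparison_id) for t in tables]
    out = pd.concat(frames, ignore_index=True)
    out[["comparison_id", "gene", "log2fc", "adj_p"]].to_csv(path, sep="\t", index=False)


def read_edges(path) -> list[SourcedEdge]:
    df = _read_tsv(path, ["gene_a", "gene_b", "n_sources", "directed"])
    return [
        SourcedEdge.make(
            r.gene_a, r.gene_b, int(r.n_sources), r.directed.lower() in ("true", "1")
        )
        for r in df.itertuples(index=False)
    ]


def write_edges(edges: list[SourcedEdge], path) -> None:
    rows = [(e.gene_a, e.gene_b, e.n_sources, str(e.directed).lower()) for e in edges]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_sources", "directed"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# DEG filtering


def filter_degs(table: DEGTable, fc_threshold: float = 1.5, p_threshold: float = 0.05) -> set[str]:
    """Genes with |fold change| > fc_threshold (linear scale) and adjusted p < p_threshold.

    Both comparisons are strict, as printed: |log2FC| > log2(fc_threshold) and
    adj_p < p_threshold. Rows with non-finite values are skipped with a warning.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lfc_cut = math.log2(fc_threshold)
    frame = table.frame
    finite = frame["log2fc"].notna() & frame["adj_p"].notna()
    finite &= np.isfinite(frame["log2fc"].astype(float)) & np.isfinite(
        frame["adj_p"].astype(float)
    )
    if not finite.all():
        warnings.warn(
            f"comparison {table.comparison_id!r}: skipped "
            f"{int((~finite).sum())} row(s) with non-finite values",
            stacklevel=2,
        )
    sel = frame[finite]
    keep = (sel["log2fc"].abs() > lfc_cut) & (sel["adj_p"] < p_threshold)
    return set(sel.loc[keep, "gene"])
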