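"""Deterministic synthetic-data generators with planted signal.

Every input shape the pipeline consumes can be simulated: annotation corpora
(term descriptions paraphrased into KE descriptions), AOP scaffolds with
planted duplicate gene sets and one fully contained AOP, chemical-gene
profiles, DEG tables whose pooled union is enriched for chosen target AOPs,
sourced edge lists with an analytically known robust subgraph, dose-response
expression from named models with known benchmark doses, and qPCR Ct tables
with planted dose-responsive genes.

Each generator emits a truth record sufficient to score recovery at its
stage. One global seed cascades to per-generator child streams through fixed
offsets, so identical config + seed reproduce byte-identical outputs while
stages stay independently regenerable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AOP, ChemicalProfile, DEGTable, GeneSetTerm, KEGeneSet, KeyEvent, SourcedEdge

__all__ = [
    "FixtureConfig",
    "simulate_corpus",
    "simulate_aop_structure",
    "simulate_chemicals",
    "simulate_moa",
    "simulate_edges",
    "simulate_dose_response",
    "simulate_ct",
]

# fixed per-generator stream offsets for the seed cascade
_STREAMS = {
    "corpus": 1,
    "aops": 2,
    "chemicals": 3,
    "moa": 4,
    "edges": 5,
    "doseresponse": 6,
    "ct": 7,
}


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic fixtures.

    Defaults emulate the shapes of the real inputs: tens of AOPs of 4-8 KEs,
    hundreds of candidate terms, a gene pool of a couple of thousand symbols,
    CTD-style chemicals of 50-1000 genes, a 20% token paraphrase noise, and
    the bleomycin qPCR dose grid (0, 2.5, 5, 10, 100).
    """

    seed: int = 0
    # corpus
    n_terms: int = 150
    n_kes: int = 50
    vocab_size: int = 600
    tokens_per_description: int = 8
    paraphrase_noise: float = 0.2
    genes_per_term: tuple[int, int] = (20, 120)
    # AOP structure
    n_aops: int = 12
    n_kes_per_aop: tuple[int, int] = (4, 8)
    ke_duplication_rate: float = 0.2
    gene_pool_size: int = 2000
    genes_per_ke: tuple[int, int] = (30, 150)
    # chemicals
    n_chemicals: int = 10
    chemical_genes: tuple[int, int] = (80, 400)
    signal_fraction: float = 0.6
    # MOA / DEG tables
    n_comparisons: int = 3
    moa_signal_fraction: float = 0.6
    background_log2fc_sd: float = 0.6
    # dose response (geometric-ish grid, 6 doses x 4 replicates = 24 obs)
    dr_dose_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
    n_replicates: int = 4
    response_noise_sd: float = 0.2
    # qPCR dose grid (bleomycin exposure design)
    dose_grid: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 100.0)
    # qPCR
    n_ct_genes: int = 25
    n_ct_responsive: int = 5
    samples_per_concentration: int = 5
    ct_noise_sd: float = 0.05

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _gene_pool(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _vocab(n: int) -> list[str]:
    return [f"tok{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# annotation corpus


def simulate_corpus(cfg: FixtureConfig):
    """Terms with descriptions and genes, KEs paraphrasing one true term each.

    Returns (terms, kes, truth) with truth mapping ke_id -> true term_id. A
    KE description is its term's description with each token independently
    swapped for a random vocabulary token with probability paraphrase_noise,
    in shuffled order.
    """
    rng = cfg.rng("corpus")
    vocab = np.array(_vocab(cfg.vocab_size))
    pool = _gene_pool(cfg.gene_pool_size)
    terms: list[GeneSetTerm] = []
    for i in range(cfg.n_terms):
        tokens = rng.choice(vocab, size=cfg.tokens_per_description, replace=False)
        n_genes = int(rng.integers(cfg.genes_per_term[0], cfg.genes_per_term[1] + 1))
        genes = frozenset(rng.choice(pool, size=n_genes, replace=False))
        terms.append(
            GeneSetTerm(
                term_id=f"T{i:04d}",
                source="GO_BP",
                name=f"T{i:04d}",
                description=" ".join(tokens),
                genes=genes,
            )
        )
    kes: list[KeyEvent] = []
    truth: dict[str, str] = {}
    for j in range(cfg.n_kes):
        term = terms[int(rng.integers(0, cfg.n_terms))]
        tokens = term.description.split()
        noisy = [
            str(rng.choice(vocab)) if rng.random() < cfg.paraphrase_noise else t
            for t in tokens
        ]
        rng.shuffle(noisy)
        ke_id = f"Ke{j:04d}"
        kes.append(KeyEvent(ke_id, f"key event {j}", " ".join(noisy)))
        truth[ke_id] = term.term_id
    return terms, kes, truth


# ---------------------------------------------------------------------------
# AOP scaffold


def simulate_aop_structure(cfg: FixtureConfig):
    """AOP/KE/KER scaffold with planted duplicate gene sets and containment.

    Returns (aops, kes, ke_sets, truth) where truth carries the planted
    group partition ("ke_to_group"), the planted contained AOP id
    ("contained_aop"), and the number of distinct gene-set classes
    ("n_groups"). The final AOP duplicates a sub-path of the first AOP with
    fresh ke_ids but identical gene sets, so after merging it adds no node or
    edge.
    """
    rng = cfg.rng("aops")
    pool = np.array(_gene_pool(cfg.gene_pool_size))
    aops: list[AOP] = []
    kes: list[KeyEvent] = []
    ke_sets: list[KEGeneSet] = []
    class_sets: list[frozenset[str]] = []  # distinct gene-set classes, in creation order
    ke_class: dict[str, int] = {}

    def new_class() -> int:
        n_genes = int(rng.integers(cfg.genes_per_ke[0], cfg.genes_per_ke[1] + 1))
        class_sets.append(frozenset(rng.choice(pool, size=n_genes, replace=False)))
        return len(class_sets) - 1

    counter = 0
    for a in range(cfg.n_aops - 1):
        length = int(rng.integers(cfg.n_kes_per_aop[0], cfg.n_kes_per_aop[1] + 1))
        chain = []
        for pos in range(length):
            ke_id = f"Ke{counter:04d}"
            counter += 1
            if class_sets and rng.random() < cfg.ke_duplication_rate:
                cls = int(rng.integers(0, len(class_sets)))
            else:
                cls = new_class()
            role = "MIE" if pos == 0 else ("AO" if pos == length - 1 else "KE")
            kes.append(KeyEvent(ke_id, f"event {ke_id}", f"synthetic event {ke_id}", role))
            ke_sets.append(KEGeneSet(ke_id, class_sets[cls]))
            ke_class[ke_id] = cls
            chain.append(ke_id)
        edges = tuple(zip(chain[:-1], chain[1:]))
        aops.append(AOP(f"Aop{a:03d}", f"pathway {a}", tuple(chain), edges))

    # planted fully contained AOP: duplicate a >=3-KE sub-path of the first AOP
    host = aops[0]
    k = min(len(host.ke_ids), max(3, len(host.ke_ids) - 1))
    start = int(rng.integers(0, len(host.ke_ids) - k + 1))
    sub = host.ke_ids[start : start + k]
    chain = []
    for src in sub:
        ke_id = f"Ke{counter:04d}"
        counter += 1
        cls = ke_class[src]
        kes.append(KeyEvent(ke_id, f"event {ke_id}", f"synthetic duplicate of {src}", "KE"))
        ke_sets.append(KEGeneSet(ke_id, class_sets[cls]))
        ke_class[ke_id] = cls
        chain.append(ke_id)
    contained_id = f"Aop{cfg.n_aops - 1:03d}"
    aops.append(
        AOP(contained_id, "contained pathway", tuple(chain), tuple(zip(chain[:-1], chain[1:])))
    )

    # ground-truth partition, group id = smallest member ke_id
    by_class: dict[int, list[str]] = {}
    for ke_id, cls in ke_class.items():
        by_class.setdefault(cls, []).append(ke_id)
    truth_groups = {}
    for ids in by_class.values():
        gid = min(ids)
        for ke_id in ids:
            truth_groups[ke_id] = gid
    truth = {
        "ke_to_group": truth_groups,
        "contained_aop": contained_id,
        "n_groups": len(by_class),
    }
    return aops, kes, ke_sets, truth


# ---------------------------------------------------------------------------
# chemicals


def simulate_chemicals(cfg: FixtureConfig, aop_sets: list[tuple[str, frozenset[str]]]):
    """CTD-style chemical profiles, each sampling signal_fraction of its genes
    from one labeled target AOP.

    Returns (chemicals, targets, relevance) with targets mapping chemical_id
    -> target aop_id and relevance mapping each target aop_id to a category
    label usable in the screening report.
    """
    rng = cfg.rng("chemicals")
    pool = np.array(_gene_pool(cfg.gene_pool_size))
    chemicals: list[ChemicalProfile] = []
    targets: dict[str, str] = {}
    for i in range(cfg.n_chemicals):
        aop_id, genes = aop_sets[int(rng.integers(0, len(aop_sets)))]
        size = int(rng.integers(cfg.chemical_genes[0], cfg.chemical_genes[1] + 1))
        n_signal = min(int(round(cfg.signal_fraction * size)), len(genes))
        signal = rng.choice(sorted(genes), size=n_signal, replace=False)
        rest = rng.choice(pool, size=size - n_signal, replace=False)
        cid = f"C{i:03d}"
        chemicals.append(
            ChemicalProfile(cid, f"chemical {i}", None, frozenset(signal) | frozenset(rest))
        )
        targets[cid] = aop_id
    relevance = {aop_id: ["target"] for aop_id in set(targets.values())}
    return chemicals, targets, relevance


# ---------------------------------------------------------------------------
# MOA DEG tables


def simulate_moa(
    cfg: FixtureConfig,
    ke_sets: list[KEGeneSet],
    target_aops: list[AOP],
    signal_fraction: float | None = None,
):
    """DEG tables whose pooled, filtered union is enriched for the target AOPs.

    Genes of the target AOPs' KEs are planted as DEGs (|log2FC| well above
    the 1.5-fold cut, small adjusted p) at rate signal_fraction, split across
    comparisons; background genes get null statistics (normal log2FC,
    uniform p). With signal_fraction=0 the tables are pure noise.
    """
    rng = cfg.rng("moa")
    frac = cfg.moa_signal_fraction if signal_fraction is None else signal_fraction
    universe = sorted(set().union(*(s.genes for s in ke_sets)))
    target_kes = {k for a in target_aops for k in a.ke_ids}
    target_genes = sorted(
        set().union(*(s.genes for s in ke_sets if s.ke_id in target_kes))
        if target_kes
        else set()
    )
    planted = set(
        rng.choice(target_genes, size=int(round(frac * len(target_genes))), replace=False)
    ) if target_genes and frac > 0 else set()

    tables = []
    for c in range(cfg.n_comparisons):
        log2fc = rng.normal(0.0, cfg.background_log2fc_sd, size=len(universe))
        adj_p = rng.uniform(0.0, 1.0, size=len(universe))
        frame = pd.DataFrame({"gene": universe, "log2fc": log2fc, "adj_p": adj_p})
        mask = frame["gene"].isin(planted)
        # planted genes deregulated in at least one comparison each
        active = mask & (rng.uniform(size=len(universe)) < 0.7)
        sign = rng.choice([-1.0, 1.0], size=len(universe))
        frame.loc[active, "log2fc"] = sign[active] * rng.uniform(1.0, 3.0, size=int(active.sum()))
        frame.loc[active, "adj_p"] = rng.uniform(0.0, 0.01, size=int(active.sum()))
        tables.append(DEGTable(f"comparison_{c}", frame))
    truth = {"target_aops": [a.aop_id for a in target_aops], "planted_genes": sorted(planted)}
    return tables, truth


# ---------------------------------------------------------------------------
# sourced edges


def simulate_edges(cfg: FixtureConfig, n_core: int = 12, n_periphery: int = 24):
    """Sourced undirected edge list with an analytically known robust subgraph.

    Core genes form a clique of uniformly high-support edges (kept: support
    equals every core node's mean or exceeds it once periphery edges lower
    the mean). Each periphery gene attaches to two core genes with supports 1
    and 5; its local mean is 3, so the 5-edge survives and the 1-edge is
    dropped (it also falls below every core node's mean). The truth record
    lists the surviving edges.
    """
    rng = cfg.rng("edges")
    core = [f"CORE{i:02d}" for i in range(n_core)]
    periphery = [f"PERI{i:02d}" for i in range(n_periphery)]
    edges: list[SourcedEdge] = []
    kept: set[tuple[str, str]] = set()
    for i in range(n_core):
        for j in range(i + 1, n_core):
            e = SourcedEdge.make(core[i], core[j], 8)
            edges.append(e)
            kept.add((e.gene_a, e.gene_b))
    for idx, p in enumerate(periphery):
        a, b = rng.choice(n_core, size=2, replace=False)
        strong = SourcedEdge.make(p, core[int(a)], 5)
        weak = SourcedEdge.make(p, core[int(b)], 1)
        edges.extend([strong, weak])
        kept.add((strong.gene_a, strong.gene_b))
    truth = {"kept_edges": kept}
    return edges, truth


def simulate_tf_edges(cfg: FixtureConfig, n_genes: int = 30, n_edges: int = 60):
    """Directed TF->target edges, single-source (kept unfiltered by design)."""
    rng = cfg.rng("edges")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    seen = set()
    edges = []
    while len(edges) < n_edges:
        a, b = rng.choice(n_genes, size=2, replace=False)
        pair = (genes[int(a)], genes[int(b)])
        if pair in seen:
            continue
        seen.add(pair)
        edges.append(SourcedEdge(pair[0], pair[1], 1, directed=True))
    return edges


# ---------------------------------------------------------------------------
# dose-response expression


def simulate_dose_response(cfg: FixtureConfig, n_linear: int = 5, n_hill: int = 3, n_flat: int = 4):
    """Long expression table (feature, dose, replicate, response) from named
    models with known benchmark doses.

    Linear genes: y = a + b d + noise, true BMD = bmrf * sd / |b|. Hill
    genes: EC50 at a mid dose. Flat genes: noise only (no BMD). Truth maps
    feature -> true BMD (None for flat genes), using the generating noise sd.
    """
    rng = cfg.rng("doseresponse")
    doses = np.array(cfg.dr_dose_grid, dtype=float)
    sd = cfg.response_noise_sd
    bmrf = 1.349
    rows = []
    truth: dict[str, float | None] = {}

    def emit(name: str, f):
        for d in doses:
            mu = f(d)
            for r in range(cfg.n_replicates):
                rows.append((name, d, r, mu + rng.normal(0.0, sd)))

    for i in range(n_linear):
        b = float(rng.uniform(0.5, 2.0)) * float(rng.choice([-1.0, 1.0]))
        a = float(rng.uniform(5.0, 9.0))
        emit(f"LIN{i:02d}", lambda d, a=a, b=b: a + b * d)
        truth[f"LIN{i:02d}"] = bmrf * sd / abs(b)
    dmax = float(doses.max())
    for i in range(n_hill):
        a = float(rng.uniform(5.0, 9.0))
        top = a + float(rng.uniform(2.0, 4.0)) * float(rng.choice([-1.0, 1.0]))
        k = float(rng.uniform(0.15, 0.4)) * dmax  # EC50 inside the tested range
        n = 2.0
        f = lambda d, a=a, top=top, k=k, n=n: a + (top - a) * d**n / (k**n + d**n)
        emit(f"HILL{i:02d}", f)
        # analytic BMD: |top-a| * x/(k^n + x) = bmr with x = d^n
        bmr = bmrf * sd
        amp = abs(top - a)
        if bmr < amp:
            x = bmr * k**n / (amp - bmr)
            truth[f"HILL{i:02d}"] = x ** (1.0 / n)
        else:
            truth[f"HILL{i:02d}"] = None
    for i in range(n_flat):
        a = float(rng.uniform(5.0, 9.0))
        emit(f"FLAT{i:02d}", lambda d, a=a: a)
        truth[f"FLAT{i:02d}"] = None
    frame = pd.DataFrame(rows, columns=["feature", "dose", "replicate", "response"])
    return frame, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables


def simulate_ct(cfg: FixtureConfig, time_points: tuple[int, ...] = (24,)):
    """Ct table with planted dose-responsive genes and a stable reference gene.

    Responsive genes are upregulated: their Ct drops linearly with dose on
    the log2 scale while the reference gene (ACTB) stays flat, so the ddCt
    log2 fold change rises dose-dependently. Truth lists the responsive
    genes.
    """
    rng = cfg.rng("ct")
    doses = list(cfg.dose_grid)
    genes = [f"Q{i:02d}" for i in range(cfg.n_ct_genes)]
    responsive = set(genes[: cfg.n_ct_responsive])
    rows = []
    sample = 0
    for tp in time_points:
        for conc in doses:
            for _ in range(cfg.samples_per_concentration):
                sid = f"S{sample:04d}"
                sample += 1
                rows.append((sid, conc, tp, "ACTB", 20.0 + rng.normal(0.0, cfg.ct_noise_sd)))
                for g in genes:
                    base = 26.0
                    if g in responsive:
                        # saturating upregulation (half-max near the mid doses,
                        # ~2.4 log2 units at the top dose), the typical shape of
                        # an induced transcript
                        base -= 2.5 * conc / (conc + 7.5)
                    rows.append((sid, conc, tp, g, base + rng.normal(0.0, cfg.ct_noise_sd)))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "concentration", "time_point", "gene", "ct"]
    )
    return frame, {"responsive": sorted(responsive)}
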