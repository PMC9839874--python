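"""NLP matching of key-event descriptions to gene-set terms.

Free text is normalized to a bag of tokens (lower-casing, punctuation
stripping, multi-word concept collapsing, stop-word removal, root mapping),
tokens are weighted by inverse document frequency over the combined corpus of
KE and term descriptions, and candidate terms are scored with an IDF-weighted
Jaccard index (JIW):

    JIW(A, B) = sum_{t in A∩B} idf(t) / sum_{t in A∪B} idf(t)

The top-k candidates per KE are emitted for human curation; accepted matches
are merged into one gene set per KE, with an ortholog fallback for terms that
carry no human genes.
"""

from __future__ import annotations

import logging
import math
import re
import string
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .io import AnnotationMatch, GeneSetTerm, IntegrityError, KEGeneSet, KeyEvent

logger = logging.getLogger(__name__)

__all__ = [
    "TokenSet",
    "ConceptDictionary",
    "IdfModel",
    "default_stopwords",
    "default_concepts",
    "preprocess",
    "build_idf",
    "weighted_jaccard",
    "rank_candidates",
    "assemble_ke_gene_set",
    "AnnotationEngine",
]

# Intra-word hyphens are kept: the normalized symbol style the dictionary
# maps to (e.g. "ppar-alpha") must survive re-preprocessing unchanged.
_PUNCT = str.maketrans({c: " " for c in string.punctuation if c != "-"})


@dataclass(frozen=True)
class TokenSet:
    """Normalized bag of tokens for one KE or term description."""

    owner_id: str
    tokens: frozenset[str]


@dataclass
class ConceptDictionary:
    """Multi-word phrase collapses and variant-token root mappings.

    Phrases are applied longest-first before tokenization; roots are applied
    per token afterwards. Every phrase replacement and every root target is
    registered as its own root so the mapping is idempotent.
    """

    phrases: dict[str, str] = field(default_factory=dict)
    roots: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for target in list(self.phrases.values()) + list(self.roots.values()):
            self.roots.setdefault(target, target)

    @classmethod
    def from_tsv(cls, path) -> "ConceptDictionary":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        phrases, roots = {}, {}
        for row in df.itertuples(index=False):
            if row.kind == "phrase":
                phrases[row.pattern.lower()] = row.replacement
            elif row.kind == "root":
                roots[row.pattern.lower()] = row.replacement
            else:
                raise ValueError(f"unknown concept kind {row.kind!r}")
        return cls(phrases, roots)

    def map_root(self, token: str) -> str:
        # iterate to a fixed point so that preprocessing is idempotent
        for _ in range(10):
            if token in self.roots:
                return self.roots[token]
            nxt = _rule_root(token)
            if nxt == token:
                return token
            token = nxt
        return token


def _rule_root(token: str) -> str:
    """Rule-based suffix stripping: plural -s/-es, -ed/-ing with doubling repair.

    Deliberately conservative and auditable; exceptions belong in the
    concept dictionary.
    """
    if len(token) <= 3 or not token.isalpha():
        return token
    for suffix in ("ing", "ed"):
        if token.endswith(suffix) and len(token) - len(suffix) >= 3:
            stem = token[: -len(suffix)]
            if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "aeiou":
                stem = stem[:-1]
            return stem
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("es") and token[-3] in "sxz":
        return token[:-2]
    if token.endswith("s") and not token.endswith(("ss", "is", "us")):
        return token[:-1]
    return token


def default_stopwords() -> frozenset[str]:
    text = resources.files("aopfinger.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


def default_concepts() -> ConceptDictionary:
    with resources.as_file(resources.files("aopfinger.data").joinpath("concepts.tsv")) as p:
        return ConceptDictionary.from_tsv(p)


def preprocess(
    raw_text: str,
    dictionary: ConceptDictionary | None = None,
    stopwords: frozenset[str] | None = None,
    owner_id: str = "",
) -> TokenSet:
    """Normalize free text to a token set.

    Order: lower-case -> punctuation removal -> multi-word concept collapse
    -> whitespace tokenization -> stop-word drop -> root mapping.
    """
    dictionary = dictionary if dictionary is not None else default_concepts()
    stopwords = stopwords if stopwords is not None else default_stopwords()
    text = raw_text.lower().translate(_PUNCT)
    for phrase in sorted(dictionary.phrases, key=len, reverse=True):
        if phrase in text:
            text = re.sub(rf"(?<![\w-]){re.escape(phrase)}(?![\w-])", dictionary.phrases[phrase], text)
    tokens = set()
    for tok in text.split():
        tok = tok.strip("-")
        if not tok or tok in stopwords:
            continue
        tokens.add(dictionary.map_root(tok))
    return TokenSet(owner_id, frozenset(tokens))


@dataclass
class IdfModel:
    """Inverse document frequencies over the combined KE + term corpus.

    idf(t) = ln(n_docs / df(t)); a token never seen is treated as df = 1
    (maximal idf) and logged.
    """

    n_docs: int
    df: dict[str, int]

    def idf(self, token: str) -> float:
        df = self.df.get(token)
        if df is None:
            logger.debug("token %r not in IDF model; treating df=1", token)
            df = 1
        return math.log(self.n_docs / df)


def build_idf(corpus: list[TokenSet]) -> IdfModel:
    if not corpus:
        raise ValueError("corpus must be non-empty")
    df: dict[str, int] = {}
    for doc in corpus:
        for tok in doc.tokens:
            df[tok] = df.get(tok, 0) + 1
    return IdfModel(n_docs=len(corpus), df=df)


def weighted_jaccard(a: TokenSet, b: TokenSet, idf: IdfModel) -> float:
    """IDF-weighted Jaccard score in [0, 1]; 0 when the union weight is 0."""
    union = a.tokens | b.tokens
    # summation in sorted order keeps the score bit-identical regardless of
    # operand order or set iteration order
    denom = sum(idf.idf(t) for t in sorted(union))
    if denom <= 0.0:
        return 0.0
    num = sum(idf.idf(t) for t in sorted(a.tokens & b.tokens))
    return num / denom


def rank_candidates(
    ke_tokens: TokenSet,
    term_tokens: list[TokenSet],
    idf: IdfModel,
    k: int = 5,
) -> list[AnnotationMatch]:
    """Top-k terms by JIW descending; ties broken by term_id ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = sorted(
        ((weighted_jaccard(ke_tokens, tt, idf), tt.owner_id) for tt in term_tokens),
        key=lambda pair: (-pair[0], pair[1]),
    )
    return [
        AnnotationMatch(ke_tokens.owner_id, term_id, score, rank, "candidate")
        for rank, (score, term_id) in enumerate(scored[:k], start=1)
    ]


def assemble_ke_gene_set(
    ke_id: str,
    accepted: list[AnnotationMatch],
    terms: dict[str, GeneSetTerm] | list[GeneSetTerm],
    orthologs: dict[str, str] | None = None,
) -> KEGeneSet | None:
    """Union of genes over accepted/manual matches, with ortholog fallback.

    A term with no human genes contributes the human orthologs of its
    mouse/rat genes; if no term yields any gene the KE is dropped (None).
    """
    if not isinstance(terms, dict):
        terms = {t.term_id: t for t in terms}
    orthologs = orthologs or {}
    genes: set[str] = set()
    used = [m for m in accepted if m.ke_id == ke_id and m.status in ("accepted", "manual")]
    if len(used) > 5:
        raise ValueError(f"KE {ke_id!r} has more than 5 accepted matches")
    for match in used:
        term = terms.get(match.term_id)
        if term is None:
            raise IntegrityError(f"accepted match references unknown term {match.term_id!r}")
        if term.genes:
            genes |= term.genes
        else:
            mapped = {orthologs[g] for g in term.nonhuman_genes if g in orthologs}
            genes |= mapped
    if not genes:
        logger.info("KE %s dropped: no resolvable genes in any accepted term", ke_id)
        return None
    return KEGeneSet(ke_id, frozenset(genes))


class AnnotationEngine:
    """End-to-end annotation: preprocessing, IDF over the joint corpus, ranking.

    The IDF corpus is the union of all KE descriptions and all term
    descriptions, matching the definition of document frequency used by the
    weighting.
    """

    def __init__(
        self,
        kes: list[KeyEvent],
        terms: list[GeneSetTerm],
        dictionary: ConceptDictionary | None = None,
        stopwords: frozenset[str] | None = None,
    ):
        self.dictionary = dictionary if dictionary is not None else default_concepts()
        self.stopwords = stopwords if stopwords is not None else default_stopwords()
        self.terms = {t.term_id: t for t in terms}
        # descriptions carry the matching signal; the title/name is the
        # fallback for records without one
        self.ke_tokens = {
            ke.ke_id: preprocess(
                ke.description or ke.title, self.dictionary, self.stopwords, ke.ke_id
            )
            for ke in kes
        }
        self.term_tokens = [
            preprocess(t.description or t.name, self.dictionary, self.stopwords, t.term_id)
            for t in terms
        ]
        self.idf = build_idf(list(self.ke_tokens.values()) + self.term_tokens)

    def rank(self, ke_id: str, k: int = 5) -> list[AnnotationMatch]:
        return rank_candidates(self.ke_tokens[ke_id], self.term_tokens, self.idf, k)

    def rank_all(self, k: int = 5) -> pd.DataFrame:
        rows = [
            (m.ke_id, m.term_id, m.score, m.rank, m.status)
            for ke_id in sorted(self.ke_tokens)
            for m in self.rank(ke_id, k)
        ]
        return pd.DataFrame(rows, columns=["ke_id", "term_id", "score", "rank", "status"])
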