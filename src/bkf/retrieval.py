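"""Coarse candidate generation: expansion-based documents + Okapi BM25.

Each hierarchy term is turned into a pseudo-document and indexed; each KG
entity is turned into a query the same way. Both sides can be *expanded*
beyond the bare surface name with

* attributive information — synonyms and the free-text definition, and/or
* structural information — names of one-hop graph neighbors (for an
  entity: KG neighbors in either triple direction; for a term: hierarchy
  parents and children).

The four expansion combinations (Name, +Atr, +Str, +Atr+Str) form the
ablation axis of the retriever. Ranking uses Okapi BM25 with the
nonnegative idf variant

    idf(q) = ln(1 + (N - df(q) + 0.5) / (df(q) + 0.5))

so a query sharing no token with a document scores exactly 0. Ties are
broken by lexicographic term id, making retrieval fully deterministic.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .models import Entity, Hierarchy, KnowledgeGraph, Term

__all__ = [
    "ExpansionStrategy",
    "tokenize",
    "build_document",
    "BM25Index",
    "index_terms",
    "bm25_score",
    "retrieve",
    "CandidateList",
]

_TOKEN = re.compile(r"[^\W_]+", re.UNICODE)

#: default cap on the number of structural neighbors folded into a document
DEFAULT_NEIGHBOR_CAP = 16


def tokenize(text: str) -> list[str]:
    """Casefold and split on maximal runs of non-alphanumeric characters.

    No stemming and no stopword removal; empty input yields an empty list.
    """
    return _TOKEN.findall(text.casefold())


@dataclass(frozen=True)
class ExpansionStrategy:
    """Which information expands a query/document beyond the surface name."""

    use_attributes: bool = False
    use_structure: bool = False

    _NAMES = {
        "name": (False, False),
        "atr": (True, False),
        "str": (False, True),
        "atr+str": (True, True),
    }

    @classmethod
    def from_name(cls, name: str) -> "ExpansionStrategy":
        key = name.lower().replace(" ", "")
        if key not in cls._NAMES:
            raise ValueError(f"unknown strategy {name!r}; expected one of {sorted(cls._NAMES)}")
        return cls(*cls._NAMES[key])

    @property
    def label(self) -> str:
        for k, v in self._NAMES.items():
            if v == (self.use_attributes, self.use_structure):
                return k
        raise AssertionError


def build_document(
    item: Entity | Term,
    graph_context: KnowledgeGraph | Hierarchy,
    strategy: ExpansionStrategy,
    *,
    neighbor_cap: int = DEFAULT_NEIGHBOR_CAP,
    term_structure: str = "parents+children",
) -> str:
    """Render the expanded pseudo-document of an entity or term.

    Segments, joined by single spaces and in fixed order: the surface name;
    if attributes are enabled, all synonyms then the definition; if
    structure is enabled, names of one-hop neighbors — for an entity the KG
    neighbors in either triple direction, for a term its parents then
    children (``term_structure="parents"`` restricts to parents only) —
    deduplicated, in lexicographic id order per group, capped at
    *neighbor_cap* names in total.
    """
    parts: list[str] = [item.name]
    if strategy.use_attributes:
        parts.extend(item.synonyms)
        if item.definition:
            parts.append(item.definition)
    if strategy.use_structure:
        if isinstance(item, Entity):
            if not isinstance(graph_context, KnowledgeGraph):
                raise TypeError("entity documents need a KnowledgeGraph context")
            neighbor_ids = graph_context.neighbors(item.id)[:neighbor_cap]
            parts.extend(graph_context[n].name for n in neighbor_ids)
        else:
            if not isinstance(graph_context, Hierarchy):
                raise TypeError("term documents need a Hierarchy context")
            if term_structure not in ("parents", "parents+children"):
                raise ValueError(f"unknown term_structure {term_structure!r}")
            ids = graph_context.parents(item.id)
            if term_structure == "parents+children":
                ids = ids + [
                    c for c in graph_context.children(item.id) if c not in set(ids)
                ]
            parts.extend(graph_context[n].name for n in ids[:neighbor_cap])
    return " ".join(p for p in parts if p)


class BM25Index:
    """Token statistics of the term corpus plus the k1/b parameters.

    Documents are aligned with hierarchy term ids. ``tf[doc_id]`` maps
    token → frequency in that document; ``df`` is corpus document
    frequency; ``avgdl`` the mean document length in tokens.
    """

    def __init__(
        self,
        docs: dict[str, list[str]],
        k1: float = 1.5,
        b: float = 0.75,
    ) -> None:
        if k1 < 0 or b < 0:
            raise ValueError("k1 and b must be nonnegative")
        self.k1 = k1
        self.b = b
        self.doc_ids: list[str] = sorted(docs)
        self.tf: dict[str, Counter[str]] = {d: Counter(docs[d]) for d in self.doc_ids}
        self.doc_len: dict[str, int] = {d: len(docs[d]) for d in self.doc_ids}
        self.n_docs: int = len(self.doc_ids)
        self.avgdl: float = (
            sum(self.doc_len.values()) / self.n_docs if self.n_docs else 0.0
        )
        self.df: Counter[str] = Counter()
        self._postings: dict[str, list[str]] = {}
        for d in self.doc_ids:
            for tok in self.tf[d]:
                self.df[tok] += 1
                self._postings.setdefault(tok, []).append(d)

    def idf(self, token: str) -> float:
        df = self.df.get(token, 0)
        if df == 0:
            return 0.0
        return math.log(1.0 + (self.n_docs - df + 0.5) / (df + 0.5))


def index_terms(
    h: Hierarchy,
    strategy: ExpansionStrategy,
    k1: float = 1.5,
    b: float = 0.75,
    *,
    neighbor_cap: int = DEFAULT_NEIGHBOR_CAP,
    term_structure: str = "parents+children",
) -> BM25Index:
    """Index every hierarchy term as one expanded document."""
    if len(h) == 0:
        raise ValueError("cannot index an empty hierarchy")
    docs = {
        tid: tokenize(
            build_document(
                h[tid], h, strategy,
                neighbor_cap=neighbor_cap, term_structure=term_structure,
            )
        )
        for tid in h.terms
    }
    return BM25Index(docs, k1=k1, b=b)


def bm25_score(index: BM25Index, query_tokens: Sequence[str], doc_id: str) -> float:
    """Okapi BM25 score of one document for a tokenized query.

    score = Σ_q idf(q) · tf(q,d)(k1+1) / (tf(q,d) + k1(1 − b + b·|d|/avgdl))
    """
    if doc_id not in index.tf:
        raise KeyError(f"unknown doc id {doc_id!r}")
    tf = index.tf[doc_id]
    norm = index.k1 * (1.0 - index.b + index.b * index.doc_len[doc_id] / index.avgdl)
    score = 0.0
    for q in query_tokens:
        f = tf.get(q, 0)
        if f:
            score += index.idf(q) * f * (index.k1 + 1.0) / (f + norm)
    return score


@dataclass(frozen=True)
class CandidateList:
    """Top-K coarsely ranked terms for one query entity."""

    entity_id: str
    ranked: tuple[tuple[str, float], ...]
    strategy: ExpansionStrategy

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranked", tuple((t, float(s)) for t, s in self.ranked))
        ids = [t for t, _ in self.ranked]
        if len(set(ids)) != len(ids):
            raise ValueError("candidate term ids must be distinct")
        scores = [s for _, s in self.ranked]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("candidate scores must be non-increasing")

    @property
    def term_ids(self) -> list[str]:
        return [t for t, _ in self.ranked]


def retrieve(
    kg: KnowledgeGraph,
    h: Hierarchy,
    index: BM25Index,
    entity_id: str,
    K: int = 20,
    strategy: ExpansionStrategy = ExpansionStrategy(),
    *,
    neighbor_cap: int = DEFAULT_NEIGHBOR_CAP,
) -> CandidateList:
    """Rank hierarchy terms for one entity and keep the top K.

    The query is the entity's expanded document, tokenized. Ties are broken
    by lexicographic term id. If K exceeds the number of terms, all terms
    are returned with a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    query = tokenize(build_document(kg[entity_id], kg, strategy, neighbor_cap=neighbor_cap))
    if K > index.n_docs:
        warnings.warn(
            f"K={K} exceeds the number of indexed terms ({index.n_docs}); returning all",
            stacklevel=2,
        )
        K = index.n_docs
    # accumulate scores via postings; docs sharing no token stay at 0
    scores: dict[str, float] = {d: 0.0 for d in index.doc_ids}
    for q in set(query):
        qf = query.count(q)  # multiplicity handled below
        postings = index._postings.get(q)
        if not postings:
            continue
        idf = index.idf(q)
        for d in postings:
            f = index.tf[d][q]
            norm = index.k1 * (1.0 - index.b + index.b * index.doc_len[d] / index.avgdl)
            scores[d] += qf * idf * f * (index.k1 + 1.0) / (f + norm)
    top = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:K]
    return CandidateList(entity_id=entity_id, ranked=tuple(top), strategy=strategy)
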