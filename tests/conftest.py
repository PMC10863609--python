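"""Shared fixtures: tiny hand-built hierarchies, random DAGs, and the
default synthetic benchmark, plus independent brute-force oracles used to
cross-check BM25, Wu-Palmer and DCG."""

from __future__ import annotations

import math
import random

import pytest

from bkf.models import Hierarchy, KnowledgeGraph, Entity, Term, Triple
from bkf.synthetic import GeneratorConfig, generate_benchmark

# ---------------------------------------------------------------------------
# Brute-force oracles (independent transcriptions, never the implementation)
# ---------------------------------------------------------------------------


def naive_bm25(docs: dict[str, list[str]], query: list[str], doc_id: str,
               k1: float = 1.5, b: float = 0.75) -> float:
    """Literal Okapi BM25 transcription over a dict of token lists."""
    n = len(docs)
    avgdl = sum(len(d) for d in docs.values()) / n
    score = 0.0
    for q in query:
        df = sum(1 for d in docs.values() if q in d)
        if df == 0:
            continue
        idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
        tf = docs[doc_id].count(q)
        if tf == 0:
            continue
        score += idf * tf * (k1 + 1) / (tf + k1 * (1 - b + b * len(docs[doc_id]) / avgdl))
    return score


class BruteDag:
    """Naive ancestor/depth/distance queries over a parent map."""

    def __init__(self, parents: dict[str, list[str]]):
        self.parents = parents

    def ancestors(self, t: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.parents[t])
        while stack:
            x = stack.pop()
            if x not in out:
                out.add(x)
                stack.extend(self.parents[x])
        return out

    def depth(self, t: str) -> int:
        if not self.parents[t]:
            return 1
        return 1 + min(self.depth(p) for p in self.parents[t])

    def updist(self, a: str, c: str) -> int:
        """Shortest upward hop count a → c (must be a or an ancestor of a)."""
        if a == c:
            return 0
        best = math.inf
        for p in self.parents[a]:
            if p == c or c in self.ancestors(p) | {p}:
                best = min(best, 1 + self.updist(p, c))
        assert best < math.inf
        return int(best)

    def wup(self, a: str, b: str) -> float:
        common = (self.ancestors(a) | {a}) & (self.ancestors(b) | {b})
        best = 0.0
        for c in common:
            d = self.depth(c)
            score = 2.0 * d / (2.0 * d + self.updist(a, c) + self.updist(b, c))
            best = max(best, score)
        return best


def naive_dcg(rels: list[float]) -> float:
    return sum((2.0 ** r - 1.0) / math.log2(i + 2) for i, r in enumerate(rels))


def random_dag(rng: random.Random, n: int = 30, p_extra: float = 0.3,
               p_new_root: float = 0.1) -> tuple[Hierarchy, dict[str, list[str]]]:
    """A random multi-root DAG plus its parent map for the brute oracle."""
    ids = [f"n{i:02d}" for i in range(n)]
    parents: dict[str, list[str]] = {ids[0]: []}
    edges: list[tuple[str, str]] = []
    for i in range(1, n):
        if rng.random() < p_new_root:
            parents[ids[i]] = []
            continue
        p1 = ids[rng.randrange(i)]
        parents[ids[i]] = [p1]
        edges.append((ids[i], p1))
        if rng.random() < p_extra:
            p2 = ids[rng.randrange(i)]
            if p2 != p1:
                parents[ids[i]].append(p2)
                edges.append((ids[i], p2))
    terms = [Term(id=t, name=f"node {t}") for t in ids]
    return Hierarchy(terms, edges), parents


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture()
def chain_h() -> Hierarchy:
    """r → a → b → c (c is the deepest leaf)."""
    terms = [
        Term(id="r", name="disease"),
        Term(id="a", name="typhus"),
        Term(id="b", name="epidemic typhus"),
        Term(id="c", name="louse borne typhus"),
    ]
    return Hierarchy(terms, [("a", "r"), ("b", "a"), ("c", "b")])


@pytest.fixture()
def diamond_h() -> Hierarchy:
    """d has parents b and c; b and c are children of r."""
    terms = [Term(id=t, name=f"term {t}") for t in "rbcd"]
    return Hierarchy(terms, [("b", "r"), ("c", "r"), ("d", "b"), ("d", "c")])


@pytest.fixture()
def small_kg() -> KnowledgeGraph:
    entities = [
        Entity(id="e1", name="immune suppression", synonyms=("immunosuppression",),
               definition="reduced immune response"),
        Entity(id="e2", name="epidemic typhus"),
        Entity(id="e3", name="drug x"),
    ]
    triples = [Triple("e1", "treats", "e2"), Triple("e3", "treats", "e1")]
    return KnowledgeGraph(entities, triples)


@pytest.fixture(scope="session")
def bench17():
    """The default synthetic benchmark: seed 17, 1000 terms, 200 entities."""
    return generate_benchmark(GeneratorConfig(seed=17))


@pytest.fixture(scope="session")
def bench_small():
    """A small fast benchmark for structural tests."""
    return generate_benchmark(GeneratorConfig(seed=5, n_terms=60, n_entities=20,
                                              max_depth=6))
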