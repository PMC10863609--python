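"""Expansion-based documents and Okapi BM25 candidate generation."""

from __future__ import annotations

import random

import pytest

from bkf.evaluation import hits_at_k
from bkf.models import Entity, Hierarchy, KnowledgeGraph, Term, Triple
from bkf.retrieval import (
    BM25Index,
    ExpansionStrategy,
    bm25_score,
    build_document,
    index_terms,
    retrieve,
    tokenize,
)

from conftest import naive_bm25


@pytest.mark.parametrize(
    ("text", "expected"),
    [
        ("Typhus, Epidemic Louse-Borne", ["typhus", "epidemic", "louse", "borne"]),
        ("", []),
        ("immune   system–disease", ["immune", "system", "disease"]),
        ("BRCA1-positive", ["brca1", "positive"]),
    ],
)
def test_tokenize(text, expected):
    assert tokenize(text) == expected


class TestBuildDocument:
    def test_name_only_is_identity(self, small_kg):
        doc = build_document(small_kg["e1"], small_kg, ExpansionStrategy())
        assert doc == "immune suppression"

    def test_attributes_append_synonyms_then_definition(self, chain_h):
        term = Term(id="x", name="epidemic typhus", synonyms=("louse-borne typhus",))
        h = Hierarchy([term], [])
        doc = build_document(term, h, ExpansionStrategy(use_attributes=True))
        assert doc == "epidemic typhus louse-borne typhus"

    def test_term_structure_is_one_hop(self, chain_h):
        doc = build_document(chain_h["b"], chain_h, ExpansionStrategy(use_structure=True))
        assert chain_h["a"].name in doc and chain_h["c"].name in doc
        assert chain_h["r"].name.split()[0] not in tokenize(doc)

    def test_term_structure_parents_only_flag(self, chain_h):
        doc = build_document(chain_h["b"], chain_h, ExpansionStrategy(use_structure=True),
                             term_structure="parents")
        assert chain_h["a"].name in doc and chain_h["c"].name not in doc

    def test_entity_structure_both_directions(self, small_kg):
        doc = build_document(small_kg["e1"], small_kg, ExpansionStrategy(use_structure=True))
        # e1 has an outgoing triple to e2 and an incoming one from e3
        assert "epidemic typhus" in doc and "drug x" in doc

    def test_neighbor_cap(self):
        ents = [Entity(id=f"e{i:02d}", name=f"name {i}") for i in range(30)]
        triples = [Triple("e00", "rel", f"e{i:02d}") for i in range(1, 30)]
        kg = KnowledgeGraph(ents, triples)
        doc = build_document(kg["e00"], kg, ExpansionStrategy(use_structure=True),
                             neighbor_cap=5)
        assert doc == "name 0 " + " ".join(f"name {i}" for i in range(1, 6))


class TestIndex:
    def test_stats(self, chain_h):
        idx = index_terms(chain_h, ExpansionStrategy())
        assert idx.n_docs == 4
        assert idx.avgdl == pytest.approx(sum(idx.doc_len.values()) / 4)
        assert max(idx.df.values()) <= idx.n_docs

    def test_avgdl_arithmetic(self):
        idx = BM25Index({"a": ["x", "y"], "b": ["x", "z"], "c": list("abcde")})
        assert idx.avgdl == 3.0

    def test_determinism(self, chain_h):
        i1 = index_terms(chain_h, ExpansionStrategy(True, True))
        i2 = index_terms(chain_h, ExpansionStrategy(True, True))
        assert i1.tf == i2.tf and i1.df == i2.df and i1.avgdl == i2.avgdl


class TestBM25Score:
    def test_zero_overlap_scores_zero(self):
        idx = BM25Index({"d1": ["lung", "cancer"], "d2": ["immune", "disease"]})
        assert bm25_score(idx, ["typhus"], "d1") == 0.0

    def test_symmetric_documents_tie(self):
        idx = BM25Index({
            "d1": ["lung", "cancer"],
            "d2": ["breast", "cancer"],
            "d3": ["immune", "system", "disease"],
        })
        s1 = bm25_score(idx, ["cancer"], "d1")
        s2 = bm25_score(idx, ["cancer"], "d2")
        s3 = bm25_score(idx, ["cancer"], "d3")
        assert s3 == 0.0 and s1 == s2 > 0.0

    def test_unknown_doc(self):
        idx = BM25Index({"d1": ["a"]})
        with pytest.raises(KeyError):
            bm25_score(idx, ["a"], "dX")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_transcription(self, seed):
        rng = random.Random(seed)
        vocab = [f"w{i}" for i in range(12)]
        docs = {
            f"d{j}": [rng.choice(vocab) for _ in range(rng.randint(1, 8))]
            for j in range(rng.randint(2, 8))
        }
        idx = BM25Index(docs)
        query = [rng.choice(vocab + ["unseen"]) for _ in range(rng.randint(1, 5))]
        for d in docs:
            assert bm25_score(idx, query, d) == pytest.approx(
                naive_bm25(docs, query, d), abs=1e-9)


def _tiny_world():
    terms = [
        Term(id="t1", name="lung cancer"),
        Term(id="t2", name="breast cancer"),
        Term(id="t3", name="immune system disease"),
    ]
    h = Hierarchy(terms, [("t2", "t1"), ("t3", "t1")])
    kg = KnowledgeGraph([Entity(id="e1", name="immune disorder")])
    return kg, h


class TestRetrieve:
    def test_unique_match_ranked_first(self):
        kg, h = _tiny_world()
        idx = index_terms(h, ExpansionStrategy())
        cand = retrieve(kg, h, idx, "e1", K=3)
        assert cand.term_ids[0] == "t3"

    def test_all_zero_scores_lexicographic(self):
        h = Hierarchy([Term(id=t, name=f"name {t}") for t in ("tb", "ta", "tc")], [])
        kg = KnowledgeGraph([Entity(id="e1", name="zzz")])
        idx = index_terms(h, ExpansionStrategy())
        cand = retrieve(kg, h, idx, "e1", K=2)
        assert cand.term_ids == ["ta", "tb"]
        assert all(s == 0.0 for _, s in cand.ranked)

    def test_k_larger_than_corpus_warns(self):
        kg, h = _tiny_world()
        idx = index_terms(h, ExpansionStrategy())
        with pytest.warns(UserWarning, match="exceeds"):
            cand = retrieve(kg, h, idx, "e1", K=10)
        assert len(cand.ranked) == 3

    def test_deterministic(self, bench_small):
        kg, h = bench_small.kg, bench_small.hierarchy
        strat = ExpansionStrategy(True, True)
        idx = index_terms(h, strat)
        eid = next(iter(kg.entities))
        c1 = retrieve(kg, h, idx, eid, K=10, strategy=strat)
        c2 = retrieve(kg, h, idx, eid, K=10, strategy=strat)
        assert c1 == c2

    def test_recall_monotone_in_k(self, bench_small):
        kg, h, gold = bench_small.kg, bench_small.hierarchy, bench_small.gold
        idx = index_terms(h, ExpansionStrategy())
        preds = {e: retrieve(kg, h, idx, e, K=20).term_ids for e in gold.as_dict()}
        recalls = [hits_at_k(preds, gold, k) for k in (1, 2, 5, 10, 20)]
        assert recalls == sorted(recalls)

    def test_duplicating_corpus_preserves_order(self):
        rng = random.Random(3)
        vocab = [f"w{i}" for i in range(10)]
        docs = {f"d{j}": [rng.choice(vocab) for _ in range(rng.randint(1, 6))]
                for j in range(5)}
        query = [rng.choice(vocab) for _ in range(4)]
        idx1 = BM25Index(docs)
        doubled = dict(docs)
        doubled.update({f"{k}_copy": v for k, v in docs.items()})
        idx2 = BM25Index(doubled)
        order1 = sorted(docs, key=lambda d: (-bm25_score(idx1, query, d), d))
        order2 = sorted(docs, key=lambda d: (-bm25_score(idx2, query, d), d))
        assert order1 == order2
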