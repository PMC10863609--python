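"""Strict and lenient ranking metrics for entity→term alignment.

Strict metrics credit only the exact gold term: Hits@k (gold within the
top k) and MRR (mean reciprocal rank of the gold term, 0 when absent).

Lenient metrics also reward *near* hits in the hierarchy:

* WuP — Wu-Palmer relatedness 2·depth(lcs)/(depth(a)+depth(b)), where lcs
  is the deepest common ancestor of the two terms (a term counts as its
  own ancestor); reported as the mean WuP between the top-1 prediction and
  the gold term. Terms in disjoint components have WuP 0, and roots have
  depth 1, so WuP of co-rooted terms is strictly positive.
* nDCG@k with exponential decay — graded relevance rel(t) = WuP(t, gold),
  gain 2^rel − 1, discount log2(rank+1); the ideal DCG is computed over
  the *whole* term set, not just the retrieved candidates, so a poor
  retriever cannot inflate its own normalizer.

Queries with a missing or empty prediction list count as misses, never as
errors: retrieval failures must be punished, not crash the evaluation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .models import AlignmentSet, Hierarchy

__all__ = [
    "hits_at_k",
    "mrr",
    "wup",
    "ndcg_at_k",
    "top1_wup",
    "EvalReport",
    "evaluate_run",
]

Predictions = Mapping[str, Sequence[str]]


def _gold_dict(gold: AlignmentSet | Mapping[str, str]) -> dict[str, str]:
    return gold.as_dict() if isinstance(gold, AlignmentSet) else dict(gold)


def hits_at_k(preds: Predictions, gold: AlignmentSet | Mapping[str, str], k: int) -> float:
    """Fraction of gold entities whose gold term is ranked in the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    g = _gold_dict(gold)
    if not g:
        raise ValueError("empty gold set")
    hit = sum(1 for e, t in g.items() if t in list(preds.get(e, ()))[:k])
    return hit / len(g)


def mrr(preds: Predictions, gold: AlignmentSet | Mapping[str, str]) -> float:
    """Mean reciprocal rank of the gold term; 0 when not retrieved."""
    g = _gold_dict(gold)
    if not g:
        raise ValueError("empty gold set")
    total = 0.0
    for e, t in g.items():
        ranked = list(preds.get(e, ()))
        if t in ranked:
            total += 1.0 / (ranked.index(t) + 1)
    return total / len(g)


def wup(h: Hierarchy, a: str, b: str) -> float:
    """Wu-Palmer relatedness of two terms; 0 if they share no ancestor.

    Each candidate subsumer c (a term subsumes itself) scores

        2·depth(c) / (2·depth(c) + d(a, c) + d(b, c))

    with depth the shortest-path depth of c and d(·, c) the shortest
    upward hop distance; the least common subsumer is the c maximizing
    that score. On trees the maximizer is exactly the deepest common
    ancestor and the score reduces to 2·depth(lcs)/(depth(a)+depth(b)).
    Measuring each argument's depth *through* c keeps the score within
    [0, 1] on multi-parent DAGs, where shortest-path depths alone can
    undercut a deep shared ancestor (or even make an ancestor deeper than
    its descendant), and guarantees wup(t, t) = 1. Score ties between
    subsumers cannot change the value.
    """
    up_a = h.up_distances(a)
    up_b = h.up_distances(b)
    common = up_a.keys() & up_b.keys()
    if not common:
        return 0.0
    return max(
        2.0 * h.depth(c) / (2.0 * h.depth(c) + up_a[c] + up_b[c]) for c in common
    )


def _rel_all_terms(h: Hierarchy, gold_term: str) -> list[float]:
    return [wup(h, t, gold_term) for t in h.terms]


def ndcg_at_k(
    preds: Predictions,
    gold: AlignmentSet | Mapping[str, str],
    h: Hierarchy,
    k: int,
) -> float:
    """Mean nDCG@k with exponential-decay gains and WuP-graded relevance.

    Per query: rel(t) = wup(t, gold); DCG@k = Σ_{i≤k} (2^rel(t_i) − 1) /
    log2(i+1); IDCG@k uses the k highest relevances over the full term
    set; nDCG = DCG/IDCG (0 when IDCG is 0).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    g = _gold_dict(gold)
    if not g:
        raise ValueError("empty gold set")
    total = 0.0
    for e, gold_t in g.items():
        ranked = list(preds.get(e, ()))[:k]
        dcg = sum(
            (2.0 ** wup(h, t, gold_t) - 1.0) / math.log2(i + 2)
            for i, t in enumerate(ranked)
        )
        ideal = sorted(_rel_all_terms(h, gold_t), reverse=True)[:k]
        idcg = sum((2.0 ** r - 1.0) / math.log2(i + 2) for i, r in enumerate(ideal))
        total += dcg / idcg if idcg > 0 else 0.0
    return total / len(g)


def top1_wup(preds: Predictions, gold: AlignmentSet | Mapping[str, str], h: Hierarchy) -> float:
    """Mean WuP between the top-1 prediction and the gold term (0 if none)."""
    g = _gold_dict(gold)
    if not g:
        raise ValueError("empty gold set")
    total = 0.0
    for e, t in g.items():
        ranked = list(preds.get(e, ()))
        if ranked:
            total += wup(h, ranked[0], t)
    return total / len(g)


@dataclass(frozen=True)
class EvalReport:
    """Strict + lenient metrics of one prediction run."""

    hits: dict[int, float]
    mrr: float
    ndcg: dict[int, float]
    wup: float
    n_queries: int

    def to_dict(self) -> dict:
        return {
            **{f"hits@{k}": v for k, v in sorted(self.hits.items())},
            **{f"ndcg@{k}": v for k, v in sorted(self.ndcg.items())},
            "wup": self.wup,
            "mrr": self.mrr,
            "n_queries": self.n_queries,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_table(self) -> str:
        """A one-row table in the conventional column order."""
        cols = (
            [f"Hits@{k}" for k in sorted(self.hits)]
            + [f"nDCG@{k}" for k in sorted(self.ndcg)]
            + ["WuP", "MRR"]
        )
        vals = (
            [self.hits[k] for k in sorted(self.hits)]
            + [self.ndcg[k] for k in sorted(self.ndcg)]
            + [self.wup, self.mrr]
        )
        header = "\t".join(cols)
        row = "\t".join(f"{100 * v:.2f}" for v in vals)
        return f"{header}\n{row}"


def evaluate_run(
    preds: Predictions,
    gold: AlignmentSet | Mapping[str, str],
    h: Hierarchy,
    ks: Sequence[int] = (1, 3, 5, 10, 20),
    ndcg_ks: Sequence[int] = (1, 3),
) -> EvalReport:
    """Assemble the full metric report for one prediction run.

    Predicted entities absent from the gold set are excluded from every
    denominator (with a warning); gold entities without predictions count
    as misses.
    """
    g = _gold_dict(gold)
    extra = sorted(set(preds) - set(g))
    if extra:
        warnings.warn(
            f"{len(extra)} predicted entities not in gold set; excluded "
            f"(first: {extra[0]!r})",
            stacklevel=2,
        )
    return EvalReport(
        hits={k: hits_at_k(preds, g, k) for k in ks},
        mrr=mrr(preds, g),
        ndcg={k: ndcg_at_k(preds, g, h, k) for k in ndcg_ks},
        wup=top1_wup(preds, g, h),
        n_queries=len(g),
    )
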