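# bkf — few-shot biomedical knowledge fusion

`bkf` aligns entities of a biomedical knowledge graph (KG) to the **most
specific** matching term of a hierarchical index system — a directed acyclic
graph of is-a (hypernym) edges such as the Disease Ontology. This
entity-to-hierarchy alignment ("knowledge fusion") is what lets independently
curated KGs be merged under one index with fine-grained granularity. The
setting is supervision-scarce: at most a handful of labeled entity–term pairs
(M = 0 or 1) are available.

The package is aimed at people building biomedical knowledge bases who need a
reproducible, LLM-backend-agnostic fusion pipeline that runs end-to-end
offline: built-in deterministic re-rank backends and a synthetic benchmark
generator stand in for hosted language models and licensing-bound datasets.

## Method

Two stages per query entity *e*:

1. **Retrieve.** Every hierarchy term *t* becomes a pseudo-document; *e*
   becomes a query. Both sides can be *expanded* with attributive information
   (synonyms, definition) and structural information (names of one-hop
   neighbors: KG neighbors for entities, parents/children for terms) — the
   four combinations Name, +Atr, +Str, +Atr+Str. Okapi BM25
   (k1 = 1.5, b = 0.75, nonnegative idf `ln(1 + (N − df + ½)/(df + ½))`)
   returns a coarse top-K candidate list (K = 20), ties broken by term id.
2. **Re-rank.** A prompt is assembled from a task description, M
   demonstrations (`Query:` / `Choices:` / `Answer:` blocks; a fixed
   out-of-domain *pseudo-demonstration* when M = 0), an optional hierarchy
   context (one `candidate isA parents` line per candidate), and the test
   block ending in a bare `Answer:`. A completion backend (deterministic
   built-ins `noop` / `oracle` / `token_overlap`, or any HTTP text-completion
   endpoint at temperature 0) proposes an ordering; a deterministic mapping
   parses it back into a permutation of the candidates — hallucinated names
   are dropped, omissions backfilled in retrieval order.

Rankings are scored with strict metrics (Hits@k, MRR) and lenient
hierarchy-aware metrics: nDCG@k with exponential decay and Wu-Palmer-graded
relevance, and mean top-1 Wu-Palmer relatedness
`WuP(a,b) = max_c 2·depth(c) / (2·depth(c) + d(a,c) + d(b,c))` over common
subsumers *c* (the deepest common ancestor, on trees).

## Worked example

Run the whole pipeline on the default synthetic benchmark (1000 terms,
depth ≤ 13, 200 entities gold-linked one-to-one, naming noise on):

```bash
$ bkf run --seed 17 --backend token-overlap --out-dir out/
Hits@1  Hits@3  Hits@5  Hits@10 Hits@20 nDCG@1  nDCG@3  WuP     MRR
92.46   97.99   98.99   98.99   100.00  95.19   72.33   95.50   95.56
```

Reading the row (values are percentages over the 199 test queries left after
the one demonstration is held out): the gold term is ranked first for 92.5 %
of entities and is always somewhere in the top 20 (Hits@20 = 100 — the
retriever's recall ceiling); MRR 95.6 says the gold term sits near rank 1 on
average. The lenient columns credit near-misses: WuP 95.5 means even wrong
top-1 predictions are hierarchically close to the gold term; nDCG@3 is lower
because its ideal ranking draws on the *whole* hierarchy, not just the
retrieved candidates. The `token-overlap` backend is a deterministic lexical
stand-in for an LLM; `--backend noop` (keep retrieval order) and
`--backend oracle` (gold first, the upper bound) bracket what any re-ranker
can achieve on the same candidates.

Stages can also be run separately — `bkf synth`, `bkf retrieve`,
`bkf prompt`, `bkf rerank`, `bkf eval` — exchanging plain JSONL/TSV artifacts,
so any stage can be re-run in isolation (e.g. pointing `bkf rerank --backend
http` at a hosted completion endpoint). The same pipeline is available as a
library via `bkf.RunConfig` / `bkf.run`, and all domain operations
(`load_kg`, `index_terms`, `retrieve`, `assemble_prompt`, `parse_answer`,
`evaluate_run`, …) are importable from `bkf`.

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch —
synthesize → retrieve (+Atr+Str, K = 20) → prompt (one-shot, hierarchy
context) → re-rank (token-overlap backend) → evaluate — with every source of
randomness driven by `--seed`, prints the metric table to stderr, and writes
its JSON result map to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| Module | Role |
| --- | --- |
| `bkf.models` | KG / hierarchy / alignment containers, JSONL+TSV readers/writers, depth & ancestor queries |
| `bkf.obo` | optional OBO 1.4 → hierarchy converter |
| `bkf.retrieval` | tokenization, expansion documents, Okapi BM25 index and top-K retrieval |
| `bkf.prompting` | demonstrations, hierarchy context, prompt assembly |
| `bkf.reranking` | answer parsing (mapping f), built-in + HTTP completion backends |
| `bkf.evaluation` | Hits@k, MRR, Wu-Palmer, nDCG, report assembly |
| `bkf.synthetic` | seeded benchmark generator (hierarchy, KG, gold links, manifest) |
| `bkf.pipeline` / `bkf.cli` | end-to-end orchestration and the `bkf` command |

See `docs/methods.md` for modeling choices, parameter defaults, and known
limitations.
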