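# Methods

This note records the scientific and numerical choices behind `bkf`: the
alignment model, the retrieval and prompting conventions, the metric
definitions on DAGs, and what the synthetic benchmark does and does not
emulate.

## Problem model

A knowledge graph 𝒢 = (E, R, RT) carries entities with textual attributes
(name, synonyms, definition, semantic types) and relational triples. A
hierarchy 𝓗 = (T, TP) carries terms with the same kind of attributes plus
hypernym (child → parent) pairs forming a DAG. The task is to link each
query entity to the most specific matching term, under a one-to-one gold
linkage and with M ∈ {0, 1} labeled pairs available as demonstrations.

Conventions that everything downstream relies on:

* identifiers are opaque, case-sensitive strings; names are never identity;
* roots have depth 1, and depth on a DAG is 1 + the shortest child→parent
  path to the nearest root — a strictly positive depth keeps Wu-Palmer
  similarity positive for co-rooted terms;
* multi-root hierarchies (forests) are allowed; cross-component relatedness
  is 0;
* surface names must not contain `;`, the prompt-grammar separator;
  loaders reject such names outright rather than escape them.

## Retrieval

Each term is indexed as one pseudo-document; each entity query is built the
same way. Document construction concatenates, in fixed order: the name; if
attribute expansion is on, all synonyms then the definition; if structural
expansion is on, the names of one-hop neighbors — for an entity, KG
neighbors in either triple direction; for a term, parents then children —
deduplicated, in lexicographic id order, capped at 16 names. The cap bounds
document length for hub nodes; relation names are excluded from entity
documents because relation vocabularies are KG-specific and would pollute
the shared lexical space. Term-side structural expansion defaults to
parents + children; a `term_structure="parents"` flag restricts it to
hypernyms only.

Tokenization casefolds and splits on maximal non-alphanumeric runs; no
stemming, no stopwords. Ranking is Okapi BM25 with k1 = 1.5, b = 0.75
(standard defaults; exposed as parameters) and the nonnegative idf variant
`ln(1 + (N − df + 0.5)/(df + 0.5))`, so zero lexical overlap scores exactly
0 and scores are never negative. Top-K selection (default K = 20) breaks
score ties by lexicographic term id, making retrieval bit-reproducible
across platforms. Requests for K beyond the corpus return all terms with a
warning rather than an error.

## Prompting

The prompt grammar is fixed and newline-normalized (`\n`):

```
<task description>

Query: <demo query>
Choices: <c1; c2; …; cK>
Answer: <a1; a2; …; aK>

Contexts: <c1 isA parents(c1); …; cK isA parents(cK)>   (optional)
Query: <test entity name>
Choices: <candidate names in retrieval order>
Answer:
```

Choices/Answer/Contexts items are joined by `"; "`. Demonstration answers
list **all** K choices in gold-first order, teaching the model to emit a
full ranking. In the zero-shot setting a fixed, built-in
*pseudo-demonstration* conveys the output format; its vocabulary (furniture
and household items) is disjoint from the biomedical token vocabulary so it
cannot leak lexical signal. The hierarchy context lists each candidate's
**direct** parents (lexicographic id order); a root candidate reads
`<name> isA ROOT`. Deeper ancestor chains were considered and rejected as
default: they grow the prompt linearly in depth for marginal signal, and
the context already chains implicitly when candidates include each other's
hypernyms. Prompts exceeding the character budget (default 16 000 ≈ 4 096
tokens × 4 chars, the ceiling of early hosted completion models) raise an
error; silent truncation would corrupt the choice list.

## Re-ranking and the mapping f

A completion backend is a function prompt → text. The parser (mapping f)
takes the text after the first `Answer:`, splits on `;` and newlines,
normalizes fragments (casefold, collapse whitespace), and matches them to
candidate names by exact normalized equality. Matching is deliberately not
fuzzy: fuzzy matching would silently reward hallucinated near-names and
corrupt evaluation. First mention wins; unmatched fragments are counted and
dropped; unmentioned candidates are appended in retrieval order. The result
is therefore always a permutation of the candidate list, and the re-ranker
is strictly a permutation layer over retrieval — with the `noop` backend the
pipeline metrics equal retrieval-only metrics exactly, and with the `oracle`
backend Hits@1 equals the retriever's recall@K. These two identities are the
package's structural self-checks.

The `oracle` backend receives the query's entity id from the pipeline (an
optional argument of `complete()`); resolving gold by surface name instead
would break the Hits@1 = recall@K identity whenever naming noise makes two
entities collide on the same name. The HTTP backend posts
`{"prompt", "temperature", "max_tokens"}` to a generic completion endpoint,
forces temperature 0 by default to suppress completion randomness, retries
with exponential backoff, and fails loudly — it never degrades to another
backend.

## Evaluation

Strict: Hits@k (gold in top k) and MRR (reciprocal gold rank, 0 when
absent — retrieval misses are penalized, never errors). Lenient:

* **WuP.** On a DAG, shortest-path depths interact badly with the textbook
  formula 2·depth(lcs)/(depth(a)+depth(b)): a multi-parent shortcut can make
  a shared ancestor deeper than the terms themselves, pushing the ratio
  above 1 and even breaking self-similarity. `bkf` therefore scores every
  common subsumer c as `2·depth(c) / (2·depth(c) + d(a,c) + d(b,c))` —
  each argument's depth measured *through* c — and takes the maximum. On
  trees the maximizer is exactly the deepest common ancestor and the value
  reduces to the textbook formula; on any DAG it is symmetric, bounded in
  [0, 1], and equals 1 iff the two terms coincide. The reported WuP column
  is the mean over queries of WuP(top-1 prediction, gold).
* **nDCG@k with exponential decay.** Graded relevance rel(t) =
  WuP(t, gold); gain 2^rel − 1; discount log2(rank+1). The ideal DCG is
  computed over the k most relevant terms in the **entire** hierarchy, not
  just the retrieved candidates, so a weak retriever cannot inflate its own
  normalizer — this makes nDCG@3 noticeably stricter than Hits@3 whenever
  the gold term has close siblings the retriever did not return.

Entities predicted but absent from the gold set are excluded from all
denominators with a warning; gold entities without predictions count as
misses.

## Synthetic benchmark

The generator emulates the *shape* of a curated disease-fusion benchmark:
a single-rooted hierarchy of 1000 terms with depth ≤ 13 (the depth of the
Disease Ontology's disease hierarchy), 200 KG entities gold-linked
one-to-one, rich attributes on both sides, and KG triples
(`associated_with`) connecting entities whose gold terms are within two
hops in the hierarchy (mean 3 triples/entity, capped by available close
pairs).

Term names are 2–3 tokens from a fixed 141-token biomedical-flavored
vocabulary, with children inheriting a parent token with probability 0.5
(lexical coherence along lineages), plus two structural guarantees: no
repeated token within a name and **no name's token set contains another's**.
Subset-free naming mirrors how curated ontologies lexically distinguish
sibling terms, and it makes the zero-noise world exactly solvable: an
exact-name query always outranks partial matches under BM25, so Name-
strategy recall@1 = 1.0 when corruption is off. Without that guarantee a
short rare-token sub-name can legitimately outscore the exact match and
the clean-world baseline would be seed-dependent.

Entity names derive from the gold term's surface forms through four
corruptions applied independently, in fixed order, with defaults chosen to
mimic naming-convention divergence between independently curated
resources: synonym usage (0.5), token reordering (0.3 — invisible to
bag-of-words retrieval, visible in prompts), token loss (0.2), and
abbreviation to initials (0.1 — the corruption that actually severs lexical
overlap). Entity attributes keep the uncorrupted term name among the
synonyms with probability 0.5, which is what makes attribute expansion
(+Atr) recover most abbreviation-induced misses. Per-entity corruption
randomness is pre-drawn in a fixed order whether or not each corruption
fires, so benchmarks at the same seed but different noise levels are
coupled: raising a probability corrupts a superset of entities, making
"recall is non-increasing in noise" a meaningful invariant rather than
seed luck.

Growth attaches each new term under a uniformly chosen existing term of
depth < max_depth; the `branching` parameter acts as a soft per-node child
cap (⌈2·branching⌉) since uniform attachment cannot simultaneously realize
a target mean branching. With probability `multi_parent_prob` (0.05) a term
gains a second parent at no greater depth, producing the multi-parent DAG
structure the WuP convention above exists for.

What the generator does **not** emulate: real-world scale (11 000+ terms),
genuinely inconsistent cross-vocabulary naming (UMLS-style lexical variants,
Latin/Greek morphology), ambiguous abbreviations shared by distinct
concepts, many-to-many raw linkages needing manual curation, and semantic
(non-lexical) similarity. A green test therefore establishes that the
machinery is correct and the expected *orderings* hold (expansion helps,
noise hurts, context is additive), not that any particular headline accuracy
transfers to real data — with purely lexical backends the synthetic world is
considerably easier than a real one.

## Numerical & degenerate-input choices

* BM25 of an empty query, or of tokens absent from the corpus, is exactly 0.
* All-zero score vectors rank candidates by lexicographic term id.
* `wup` across disjoint components is 0; nDCG of a query whose ideal DCG is
  0 is defined as 0.
* Hierarchies must be non-empty, acyclic, duplicate-edge-free, and rooted;
  violations raise at construction with the offending cycle/id named.
* The few-shot split is a seeded uniform sample; M must be < |gold|.
* Seeds are plain Python ints; every stochastic routine takes its own
  `random.Random(seed)` so library users cannot perturb each other's
  streams.

## Known limitations

* Only lexical built-in backends ship; reproducing LLM-backed re-ranking
  requires pointing the HTTP backend at a hosted completion endpoint.
* Character-based prompt budgeting approximates tokenizer-based limits.
* The BM25 index is held in memory and rebuilt per strategy; persistence
  beyond JSON artifacts is out of scope.
* OBO import covers the 1.4 tags needed for alignment (`is_a`, `synonym`,
  `def`); OWL reasoning and cross-ontology consistency checking are out of
  scope.
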