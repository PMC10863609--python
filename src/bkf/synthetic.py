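"""Synthetic benchmark generator: hierarchy + KG + one-to-one gold links.

Real fusion benchmarks pair a disease-centric KG with a curated disease
hierarchy and a small manually verified one-to-one linkage. Nothing of
that shape can ship with a library, so this module grows a comparable
world from a seed: a single-rooted DAG of a configurable size and depth,
a KG whose entities are gold-linked one-to-one to hierarchy terms, and
naming-convention noise that makes the entity surface names diverge from
their gold terms the way independently curated resources do (synonym
usage, token reordering, token loss, abbreviation).

Everything is driven by one integer seed and is byte-deterministic across
platforms: generation uses only the stdlib Mersenne Twister with a fixed
draw order, and per-entity corruption randomness is pre-drawn whether or
not each corruption fires, so benchmarks at different noise levels but
the same seed are *coupled* — raising a corruption probability can only
corrupt more entities, never different ones.

Term surface names are built from a fixed biomedical-flavored vocabulary
with two structural guarantees: no repeated token within a name, and no
name whose token set contains (or is contained in) another name's token
set. Subset-free naming makes the zero-noise world exactly solvable by
lexical retrieval (an exact-name query always outranks partial matches
under BM25), which pins the generator's noise dial as the only source of
retrieval error.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .models import (
    AlignmentPair,
    AlignmentSet,
    Entity,
    Hierarchy,
    KnowledgeGraph,
    Term,
    Triple,
    write_hierarchy,
    write_kg,
    write_links,
)

__all__ = [
    "VOCAB",
    "NoiseConfig",
    "GeneratorConfig",
    "SyntheticBenchmark",
    "generate_hierarchy",
    "generate_kg",
    "generate_benchmark",
    "split_few_shot",
]

#: Fixed biomedical-flavored token vocabulary for term surface names.
VOCAB: tuple[str, ...] = (
    "disease", "syndrome", "disorder", "carcinoma", "sarcoma", "lymphoma",
    "leukemia", "neoplasm", "tumor", "cancer", "infection", "inflammation",
    "fibrosis", "stenosis", "atrophy", "dystrophy", "hyperplasia", "dysplasia",
    "edema", "ischemia", "necrosis", "sclerosis", "thrombosis", "embolism",
    "anemia", "neuropathy", "myopathy", "cardiomyopathy", "nephropathy",
    "retinopathy", "dermatitis", "hepatitis", "nephritis", "arthritis",
    "colitis", "gastritis", "meningitis", "encephalitis", "bronchitis",
    "pneumonia", "asthma", "diabetes", "hypertension", "hypotension",
    "obesity", "sepsis", "abscess", "ulcer", "lesion", "cyst", "polyp",
    "hernia", "fracture", "deficiency", "intolerance", "allergy",
    "autoimmune", "congenital", "hereditary", "familial", "idiopathic",
    "chronic", "acute", "recurrent", "progressive", "juvenile", "neonatal",
    "pediatric", "malignant", "benign", "refractory", "secondary",
    "metastatic", "systemic", "localized", "epidemic", "viral", "bacterial",
    "fungal", "parasitic", "hepatic", "renal", "cardiac", "pulmonary",
    "gastric", "intestinal", "colonic", "pancreatic", "thyroid", "adrenal",
    "pituitary", "ovarian", "testicular", "prostatic", "mammary", "lobar",
    "alveolar", "biliary", "cerebral", "spinal", "ocular", "retinal",
    "corneal", "dermal", "cutaneous", "muscular", "skeletal", "vascular",
    "arterial", "venous", "lymphatic", "immune", "hematologic", "metabolic",
    "endocrine", "neurologic", "psychiatric", "respiratory", "digestive",
    "urinary", "reproductive", "cranial", "facial", "oral", "dental",
    "nasal", "sinus", "pharyngeal", "laryngeal", "esophageal", "osseous",
    "articular", "cartilaginous", "tendinous", "membranous", "mucosal",
    "glandular", "cellular", "genetic", "chromosomal", "mitochondrial",
)


@dataclass(frozen=True)
class NoiseConfig:
    """Per-corruption probabilities, applied independently and in order:
    synonym_swap → token_shuffle → token_drop → abbreviation."""

    synonym_swap: float = 0.5
    token_shuffle: float = 0.3
    token_drop: float = 0.2
    abbreviation: float = 0.1

    def __post_init__(self) -> None:
        for name, p in asdict(self).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"noise probability {name}={p} outside [0, 1]")

    @classmethod
    def uniform(cls, level: float) -> "NoiseConfig":
        """All four corruption probabilities set to *level*."""
        return cls(level, level, level, level)


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape and noise of a synthetic benchmark; the seed is mandatory."""

    seed: int
    n_terms: int = 1000
    max_depth: int = 13
    branching: float = 3.0
    multi_parent_prob: float = 0.05
    n_entities: int = 200
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    n_synonyms: int = 2
    triple_density: float = 3.0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if self.n_entities > self.n_terms:
            raise ValueError("n_entities must not exceed n_terms (one-to-one gold)")
        if not 0.0 <= self.multi_parent_prob <= 1.0:
            raise ValueError("multi_parent_prob outside [0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


def _fresh_name(
    rng: random.Random,
    parent_tokens: tuple[str, ...],
    taken: list[frozenset[str]],
) -> str:
    """Sample a subset-free name, inheriting a parent token half the time."""
    for attempt in range(400):
        n_tok = 2 if rng.random() < 0.6 else 3
        if attempt > 300:
            n_tok += 1  # widen to escape a crowded neighborhood
        tokens: list[str] = []
        if parent_tokens and rng.random() < 0.5:
            tokens.append(rng.choice(parent_tokens))
        while len(tokens) < n_tok:
            tok = rng.choice(VOCAB)
            if tok not in tokens:
                tokens.append(tok)
        ts = frozenset(tokens)
        if all(not (ts <= other or other <= ts) for other in taken):
            taken.append(ts)
            return " ".join(tokens)
    raise RuntimeError("could not sample a subset-free name; vocabulary exhausted")


def _paraphrases(rng: random.Random, name: str, n: int) -> tuple[str, ...]:
    """Token-level paraphrases of a name: replace one token, maybe reorder."""
    tokens = name.split()
    out: list[str] = []
    for _ in range(n):
        variant = list(tokens)
        i = rng.randrange(len(variant))
        replacement = rng.choice(VOCAB)
        while replacement in variant:
            replacement = rng.choice(VOCAB)
        variant[i] = replacement
        if rng.random() < 0.5:
            variant.reverse()
        out.append(" ".join(variant))
    return tuple(out)


def generate_hierarchy(cfg: GeneratorConfig) -> Hierarchy:
    """Grow a single-rooted DAG by seeded preferential-free attachment.

    Each new term attaches under a uniformly chosen existing term whose
    depth is below ``max_depth`` and whose child count is below a soft cap
    of ``ceil(2·branching)``; with probability ``multi_parent_prob`` it
    also gains a second parent at no greater depth (acyclicity is free:
    the new node has no descendants yet).
    """
    rng = random.Random(cfg.seed)
    width = max(4, len(str(cfg.n_terms)))
    ids = [f"t{i:0{width}d}" for i in range(cfg.n_terms)]
    taken: list[frozenset[str]] = []
    names: dict[str, str] = {ids[0]: _fresh_name(rng, (), taken)}
    depths: dict[str, int] = {ids[0]: 1}
    children_count: dict[str, int] = {ids[0]: 0}
    parents_of: dict[str, list[str]] = {ids[0]: []}
    edges: list[tuple[str, str]] = []
    child_cap = max(1, math.ceil(2 * cfg.branching))

    for tid in ids[1:]:
        eligible = [
            t for t in ids[: len(names)]
            if depths[t] < cfg.max_depth and children_count[t] < child_cap
        ]
        if not eligible:  # every slot capped: fall back to depth rule only
            eligible = [t for t in ids[: len(names)] if depths[t] < cfg.max_depth]
        parent = rng.choice(eligible)
        names[tid] = _fresh_name(rng, tuple(names[parent].split()), taken)
        depths[tid] = depths[parent] + 1
        children_count[parent] += 1
        children_count[tid] = 0
        parents_of[tid] = [parent]
        edges.append((tid, parent))
        if rng.random() < cfg.multi_parent_prob and len(names) > 2:
            pool = [
                t for t in ids[: len(names) - 1]
                if depths[t] <= depths[parent] and t != parent
            ]
            if pool:
                second = rng.choice(pool)
                parents_of[tid].append(second)
                children_count[second] += 1
                edges.append((tid, second))
                depths[tid] = min(depths[tid], depths[second] + 1)

    terms: list[Term] = []
    for tid in ids:
        name = names[tid]
        syns = _paraphrases(rng, name, cfg.n_synonyms)
        if parents_of[tid]:
            parent_name = names[parents_of[tid][0]]
            distinct = [t for t in name.split() if t not in parent_name.split()]
            definition = " ".join([parent_name] + distinct)
        else:
            definition = name
        terms.append(Term(id=tid, name=name, synonyms=syns, definition=definition))
    return Hierarchy(terms, edges)


def _corrupt_name(term: Term, noise: NoiseConfig, draws: dict) -> str:
    """Apply the corruption pipeline using pre-drawn randomness."""
    if draws["u_syn"] < noise.synonym_swap and term.synonyms:
        base = term.synonyms[draws["i_syn"] % len(term.synonyms)]
    else:
        base = term.name
    tokens = base.split()
    if draws["u_shuffle"] < noise.token_shuffle and len(tokens) > 1:
        random.Random(draws["salt_shuffle"]).shuffle(tokens)
    if draws["u_drop"] < noise.token_drop and len(tokens) > 1:
        del tokens[draws["i_drop"] % len(tokens)]
    if draws["u_abbr"] < noise.abbreviation and len(tokens) > 1:
        return "".join(t[0] for t in tokens).upper()
    return " ".join(tokens)


def generate_kg(h: Hierarchy, cfg: GeneratorConfig) -> tuple[KnowledgeGraph, AlignmentSet]:
    """Sample entities gold-linked one-to-one to terms, with naming noise.

    Entity names derive from their gold term's surface forms through the
    corruption pipeline; attributes carry the uncorrupted term name among
    the synonyms with probability 0.5 and a token-noised definition.
    Triples connect entities whose gold terms share an ancestor within two
    hops, under the single relation ``associated_with``, up to a mean of
    ``triple_density`` triples per entity.
    """
    rng = random.Random(cfg.seed + 1)
    term_ids = rng.sample(sorted(h.terms), cfg.n_entities)
    width = max(4, len(str(cfg.n_entities)))
    entities: list[Entity] = []
    pairs: list[AlignmentPair] = []
    for i, tid in enumerate(term_ids):
        term = h[tid]
        # fixed draw order, independent of which corruptions fire
        draws = {
            "u_syn": rng.random(),
            "i_syn": rng.randrange(1 << 20),
            "u_shuffle": rng.random(),
            "salt_shuffle": rng.randrange(1 << 30),
            "u_drop": rng.random(),
            "i_drop": rng.randrange(1 << 20),
            "u_abbr": rng.random(),
        }
        u_keep_name = rng.random()
        salt_syn = rng.randrange(1 << 30)
        salt_def = rng.randrange(1 << 30)
        eid = f"e{i:0{width}d}"
        name = _corrupt_name(term, cfg.noise, draws)
        local = random.Random(salt_syn)
        synonyms: list[str] = []
        if u_keep_name < 0.5:
            synonyms.append(term.name)
        for syn in term.synonyms[: cfg.n_synonyms]:
            toks = syn.split()
            if local.random() < 0.3 and len(toks) > 1:
                toks[local.randrange(len(toks))] = local.choice(VOCAB)
            synonyms.append(" ".join(toks))
        dloc = random.Random(salt_def)
        def_tokens = [t for t in term.definition.split() if dloc.random() >= 0.1]
        entities.append(
            Entity(
                id=eid,
                name=name,
                synonyms=tuple(synonyms),
                definition=" ".join(def_tokens),
                semantic_types=("disease",),
            )
        )
        pairs.append(AlignmentPair(entity_id=eid, term_id=tid))

    # triples between entities whose gold terms are hierarchically close
    anc2: dict[str, set[str]] = {}
    for tid in term_ids:
        near = {tid} | set(h.parents(tid))
        for p in h.parents(tid):
            near |= set(h.parents(p))
        anc2[tid] = near
    candidates = [
        (entities[i].id, entities[j].id)
        for i in range(len(entities))
        for j in range(i + 1, len(entities))
        if anc2[term_ids[i]] & anc2[term_ids[j]]
    ]
    rng.shuffle(candidates)
    n_triples = min(len(candidates), round(cfg.triple_density * cfg.n_entities))
    triples = [Triple(hd, "associated_with", tl) for hd, tl in candidates[:n_triples]]
    kg = KnowledgeGraph(entities, triples)
    gold = AlignmentSet(pairs)
    gold.validate_against(kg, h)
    return kg, gold


@dataclass(frozen=True)
class SyntheticBenchmark:
    hierarchy: Hierarchy
    kg: KnowledgeGraph
    gold: AlignmentSet
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_hierarchy(self.hierarchy, out / "terms.jsonl", out / "edges.tsv")
        write_kg(self.kg, out / "entities.jsonl", out / "triples.tsv")
        write_links(self.gold, out / "links.tsv")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def generate_benchmark(cfg: GeneratorConfig) -> SyntheticBenchmark:
    """Hierarchy + KG + gold links + statistics manifest, from one seed."""
    h = generate_hierarchy(cfg)
    kg, gold = generate_kg(h, cfg)
    manifest = {
        "config": asdict(cfg),
        "statistics": {
            "n_terms": len(h),
            "n_edges": len(h.hypernym_pairs),
            "n_roots": len(h.roots),
            "max_depth": h.max_depth(),
            "n_entities": len(kg),
            "n_triples": len(kg.triples),
            "n_relations": len(kg.relations),
            "n_links": len(gold),
        },
    }
    return SyntheticBenchmark(hierarchy=h, kg=kg, gold=gold, manifest=manifest)


def split_few_shot(
    gold: AlignmentSet, M: int, seed: int
) -> tuple[list[AlignmentPair], list[AlignmentPair]]:
    """Split the gold linkage into M demonstration pairs and a test set."""
    if not 0 <= M < len(gold):
        raise ValueError(f"M must satisfy 0 <= M < {len(gold)}, got {M}")
    rng = random.Random(seed)
    idx = set(rng.sample(range(len(gold.pairs)), M))
    demos = [p for i, p in enumerate(gold.pairs) if i in idx]
    test = [p for i, p in enumerate(gold.pairs) if i not in idx]
    return demos, test
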