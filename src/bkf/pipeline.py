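"""End-to-end orchestration: data → retrieve → prompt → rerank → evaluate.

Every stage writes a plain JSONL artifact so any stage can be re-run in
isolation, and every artifact embeds the hash of the run configuration.
With a deterministic backend the whole run is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .evaluation import EvalReport, evaluate_run
from .models import (
    AlignmentPair,
    AlignmentSet,
    Hierarchy,
    KnowledgeGraph,
    load_hierarchy,
    load_kg,
    load_links,
)
from .prompting import (
    DEFAULT_TASK_DESCRIPTION,
    Demonstration,
    assemble_prompt,
    make_pseudo_demonstration,
)
from .reranking import CompletionBackend, HTTPBackend, builtin_backends, rerank
from .retrieval import CandidateList, ExpansionStrategy, index_terms, retrieve
from .synthetic import GeneratorConfig, generate_benchmark, split_few_shot

__all__ = ["RunConfig", "run", "read_jsonl_artifact", "write_jsonl_artifact"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs; defaults for all but the data.

    Exactly one of ``generator`` (synthesize the benchmark) or ``data_dir``
    (load entities.jsonl/triples.tsv/terms.jsonl/edges.tsv/links.tsv) must
    be given.
    """

    seed: int
    generator: GeneratorConfig | None = None
    data_dir: str | None = None
    strategy: str = "atr+str"
    K: int = 20
    shots: int = 1
    with_context: bool = True
    backend: str = "token_overlap"
    backend_options: dict = field(default_factory=dict)
    ks: tuple[int, ...] = (1, 3, 5, 10, 20)
    ndcg_ks: tuple[int, ...] = (1, 3)
    task_description: str = DEFAULT_TASK_DESCRIPTION
    budget_chars: int = 16000
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.data_dir is None):
            raise ValueError("exactly one of generator or data_dir must be set")

    def config_hash(self) -> str:
        """Hash of the run semantics; the output location is excluded so
        re-running the same configuration elsewhere reproduces the hash."""
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_jsonl_artifact(path: Path, meta: dict, records: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"_meta": meta}, sort_keys=True) + "\n")
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_jsonl_artifact(path: str | Path) -> tuple[dict, list[dict]]:
    meta: dict = {}
    records: list[dict] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if "_meta" in rec:
                meta = rec["_meta"]
            else:
                records.append(rec)
    return meta, records


def _make_backend(cfg: RunConfig, gold: AlignmentSet, h: Hierarchy) -> CompletionBackend:
    name = cfg.backend.replace("-", "_")
    if name == "http":
        return HTTPBackend(**cfg.backend_options)
    backends = builtin_backends(gold=gold, h=h)
    if name not in backends:
        raise ValueError(f"unknown backend {cfg.backend!r}; expected one of "
                         f"{sorted(backends) + ['http']}")
    return backends[name]


def _make_demonstration(
    pair: AlignmentPair,
    kg: KnowledgeGraph,
    h: Hierarchy,
    index,
    cfg: RunConfig,
    strategy: ExpansionStrategy,
) -> Demonstration:
    """A real demonstration: the demo entity's own candidate list with the
    gold term answered first. If retrieval missed the gold term, the last
    candidate is swapped for it so the answer stays within the choices."""
    cand = retrieve(kg, h, index, pair.entity_id, K=cfg.K, strategy=strategy)
    term_ids = cand.term_ids
    if pair.term_id not in term_ids:
        term_ids = term_ids[:-1] + [pair.term_id]
    gold_name = h[pair.term_id].name
    choices = [h[t].name for t in term_ids]
    answer = [gold_name] + [c for c in choices if c != gold_name]
    return Demonstration(
        query_name=kg[pair.entity_id].name,
        choice_names=tuple(choices),
        answer_names=tuple(answer),
    )


def run(cfg: RunConfig) -> EvalReport:
    """Execute all stages; persist artifacts if ``out_dir`` is set."""
    t0 = time.perf_counter()
    chash = cfg.config_hash()
    meta = {"config_hash": chash, "seed": cfg.seed}

    # --- data ---------------------------------------------------------
    if cfg.generator is not None:
        bench = generate_benchmark(cfg.generator)
        kg, h, gold = bench.kg, bench.hierarchy, bench.gold
    else:
        d = Path(cfg.data_dir)
        kg = load_kg(d / "entities.jsonl", d / "triples.tsv")
        h = load_hierarchy(d / "terms.jsonl", d / "edges.tsv")
        gold = load_links(d / "links.tsv")
        gold.validate_against(kg, h)
    demo_pairs, test_pairs = split_few_shot(gold, cfg.shots, cfg.seed)
    logger.info("data: %d entities, %d terms, %d gold links (%d demo / %d test) [%.2fs]",
                len(kg), len(h), len(gold), len(demo_pairs), len(test_pairs),
                time.perf_counter() - t0)

    # --- retrieve -----------------------------------------------------
    t1 = time.perf_counter()
    strategy = ExpansionStrategy.from_name(cfg.strategy)
    index = index_terms(h, strategy)
    candidates: dict[str, CandidateList] = {
        p.entity_id: retrieve(kg, h, index, p.entity_id, K=cfg.K, strategy=strategy)
        for p in test_pairs
    }
    logger.info("retrieve: %d candidate lists of K=%d [%.2fs]",
                len(candidates), cfg.K, time.perf_counter() - t1)

    # --- prompt -------------------------------------------------------
    t2 = time.perf_counter()
    if demo_pairs:
        demos = [
            _make_demonstration(p, kg, h, index, cfg, strategy) for p in demo_pairs
        ]
    else:
        demos = [make_pseudo_demonstration()]
    prompts = {
        eid: assemble_prompt(
            cfg.task_description, demos, cand, kg[eid].name, h,
            with_context=cfg.with_context, budget_chars=cfg.budget_chars,
        )
        for eid, cand in candidates.items()
    }
    logger.info("prompt: %d prompts, %d demonstration(s)%s [%.2fs]",
                len(prompts), len(demos),
                " (pseudo)" if demos and demos[0].is_pseudo else "",
                time.perf_counter() - t2)

    # --- rerank -------------------------------------------------------
    t3 = time.perf_counter()
    backend = _make_backend(cfg, gold, h)
    results = {
        eid: rerank(prompts[eid], candidates[eid], backend, h)
        for eid in candidates
    }
    preds = {eid: list(r.ranked_terms) for eid, r in results.items()}
    logger.info("rerank: backend=%s, %d results [%.2fs]",
                backend.name, len(results), time.perf_counter() - t3)

    # --- evaluate -----------------------------------------------------
    t4 = time.perf_counter()
    test_gold = {p.entity_id: p.term_id for p in test_pairs}
    report = evaluate_run(preds, test_gold, h, ks=cfg.ks, ndcg_ks=cfg.ndcg_ks)
    logger.info("evaluate: %d queries [%.2fs]; total %.2fs",
                report.n_queries, time.perf_counter() - t4, time.perf_counter() - t0)

    # --- artifacts ----------------------------------------------------
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if cfg.generator is not None:
            bench.write(out / "data")
        write_jsonl_artifact(
            out / "candidates.jsonl", {**meta, "stage": "retrieve"},
            ({"entity_id": eid, "ranked": [[t, s] for t, s in c.ranked],
              "strategy": c.strategy.label} for eid, c in candidates.items()),
        )
        write_jsonl_artifact(
            out / "prompts.jsonl", {**meta, "stage": "prompt"},
            ({"entity_id": eid, "prompt": p.rendered,
              "choices": list(p.test_choices),
              "term_ids": candidates[eid].term_ids} for eid, p in prompts.items()),
        )
        write_jsonl_artifact(
            out / "predictions.jsonl", {**meta, "stage": "rerank"},
            ({"entity_id": eid, "ranked_terms": list(r.ranked_terms),
              "raw_completion": r.raw_completion,
              "parse_report": r.parse_report} for eid, r in results.items()),
        )
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump({**meta, "metrics": report.to_dict()}, fh,
                      sort_keys=True, indent=2)
            fh.write("\n")
    return report
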