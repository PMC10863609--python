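"""Re-ranking: completion backends and the answer→ranking mapping f.

The re-ranker is strictly a permutation layer over retrieval: a backend
turns a rendered prompt into a completion string, and :func:`parse_answer`
maps that text back onto the candidate list. Names generated by the model
that match no candidate (hallucinations) are dropped and counted;
candidates the model failed to mention are appended in retrieval order
(backfilled), so the result is always a permutation of the candidates.

Built-in deterministic backends substitute for a hosted language model in
tests and offline runs:

* ``noop`` — echoes the choices in given order (re-ranking disabled);
* ``oracle`` — places the gold term first (upper bound of the pipeline);
* ``token_overlap`` — orders choices by Jaccard similarity between the
  tokenized query and choice names, a cheap lexical re-ranker.

A generic HTTP completion backend (single POST, temperature 0 by default,
exponential-backoff retries) connects any hosted text-completion endpoint.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .models import AlignmentSet, Hierarchy
from .prompting import PromptBundle
from .retrieval import CandidateList, tokenize

__all__ = [
    "CompletionBackend",
    "BackendError",
    "RerankResult",
    "parse_answer",
    "rerank",
    "NoopBackend",
    "OracleBackend",
    "TokenOverlapBackend",
    "HTTPBackend",
    "builtin_backends",
]

logger = logging.getLogger(__name__)


class BackendError(RuntimeError):
    """A backend failed to produce a completion; carries the entity id."""

    def __init__(self, message: str, entity_id: str | None = None) -> None:
        super().__init__(message)
        self.entity_id = entity_id


class CompletionBackend:
    """Prompt → completion. Subclasses set ``name`` and ``deterministic``."""

    name: str = "base"
    deterministic: bool = False

    def complete(self, prompt: str, entity_id: str | None = None) -> str:
        raise NotImplementedError


def _normalize(s: str) -> str:
    return " ".join(s.casefold().split())


@dataclass(frozen=True)
class RerankResult:
    entity_id: str
    ranked_terms: tuple[str, ...]
    raw_completion: str
    parse_report: dict[str, int]


def parse_answer(
    completion: str,
    candidates: CandidateList,
    name_of: Callable[[str], str],
) -> RerankResult:
    """The mapping function f: completion text → permutation of candidates.

    Takes the text after the first "Answer:" (or the whole completion),
    splits on ";" and newlines, normalizes fragments (casefold, strip,
    collapse whitespace), and matches them to candidate names by exact
    normalized equality. First mention of each candidate wins; unmatched
    fragments are dropped (counted); unmentioned candidates are backfilled
    in retrieval order (counted). Never raises on malformed text — the
    worst case is retrieval order with 0 matches.
    """
    if not candidates.ranked:
        raise ValueError("candidate list is empty")
    marker = "Answer:"
    idx = completion.find(marker)
    text = completion[idx + len(marker):] if idx >= 0 else completion
    by_name: dict[str, str] = {}
    for tid in candidates.term_ids:
        by_name.setdefault(_normalize(name_of(tid)), tid)
    matched: list[str] = []
    seen: set[str] = set()
    dropped = 0
    for raw in text.replace("\n", ";").split(";"):
        frag = _normalize(raw)
        if not frag:
            continue
        tid = by_name.get(frag)
        if tid is None:
            dropped += 1
        elif tid not in seen:
            seen.add(tid)
            matched.append(tid)
    backfilled = [tid for tid in candidates.term_ids if tid not in seen]
    return RerankResult(
        entity_id=candidates.entity_id,
        ranked_terms=tuple(matched + backfilled),
        raw_completion=completion,
        parse_report={
            "matched": len(matched),
            "dropped": dropped,
            "backfilled": len(backfilled),
        },
    )


def rerank(
    prompt: PromptBundle,
    candidates: CandidateList,
    backend: CompletionBackend,
    h: Hierarchy,
) -> RerankResult:
    """Run the backend on the rendered prompt and parse the completion."""
    try:
        completion = backend.complete(prompt.rendered, entity_id=candidates.entity_id)
    except BackendError:
        raise
    except Exception as exc:  # noqa: BLE001 — wrap with the failing entity id
        raise BackendError(str(exc), entity_id=candidates.entity_id) from exc
    logger.debug("backend=%s entity=%s completion=%r", backend.name,
                 candidates.entity_id, completion)
    return parse_answer(completion, candidates, lambda tid: h[tid].name)


# ---------------------------------------------------------------------------
# Built-in deterministic backends
# ---------------------------------------------------------------------------


def _last_query_and_choices(prompt: str) -> tuple[str, list[str]]:
    queries = [ln[len("Query: "):] for ln in prompt.splitlines() if ln.startswith("Query: ")]
    choices = [ln[len("Choices: "):] for ln in prompt.splitlines() if ln.startswith("Choices: ")]
    if not queries or not choices:
        raise BackendError("prompt has no Query:/Choices: lines")
    return queries[-1], choices[-1].split("; ")


class NoopBackend(CompletionBackend):
    """Echo the choices unchanged; re-ranking becomes the identity."""

    name = "noop"
    deterministic = True

    def complete(self, prompt: str, entity_id: str | None = None) -> str:
        _, choices = _last_query_and_choices(prompt)
        return "Answer: " + "; ".join(choices)


class OracleBackend(CompletionBackend):
    """Answer with the gold term first — the pipeline's upper bound.

    Needs the gold alignment and the hierarchy to resolve the gold term's
    surface name. Entities absent from the gold set fall back to noop
    behavior (logged).
    """

    name = "oracle"
    deterministic = True

    def __init__(self, gold: AlignmentSet, h: Hierarchy) -> None:
        self._gold = gold.as_dict()
        self._h = h

    def complete(self, prompt: str, entity_id: str | None = None) -> str:
        _, choices = _last_query_and_choices(prompt)
        gold_tid = self._gold.get(entity_id) if entity_id is not None else None
        if gold_tid is None:
            logger.warning("oracle: entity %r not in gold set; noop fallback", entity_id)
            return "Answer: " + "; ".join(choices)
        gold_name = self._h[gold_tid].name
        if gold_name in choices:
            ordered = [gold_name] + [c for c in choices if c != gold_name]
        else:
            ordered = choices
        return "Answer: " + "; ".join(ordered)


class TokenOverlapBackend(CompletionBackend):
    """Order choices by Jaccard token overlap with the query (ties stable)."""

    name = "token_overlap"
    deterministic = True

    def complete(self, prompt: str, entity_id: str | None = None) -> str:
        query, choices = _last_query_and_choices(prompt)
        q = set(tokenize(query))

        def jaccard(choice: str) -> float:
            c = set(tokenize(choice))
            union = q | c
            return len(q & c) / len(union) if union else 0.0

        ordered = sorted(choices, key=jaccard, reverse=True)  # stable sort
        return "Answer: " + "; ".join(ordered)


def builtin_backends(
    gold: AlignmentSet | None = None,
    h: Hierarchy | None = None,
) -> dict[str, CompletionBackend]:
    """The deterministic test backends; oracle only if gold+hierarchy given."""
    backends: dict[str, CompletionBackend] = {
        "noop": NoopBackend(),
        "token_overlap": TokenOverlapBackend(),
    }
    if gold is not None:
        if h is None:
            raise ValueError("oracle backend needs the hierarchy")
        backends["oracle"] = OracleBackend(gold, h)
    return backends


class HTTPBackend(CompletionBackend):
    """Generic text-completion endpoint: one JSON POST per prompt.

    Payload: ``{"prompt": ..., "temperature": ..., "max_tokens": ...}``.
    Temperature defaults to 0 to suppress completion randomness. The
    completion is read from the response's ``completion``, ``text`` or
    ``choices[0].text`` field. Transient failures are retried with
    exponential backoff; after the retry budget a :class:`BackendError`
    is raised — the backend never silently degrades to another strategy.
    """

    name = "http"
    deterministic = False

    def __init__(
        self,
        url: str,
        *,
        api_key: str | None = None,
        temperature: float = 0.0,
        max_tokens: int = 256,
        retries: int = 3,
        backoff: float = 0.5,
        timeout: float = 30.0,
        extra_payload: Mapping[str, object] | None = None,
    ) -> None:
        self.url = url
        self.api_key = api_key
        self.temperature = temperature
        self.max_tokens = max_tokens
        self.retries = retries
        self.backoff = backoff
        self.timeout = timeout
        self.extra_payload = dict(extra_payload or {})
        self.deterministic = temperature == 0.0

    def _extract(self, payload: dict) -> str:
        if "completion" in payload:
            return str(payload["completion"])
        if "text" in payload:
            return str(payload["text"])
        choices = payload.get("choices")
        if isinstance(choices, list) and choices and "text" in choices[0]:
            return str(choices[0]["text"])
        raise BackendError(f"cannot find completion text in response keys {sorted(payload)}")

    def complete(self, prompt: str, entity_id: str | None = None) -> str:
        body = {
            "prompt": prompt,
            "temperature": self.temperature,
            "max_tokens": self.max_tokens,
            **self.extra_payload,
        }
        data = json.dumps(body).encode("utf-8")
        headers = {"Content-Type": "application/json"}
        if self.api_key:
            headers["Authorization"] = f"Bearer {self.api_key}"
        last_error: Exception | None = None
        for attempt in range(self.retries):
            if attempt:
                time.sleep(self.backoff * 2 ** (attempt - 1))
            req = urllib.request.Request(self.url, data=data, headers=headers)
            try:
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    return self._extract(json.loads(resp.read().decode("utf-8")))
            except (urllib.error.URLError, urllib.error.HTTPError, TimeoutError) as exc:
                last_error = exc
                logger.warning("http backend attempt %d/%d failed: %s",
                               attempt + 1, self.retries, exc)
        raise BackendError(
            f"completion endpoint failed after {self.retries} attempts: {last_error}",
            entity_id=entity_id,
        )
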