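"""Hierarchy-oriented prompt construction for the listwise re-ranker.

A prompt is composed of a task description, a handful of demonstrations
(real labeled pairs, or one built-in *pseudo* demonstration in the
zero-shot setting), an optional hierarchy context exposing each
candidate's hypernyms ("X isA Y"), and the test block ending in a bare
"Answer:" line for the language model to complete.

The rendering grammar is fixed and byte-deterministic (newline "\\n",
separator "; ") so that downstream answer parsing and golden-file tests
are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .models import Hierarchy
from .retrieval import CandidateList

__all__ = [
    "DEFAULT_TASK_DESCRIPTION",
    "Demonstration",
    "PromptBundle",
    "render_demonstration",
    "make_pseudo_demonstration",
    "make_hierarchy_context",
    "assemble_prompt",
]

#: Default instruction; the exact wording is a package choice, overridable.
DEFAULT_TASK_DESCRIPTION = (
    "Given a query and a list of choices, rank all choices from the most "
    "specific match for the query to the least specific match. Reply with "
    "the ranked choices separated by '; '."
)

SEP = "; "
ROOT_PLACEHOLDER = "ROOT"


@dataclass(frozen=True)
class Demonstration:
    """One worked example: query, choice list, and fully ordered answer."""

    query_name: str
    choice_names: tuple[str, ...]
    answer_names: tuple[str, ...]
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "choice_names", tuple(self.choice_names))
        object.__setattr__(self, "answer_names", tuple(self.answer_names))
        if not self.choice_names:
            raise ValueError("demonstration must have at least one choice")
        if not self.is_pseudo:
            missing = [a for a in self.answer_names if a not in self.choice_names]
            if missing:
                raise ValueError(
                    f"answer names not among choices: {missing!r}"
                )


def render_demonstration(d: Demonstration) -> str:
    """Render the three-line Query/Choices/Answer block."""
    return (
        f"Query: {d.query_name}\n"
        f"Choices: {SEP.join(d.choice_names)}\n"
        f"Answer: {SEP.join(d.answer_names)}"
    )


def make_pseudo_demonstration() -> Demonstration:
    """The built-in out-of-domain demonstration for the zero-shot setting.

    When no labeled pair exists, a fixed general-domain example still shows
    the model the expected output format. Its vocabulary is deliberately
    disjoint from biomedical naming so it cannot leak lexical signal into
    the test query.
    """
    return Demonstration(
        query_name="antique oak bookshelf",
        choice_names=("wooden furniture", "garden tool", "kitchen appliance"),
        answer_names=("wooden furniture", "garden tool", "kitchen appliance"),
        is_pseudo=True,
    )


def make_hierarchy_context(h: Hierarchy, candidates: CandidateList) -> list[str]:
    """One "child isA parent(s)" line per candidate, in candidate order.

    Parents are listed by lexicographic id; a root candidate reads
    "{name} isA ROOT".
    """
    lines: list[str] = []
    for tid in candidates.term_ids:
        term = h[tid]
        parent_ids = h.parents(tid)
        if parent_ids:
            parent_names = ", ".join(h[p].name for p in parent_ids)
        else:
            parent_names = ROOT_PLACEHOLDER
        lines.append(f"{term.name} isA {parent_names}")
    return lines


@dataclass(frozen=True)
class PromptBundle:
    """A fully rendered prompt plus the pieces it was assembled from."""

    task_description: str
    demonstrations: tuple[Demonstration, ...]
    context_lines: tuple[str, ...] | None
    test_query: str
    test_choices: tuple[str, ...]
    rendered: str


def assemble_prompt(
    task_description: str,
    demos: Sequence[Demonstration],
    candidates: CandidateList,
    entity_name: str,
    h: Hierarchy,
    *,
    with_context: bool = False,
    budget_chars: int = 16000,
) -> PromptBundle:
    """Compose the full prompt string for one query entity.

    Layout: task description, blank line, demonstration blocks separated by
    blank lines, blank line, optional single "Contexts:" line, then the
    test "Query:"/"Choices:" lines and a terminal bare "Answer:" line.
    Exceeding *budget_chars* raises instead of silently truncating.
    """
    if not candidates.ranked:
        raise ValueError("candidate list is empty")
    choices = tuple(h[tid].name for tid in candidates.term_ids)
    context_lines = (
        tuple(make_hierarchy_context(h, candidates)) if with_context else None
    )
    blocks: list[str] = [task_description]
    blocks.extend(render_demonstration(d) for d in demos)
    test_lines: list[str] = []
    if context_lines is not None:
        test_lines.append(f"Contexts: {SEP.join(context_lines)}")
    test_lines.append(f"Query: {entity_name}")
    test_lines.append(f"Choices: {SEP.join(choices)}")
    test_lines.append("Answer:")
    blocks.append("\n".join(test_lines))
    rendered = "\n\n".join(blocks)
    if len(rendered) > budget_chars:
        raise ValueError(
            f"prompt length {len(rendered)} exceeds budget_chars={budget_chars} "
            f"(over by {len(rendered) - budget_chars})"
        )
    return PromptBundle(
        task_description=task_description,
        demonstrations=tuple(demos),
        context_lines=context_lines,
        test_query=entity_name,
        test_choices=choices,
        rendered=rendered,
    )
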