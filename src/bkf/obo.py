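"""Optional OBO 1.4 import: convert a flat OBO file into a :class:`Hierarchy`.

Only the tags needed for alignment are read: ``id``, ``name``, ``is_a``
(hypernym pairs), ``synonym`` and ``def`` (textual attributes). Obsolete
terms are skipped. This is a converter for convenience — the canonical
on-disk formats of this package are JSONL + TSV.
"""

from __future__ import annotations

import re
from pathlib import Path

from .models import Hierarchy, Term, ValidationError

__all__ = ["read_obo"]

_QUOTED = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _unquote(value: str) -> str:
    m = _QUOTED.search(value)
    return m.group(1).replace('\\"', '"') if m else value.strip()


def read_obo(path: str | Path) -> Hierarchy:
    """Parse ``[Term]`` stanzas of an OBO file into a validated Hierarchy."""
    terms: list[Term] = []
    edges: list[tuple[str, str]] = []
    stanza: dict | None = None

    def flush() -> None:
        if stanza is None or stanza.get("obsolete"):
            return
        if "id" not in stanza or "name" not in stanza:
            raise ValidationError(f"OBO term stanza missing id or name near {stanza}")
        terms.append(
            Term(
                id=stanza["id"],
                name=stanza["name"],
                synonyms=tuple(stanza.get("synonyms", ())),
                definition=stanza.get("definition", ""),
            )
        )
        for parent in stanza.get("is_a", ()):
            edges.append((stanza["id"], parent))

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("!")[0].strip()
            if line == "[Term]":
                flush()
                stanza = {}
                continue
            if line.startswith("["):  # other stanza type ([Typedef] etc.)
                flush()
                stanza = None
                continue
            if stanza is None or ":" not in line:
                continue
            tag, _, value = line.partition(":")
            value = value.strip()
            if tag == "id":
                stanza["id"] = value
            elif tag == "name":
                stanza["name"] = value
            elif tag == "is_a":
                stanza.setdefault("is_a", []).append(value.split()[0])
            elif tag == "synonym":
                stanza.setdefault("synonyms", []).append(_unquote(value))
            elif tag == "def":
                stanza["definition"] = _unquote(value)
            elif tag == "is_obsolete" and value.lower() == "true":
                stanza["obsolete"] = True
    flush()
    return Hierarchy(terms, edges)
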