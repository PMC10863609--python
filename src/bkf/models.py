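"""Domain model for biomedical knowledge fusion.

The fusion task aligns entities of a source knowledge graph (KG) — a
multi-relational graph whose nodes carry rich textual attributes (surface
name, synonyms, free-text definition, semantic types) — to the *most
specific* matching term of a target index hierarchy: a directed acyclic
graph of terms connected by hypernym (child → parent, "is-a") edges, such
as the Disease Ontology.

This module defines the containers for both sides of the alignment
(:class:`KnowledgeGraph`, :class:`Hierarchy`), the gold linkage
(:class:`AlignmentSet`), plain-text readers/writers (JSONL for attributed
records, TSV for edges/triples/links), and the structural queries the rest
of the package needs: parents, ancestors, and depth.

Conventions
-----------
* Identifiers are case-sensitive opaque strings; surface names are never
  used for identity.
* Roots have depth 1 (not 0), so Wu-Palmer similarity between co-rooted
  terms is strictly positive. On a DAG the depth of a term is 1 plus the
  length of the *shortest* child→parent path to the nearest root.
* Multi-root hierarchies (forests) are permitted.
* Surface names must not contain ";" — it is the separator of the prompt
  grammar downstream, and ambiguity there cannot be repaired later.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "ValidationError",
    "Entity",
    "Triple",
    "KnowledgeGraph",
    "Term",
    "Hierarchy",
    "AlignmentPair",
    "AlignmentSet",
    "load_kg",
    "write_kg",
    "load_hierarchy",
    "write_hierarchy",
    "load_links",
    "write_links",
]


class ValidationError(ValueError):
    """Raised when a structure violates its invariants."""


def _check_name(name: str, what: str, ident: str) -> None:
    if not name:
        raise ValidationError(f"{what} {ident!r} has an empty name")
    if ";" in name:
        raise ValidationError(
            f"{what} {ident!r} has a name containing ';' ({name!r}); "
            "';' is reserved as the prompt separator"
        )


@dataclass(frozen=True)
class Entity:
    """A KG entity with its textual attributes."""

    id: str
    name: str
    synonyms: tuple[str, ...] = ()
    definition: str = ""
    semantic_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("entity id must be nonempty")
        _check_name(self.name, "entity", self.id)
        object.__setattr__(self, "synonyms", tuple(self.synonyms))
        object.__setattr__(self, "semantic_types", tuple(self.semantic_types))


@dataclass(frozen=True)
class Triple:
    """A relational triple (head, relation, tail) between entity ids."""

    head: str
    relation: str
    tail: str


class KnowledgeGraph:
    """Entities keyed by id plus relational triples over them.

    Invariants enforced at construction: entity ids unique, every triple
    endpoint resolves to an entity, and the relation set covers every
    relation name a triple uses.
    """

    def __init__(self, entities: Iterable[Entity], triples: Iterable[Triple] = ()) -> None:
        self.entities: dict[str, Entity] = {}
        for e in entities:
            if e.id in self.entities:
                raise ValidationError(f"duplicate entity id {e.id!r}")
            self.entities[e.id] = e
        self.triples: list[Triple] = []
        for i, t in enumerate(triples):
            for endpoint in (t.head, t.tail):
                if endpoint not in self.entities:
                    raise ValidationError(
                        f"triple {i} ({t.head!r}, {t.relation!r}, {t.tail!r}) "
                        f"references unknown entity {endpoint!r}"
                    )
            self.triples.append(t)
        self.relations: frozenset[str] = frozenset(t.relation for t in self.triples)
        self._adj: dict[str, set[str]] | None = None

    def __len__(self) -> int:
        return len(self.entities)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.entities

    def __getitem__(self, entity_id: str) -> Entity:
        try:
            return self.entities[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity id {entity_id!r}") from None

    def neighbors(self, entity_id: str) -> list[str]:
        """One-hop neighbor ids in either triple direction, deduplicated,
        in lexicographic order."""
        if entity_id not in self.entities:
            raise KeyError(f"unknown entity id {entity_id!r}")
        if self._adj is None:
            adj: dict[str, set[str]] = {eid: set() for eid in self.entities}
            for t in self.triples:
                adj[t.head].add(t.tail)
                adj[t.tail].add(t.head)
            self._adj = adj
        return sorted(self._adj[entity_id] - {entity_id})


@dataclass(frozen=True)
class Term:
    """A hierarchy term with its textual attributes."""

    id: str
    name: str
    synonyms: tuple[str, ...] = ()
    definition: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("term id must be nonempty")
        _check_name(self.name, "term", self.id)
        object.__setattr__(self, "synonyms", tuple(self.synonyms))


class Hierarchy:
    """Terms plus hypernym (child → parent) edges forming a DAG.

    The directed graph is validated at construction: edge endpoints must
    exist, duplicate edges are rejected, the graph must be acyclic, and at
    least one root (a term with no parent) must exist.
    """

    def __init__(
        self,
        terms: Iterable[Term],
        hypernym_pairs: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.terms: dict[str, Term] = {}
        for t in terms:
            if t.id in self.terms:
                raise ValidationError(f"duplicate term id {t.id!r}")
            self.terms[t.id] = t
        if not self.terms:
            raise ValidationError("hierarchy must contain at least one term")
        # child -> parent digraph
        self._g = nx.DiGraph()
        self._g.add_nodes_from(self.terms)
        self.hypernym_pairs: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for child, parent in hypernym_pairs:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise ValidationError(
                        f"hypernym pair ({child!r}, {parent!r}) references "
                        f"unknown term {endpoint!r}"
                    )
            if (child, parent) in seen:
                raise ValidationError(f"duplicate hypernym pair ({child!r}, {parent!r})")
            seen.add((child, parent))
            self.hypernym_pairs.append((child, parent))
            self._g.add_edge(child, parent)
        try:
            cycle = nx.find_cycle(self._g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle is not None:
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise ValidationError(f"hierarchy contains a cycle: {path}")
        self.roots: tuple[str, ...] = tuple(
            sorted(n for n in self._g.nodes if self._g.out_degree(n) == 0)
        )
        if not self.roots:
            raise ValidationError("hierarchy has no root (every term has a parent)")
        self._depths: dict[str, int] | None = None
        self._up_dist: dict[str, dict[str, int]] = {}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise KeyError(f"unknown term id {term_id!r}") from None

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise KeyError(f"unknown term id {term_id!r}")

    def parents(self, term_id: str) -> list[str]:
        """Direct hypernyms of *term_id*, in lexicographic id order."""
        self._require(term_id)
        return sorted(self._g.successors(term_id))

    def children(self, term_id: str) -> list[str]:
        """Direct hyponyms of *term_id*, in lexicographic id order."""
        self._require(term_id)
        return sorted(self._g.predecessors(term_id))

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive hypernym closure of *term_id*, excluding itself."""
        self._require(term_id)
        return set(nx.descendants(self._g, term_id))

    def depth(self, term_id: str) -> int:
        """Depth of a term: roots have depth 1; otherwise 1 + the length of
        the shortest child→parent path to the nearest root."""
        self._require(term_id)
        if self._depths is None:
            # one backwards BFS from the root set over parent->child edges
            depths: dict[str, int] = {r: 1 for r in self.roots}
            frontier = list(self.roots)
            while frontier:
                nxt: list[str] = []
                for node in frontier:
                    for child in self._g.predecessors(node):
                        if child not in depths:
                            depths[child] = depths[node] + 1
                            nxt.append(child)
                frontier = nxt
            self._depths = depths
        return self._depths[term_id]

    def up_distances(self, term_id: str) -> dict[str, int]:
        """Shortest upward (child→parent) hop distance from *term_id* to
        each of its ancestors, itself included at distance 0. Memoized."""
        self._require(term_id)
        cached = self._up_dist.get(term_id)
        if cached is None:
            cached = nx.single_source_shortest_path_length(self._g, term_id)
            self._up_dist[term_id] = cached
        return cached

    def max_depth(self) -> int:
        self.depth(self.roots[0])  # populate cache
        assert self._depths is not None
        return max(self._depths.values())


@dataclass(frozen=True)
class AlignmentPair:
    """A gold link: KG entity id → hierarchy term id."""

    entity_id: str
    term_id: str


class AlignmentSet:
    """A one-to-one set of entity–term alignment pairs.

    ``few_shot_size`` records how many pairs are available as labeled
    demonstrations (M); the alignment problem is few-shot, so M is tiny
    (0 or 1 in the evaluated settings).
    """

    def __init__(self, pairs: Iterable[AlignmentPair], few_shot_size: int = 0) -> None:
        if few_shot_size < 0:
            raise ValidationError("few_shot_size must be nonnegative")
        self.pairs: list[AlignmentPair] = list(pairs)
        ents: set[str] = set()
        terms: set[str] = set()
        for p in self.pairs:
            if p.entity_id in ents:
                raise ValidationError(f"entity {p.entity_id!r} linked twice")
            if p.term_id in terms:
                raise ValidationError(f"term {p.term_id!r} linked twice")
            ents.add(p.entity_id)
            terms.add(p.term_id)
        self.few_shot_size = few_shot_size

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[AlignmentPair]:
        return iter(self.pairs)

    def as_dict(self) -> dict[str, str]:
        return {p.entity_id: p.term_id for p in self.pairs}

    def validate_against(self, kg: KnowledgeGraph, h: Hierarchy) -> None:
        for p in self.pairs:
            if p.entity_id not in kg:
                raise ValidationError(f"alignment references unknown entity {p.entity_id!r}")
            if p.term_id not in h:
                raise ValidationError(f"alignment references unknown term {p.term_id!r}")


# ---------------------------------------------------------------------------
# Readers / writers (JSONL for attributed records, TSV for edge-like files)
# ---------------------------------------------------------------------------


def _read_jsonl(path: str | Path) -> Iterator[tuple[int, dict]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}:{lineno}: invalid JSON ({exc})") from None
            yield lineno, rec


def load_kg(entity_path: str | Path, triple_path: str | Path) -> KnowledgeGraph:
    """Load a KG from an entities JSONL file and a triples TSV file.

    The entity file has one JSON record per line with keys ``id`` and
    ``name`` and optional ``synonyms``, ``definition``, ``semantic_types``.
    The triple file has three tab-separated columns head/relation/tail.
    """
    entities = [
        Entity(
            id=rec["id"],
            name=rec["name"],
            synonyms=tuple(rec.get("synonyms", ())),
            definition=rec.get("definition", ""),
            semantic_types=tuple(rec.get("semantic_types", ())),
        )
        for _, rec in _read_jsonl(entity_path)
    ]
    kg = KnowledgeGraph(entities)  # validate entity uniqueness first
    triples: list[Triple] = []
    with open(triple_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ValidationError(
                    f"{triple_path}:{lineno}: expected 3 tab-separated columns, got {len(cols)}"
                )
            head, relation, tail = cols
            for endpoint in (head, tail):
                if endpoint not in kg:
                    raise ValidationError(
                        f"{triple_path}:{lineno}: triple references unknown entity {endpoint!r}"
                    )
            triples.append(Triple(head, relation, tail))
    return KnowledgeGraph(kg.entities.values(), triples)


def write_kg(kg: KnowledgeGraph, entity_path: str | Path, triple_path: str | Path) -> None:
    with open(entity_path, "w", encoding="utf-8") as fh:
        for e in kg.entities.values():
            fh.write(
                json.dumps(
                    {
                        "id": e.id,
                        "name": e.name,
                        "synonyms": list(e.synonyms),
                        "definition": e.definition,
                        "semantic_types": list(e.semantic_types),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    with open(triple_path, "w", encoding="utf-8") as fh:
        for t in kg.triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def load_hierarchy(term_path: str | Path, edge_path: str | Path) -> Hierarchy:
    """Load a hierarchy from a terms JSONL file and a child<TAB>parent TSV."""
    terms = [
        Term(
            id=rec["id"],
            name=rec["name"],
            synonyms=tuple(rec.get("synonyms", ())),
            definition=rec.get("definition", ""),
        )
        for _, rec in _read_jsonl(term_path)
    ]
    edges: list[tuple[str, str]] = []
    with open(edge_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValidationError(
                    f"{edge_path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}"
                )
            edges.append((cols[0], cols[1]))
    return Hierarchy(terms, edges)


def write_hierarchy(h: Hierarchy, term_path: str | Path, edge_path: str | Path) -> None:
    with open(term_path, "w", encoding="utf-8") as fh:
        for t in h.terms.values():
            fh.write(
                json.dumps(
                    {
                        "id": t.id,
                        "name": t.name,
                        "synonyms": list(t.synonyms),
                        "definition": t.definition,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    with open(edge_path, "w", encoding="utf-8") as fh:
        for child, parent in h.hypernym_pairs:
            fh.write(f"{child}\t{parent}\n")


def load_links(path: str | Path, few_shot_size: int = 0) -> AlignmentSet:
    """Load a gold linkage from an entity_id<TAB>term_id TSV."""
    pairs: list[AlignmentPair] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}"
                )
            pairs.append(AlignmentPair(cols[0], cols[1]))
    return AlignmentSet(pairs, few_shot_size=few_shot_size)


def write_links(links: AlignmentSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in links.pairs:
            fh.write(f"{p.entity_id}\t{p.term_id}\n")
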