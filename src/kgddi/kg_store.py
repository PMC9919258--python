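"""Typed knowledge-graph store: load, validate, index, and sample neighbors.

Entities are drugs, proteins, genes, or diseases; edges are relation-labeled
triples ``(head, relation, tail)``. The adjacency view is undirected by
default (each stored triple contributes an inverse edge) so that
protein/gene/disease context reaches drug nodes during graph convolution;
a directed view is available via ``directed=True``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

ENTITY_TYPES = ("drug", "protein", "gene", "disease")


class KGError(ValueError):
    """Fatal validation error in knowledge-graph input."""


@dataclass(frozen=True)
class Entity:
    id: int
    name: str
    etype: str


@dataclass(frozen=True)
class Relation:
    id: int
    name: str


@dataclass(frozen=True)
class Triple:
    head: int
    relation: int
    tail: int


@dataclass
class KnowledgeGraph:
    """Validated KG with dense entity/relation ids and a neighbor index.

    ``adjacency[v]`` lists ``(relation_id, neighbor_id)`` pairs; for every
    stored triple (h, r, t) it holds (r, t) under h and — unless the graph
    was built directed — (r, h) under t.
    """

    entities: list[Entity]
    relations: list[Relation]
    triples: list[Triple]
    adjacency: dict[int, list[tuple[int, int]]] = field(repr=False)
    directed: bool = False

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    def name_to_id(self) -> dict[str, int]:
        return {e.name: e.id for e in self.entities}

    def drug_ids(self) -> list[int]:
        return [e.id for e in self.entities if e.etype == "drug"]

    def entity_type_counts(self) -> dict[str, int]:
        return dict(Counter(e.etype for e in self.entities))

    def relation_counts(self) -> dict[str, int]:
        by_id = Counter(t.relation for t in self.triples)
        return {r.name: by_id.get(r.id, 0) for r in self.relations}


def build_kg(
    entities: list[Entity],
    relations: list[Relation],
    triples: list[Triple],
    directed: bool = False,
    allow_self: bool = False,
) -> KnowledgeGraph:
    """Assemble a KnowledgeGraph from resolved components.

    Deduplicates triples (keeping first occurrence order) and builds the
    adjacency index. Self-relation triples (head == tail) are rejected
    unless ``allow_self``.
    """
    for i, e in enumerate(entities):
        if e.id != i:
            raise KGError(f"entity ids must be dense 0..E-1; got id {e.id} at position {i}")
        if e.etype not in ENTITY_TYPES:
            raise KGError(f"entity {e.name!r}: unknown type {e.etype!r}")
    names = [e.name for e in entities]
    if len(set(names)) != len(names):
        dup = [n for n, c in Counter(names).items() if c > 1]
        raise KGError(f"duplicate entity names: {dup[:5]}")
    rnames = [r.name for r in relations]
    if len(set(rnames)) != len(rnames):
        raise KGError("duplicate relation names")

    n_e, n_r = len(entities), len(relations)
    seen: set[tuple[int, int, int]] = set()
    dedup: list[Triple] = []
    for t in triples:
        if not (0 <= t.head < n_e and 0 <= t.tail < n_e):
            raise KGError(f"triple {t} references entity id outside 0..{n_e - 1}")
        if not 0 <= t.relation < n_r:
            raise KGError(f"triple {t} references relation id outside 0..{n_r - 1}")
        if t.head == t.tail and not allow_self:
            raise KGError(f"self-relation triple on entity {entities[t.head].name!r} rejected")
        key = (t.head, t.relation, t.tail)
        if key in seen:
            continue
        seen.add(key)
        dedup.append(t)

    adjacency: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_e)}
    for t in dedup:
        adjacency[t.head].append((t.relation, t.tail))
        if not directed:
            adjacency[t.tail].append((t.relation, t.head))
    return KnowledgeGraph(entities, relations, dedup, adjacency, directed)


def _read_tsv_rows(path, n_cols: int, what: str) -> list[tuple[list[str], int]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise KGError(
                    f"{what} {path}: line {lineno} has {len(parts)} columns, expected {n_cols}"
                )
            rows.append((parts, lineno))
    return rows


def load_triples(triple_path, entity_path, directed: bool = False) -> KnowledgeGraph:
    """Load a KG from a triple TSV (head, relation, tail) and entity TSV (id, name, etype).

    Triple endpoints are entity *names* resolved against the entity file;
    relation names get dense ids in order of first appearance. Unknown
    entities, malformed rows, and an empty triple file are fatal.
    """
    entities = []
    for parts, lineno in _read_tsv_rows(entity_path, 3, "entity file"):
        entities.append(Entity(id=int(parts[0]), name=parts[1], etype=parts[2]))
    entities.sort(key=lambda e: e.id)

    name_to_id = {e.name: e.id for e in entities}
    rel_ids: dict[str, int] = {}
    triples = []
    triple_rows = _read_tsv_rows(triple_path, 3, "triple file")
    if not triple_rows:
        raise KGError(f"triple file {triple_path} contains no triples")
    for (h, r, t), lineno in triple_rows:
        for endpoint in (h, t):
            if endpoint not in name_to_id:
                raise KGError(
                    f"triple file line {lineno}: entity {endpoint!r} not in entity file"
                )
        rid = rel_ids.setdefault(r, len(rel_ids))
        triples.append(Triple(name_to_id[h], rid, name_to_id[t]))
    relations = [Relation(i, name) for name, i in sorted(rel_ids.items(), key=lambda kv: kv[1])]
    return build_kg(entities, relations, triples, directed=directed)


def neighbors(kg: KnowledgeGraph, v: int) -> list[tuple[int, int]]:
    """Full (relation, neighbor) list of entity ``v``; empty if isolated."""
    if not 0 <= v < kg.n_entities:
        raise KGError(f"entity id {v} outside 0..{kg.n_entities - 1}")
    return list(kg.adjacency[v])


def sample_neighbors(
    kg: KnowledgeGraph, v: int, n: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Uniformly sample exactly ``n`` (relation, neighbor) entries for ``v``.

    Without replacement when degree >= n (a subset), with replacement when
    degree < n (so receptive fields stay shape-regular). Isolated entities
    are fatal: filter isolated drugs upstream before training.
    """
    nbrs = neighbors(kg, v)
    if not nbrs:
        raise KGError(
            f"entity {kg.entities[v].name!r} is isolated; filter isolated drugs upstream"
        )
    if n < 1:
        raise KGError("neighbor sample size must be >= 1")
    replace = len(nbrs) < n
    idx = rng.choice(len(nbrs), size=n, replace=replace)
    return [nbrs[i] for i in idx]
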