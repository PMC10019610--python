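"""Readers and containers for DRKG-dialect knowledge-graph resources.

The DRKG TSV dialect encodes the entity type inside the entity ID
(``Compound::DB00001``, ``Disease::MESH:D003141``) and ships triples as
headerless ``head<TAB>relation<TAB>tail`` lines.  This module parses those
files into typed containers, restricts the graph to a chosen set of entity
types, aligns pretrained embedding vectors with graph entity indices, and
loads the drug-name resources needed to compare rankings against a
name-keyed clinical-trials list.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EntityType",
    "EntityRef",
    "Triple",
    "KnowledgeGraph",
    "NameMap",
    "MalformedLineError",
    "read_triples",
    "filter_graph",
    "build_graph",
    "read_embeddings",
    "write_embeddings",
    "select_entities",
    "read_candidate_list",
    "read_name_map",
    "is_treats_relation",
    "DEFAULT_KEEP_TYPES",
    "DRUGBANK_ID_PATTERN",
    "COVID_KEYWORDS",
]


class EntityType(str, Enum):
    """Entity classes retained by the default graph restriction."""

    GENE = "gene"
    COMPOUND = "compound"
    ANATOMY = "anatomy"
    DISEASE = "disease"
    OTHER = "other"


#: Default restriction: gene, compound, anatomy and disease entities.
DEFAULT_KEEP_TYPES = frozenset(
    {EntityType.GENE, EntityType.COMPOUND, EntityType.ANATOMY, EntityType.DISEASE}
)

#: DrugBank-style compound IDs mark the "drug" subset of compounds.
DRUGBANK_ID_PATTERN = re.compile(r"DB\d+$")

#: Substrings (case-insensitive) identifying COVID-19 disease entities.
COVID_KEYWORDS = ("sars-cov2", "sars-cov-2", "sars_cov2", "covid")

_KNOWN_PREFIXES = {
    "gene": EntityType.GENE,
    "compound": EntityType.COMPOUND,
    "anatomy": EntityType.ANATOMY,
    "disease": EntityType.DISEASE,
}


class MalformedLineError(ValueError):
    """A triples line that does not split into head/relation/tail."""


@dataclass(frozen=True)
class EntityRef:
    """A typed entity; ``raw_id`` is the full ``Type::local`` token."""

    entity_type: EntityType
    local_id: str
    raw_id: str

    @classmethod
    def parse(cls, raw_id: str) -> "EntityRef":
        prefix, sep, local = raw_id.partition("::")
        if not sep:
            return cls(EntityType.OTHER, raw_id, raw_id)
        etype = _KNOWN_PREFIXES.get(prefix.lower(), EntityType.OTHER)
        return cls(etype, local, raw_id)


@dataclass(frozen=True)
class Triple:
    head: EntityRef
    relation: str
    tail: EntityRef


@dataclass
class KnowledgeGraph:
    """Typed triples plus a dense, stable 0-based entity index.

    Entity indices are assigned in order of first appearance in the triple
    list (heads before tails within a triple), so the index assignment is
    reproducible byte-for-byte from the same input.
    """

    entities: list[EntityRef]
    triples: list[Triple]
    relation_types: set[str]
    index: dict[str, int] = field(repr=False)

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    def entity_index(self, ref: EntityRef | str) -> int:
        raw = ref if isinstance(ref, str) else ref.raw_id
        return self.index[raw]


def read_triples(path: str | Path, strict: bool = True) -> list[Triple]:
    """Read a headerless ``head<TAB>relation<TAB>tail`` TSV.

    Lines with fewer than three tab-separated fields are fatal in strict
    mode (reported with their line number); in lenient mode they are
    skipped with a counted warning.  Empty lines are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"triples file not found: {path}")
    triples: list[Triple] = []
    bad_lines: list[int] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or any(not f for f in fields[:3]):
                if strict:
                    raise MalformedLineError(
                        f"{path}:{lineno}: expected 3 tab-separated fields, "
                        f"got {len(fields)}"
                    )
                bad_lines.append(lineno)
                continue
            head, relation, tail = fields[0], fields[1], fields[2]
            triples.append(Triple(EntityRef.parse(head), relation, EntityRef.parse(tail)))
    if bad_lines:
        warnings.warn(
            f"{path}: skipped {len(bad_lines)} malformed line(s) "
            f"(first at line {bad_lines[0]})",
            stacklevel=2,
        )
    return triples


def build_graph(triples: Iterable[Triple]) -> KnowledgeGraph:
    """Assemble a graph whose entities are the triple endpoints."""
    index: dict[str, int] = {}
    entities: list[EntityRef] = []
    kept: list[Triple] = []
    relations: set[str] = set()
    for t in triples:
        for ref in (t.head, t.tail):
            if ref.raw_id not in index:
                index[ref.raw_id] = len(entities)
                entities.append(ref)
        kept.append(t)
        relations.add(t.relation)
    return KnowledgeGraph(entities=entities, triples=kept, relation_types=relations, index=index)


def filter_graph(
    triples: Iterable[Triple],
    keep_types: Iterable[EntityType] = DEFAULT_KEEP_TYPES,
) -> KnowledgeGraph:
    """Restrict to triples whose head AND tail types are both kept.

    With the default ``keep_types`` this is the gene/compound/anatomy/
    disease restriction applied to the full DRKG.  Duplicate triples are
    retained here (the reader is lossless); they collapse later at
    adjacency construction.
    """
    keep = frozenset(EntityType(t) for t in keep_types)
    if not keep:
        raise ValueError("keep_types must be non-empty")
    kept = [t for t in triples if t.head.entity_type in keep and t.tail.entity_type in keep]
    if not kept:
        warnings.warn("filter_graph produced an empty graph", stacklevel=2)
    return build_graph(kept)


def read_embeddings(
    path: str | Path,
    graph: KnowledgeGraph,
    strict: bool = True,
) -> np.ndarray:
    """Load entity embeddings aligned to graph entity indices.

    Accepts either a TSV (``entity_id<TAB>v1<TAB>...``) or a ``.npz``
    archive with ``ids`` and ``matrix`` arrays.  Alignment is by entity
    ID, never by file position.  Missing vectors are fatal in strict mode;
    a dimensionality mismatch between rows is always fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"embeddings file not found: {path}")
    vectors: dict[str, np.ndarray] = {}
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as archive:
            ids = [str(x) for x in archive["ids"]]
            matrix = np.asarray(archive["matrix"], dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[0] != len(ids):
            raise ValueError(f"{path}: matrix shape {matrix.shape} does not match {len(ids)} ids")
        vectors = {eid: matrix[i] for i, eid in enumerate(ids)}
        dim = matrix.shape[1]
    else:
        dim = -1
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                row = np.asarray([float(v) for v in fields[1:]], dtype=np.float64)
                if dim < 0:
                    dim = row.size
                elif row.size != dim:
                    raise ValueError(
                        f"{path}:{lineno}: vector of length {row.size}, expected {dim}"
                    )
                vectors[fields[0]] = row
    missing = [e.raw_id for e in graph.entities if e.raw_id not in vectors]
    if missing:
        msg = f"{len(missing)} graph entities lack embedding vectors (e.g. {missing[:3]})"
        if strict:
            raise KeyError(msg)
        warnings.warn(msg + "; filled with zeros", stacklevel=2)
    table = np.zeros((graph.n_entities, dim), dtype=np.float64)
    for i, ent in enumerate(graph.entities):
        if ent.raw_id in vectors:
            table[i] = vectors[ent.raw_id]
    if not np.all(np.isfinite(table)):
        raise ValueError(f"{path}: embeddings contain non-finite values")
    return table


def write_embeddings(path: str | Path, graph: KnowledgeGraph, table: np.ndarray) -> None:
    """Persist embeddings as an ``.npz`` (ids + row-major matrix)."""
    np.savez(
        Path(path),
        ids=np.asarray([e.raw_id for e in graph.entities]),
        matrix=np.asarray(table, dtype=np.float64),
    )


def _as_predicate(pattern: None | str | re.Pattern | Callable[[str], bool]):
    if pattern is None:
        return lambda _local: True
    if callable(pattern) and not isinstance(pattern, re.Pattern):
        return pattern
    compiled = re.compile(pattern) if isinstance(pattern, str) else pattern
    return lambda local: compiled.search(local) is not None


def select_entities(
    graph: KnowledgeGraph,
    entity_type: EntityType | str,
    id_predicate: None | str | re.Pattern | Callable[[str], bool] = None,
) -> list[int]:
    """Indices of entities of a type, optionally filtered on local_id.

    Returned in ascending entity-index order (deterministic).  Typical
    uses: DrugBank-ID compounds as the drug set, COVID-keyword diseases
    as the prediction target set.
    """
    etype = EntityType(entity_type)
    pred = _as_predicate(id_predicate)
    return [i for i, e in enumerate(graph.entities) if e.entity_type == etype and pred(e.local_id)]


def select_drugs(graph: KnowledgeGraph) -> list[int]:
    """Compounds with DrugBank-style IDs (``DB`` + digits)."""
    return select_entities(graph, EntityType.COMPOUND, DRUGBANK_ID_PATTERN)


def select_covid_diseases(graph: KnowledgeGraph, keywords: Sequence[str] = COVID_KEYWORDS) -> list[int]:
    """Diseases whose local ID contains a COVID-19 keyword."""
    lowered = tuple(k.lower() for k in keywords)
    return select_entities(
        graph,
        EntityType.DISEASE,
        lambda local: any(k in local.lower() for k in lowered),
    )


#: Relation-token markers of the compound-treats-disease family across the
#: DRKG source vocabularies (GNBR "T", Hetionet "CtD", DrugBank "treats").
_TREATS_MARKERS = ("::t::", "::ctd::", "treats")


def is_treats_relation(relation: str) -> bool:
    rel = relation.lower()
    return any(marker in rel for marker in _TREATS_MARKERS)


def normalize_name(name: str) -> str:
    return name.strip().casefold()


def read_candidate_list(path: str | Path) -> set[str]:
    """Read a one-name-per-line drug list into a normalized name set."""
    path = Path(path)
    names: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            norm = normalize_name(line)
            if norm:
                names.append(norm)
    unique = set(names)
    if not unique:
        warnings.warn(f"{path}: empty candidate list", stacklevel=2)
    elif len(unique) < len(names):
        warnings.warn(
            f"{path}: collapsed {len(names) - len(unique)} duplicate name(s)",
            stacklevel=2,
        )
    return unique


class NameMap:
    """Compound local_id -> human-readable drug name.

    Lookups preserve the stored casing of names; key matching is
    case-insensitive.  Unknown IDs resolve to ``"<unknown>"``.
    """

    UNKNOWN = "<unknown>"

    def __init__(self, mapping: dict[str, str] | None = None):
        self._names: dict[str, str] = {}
        for key, value in (mapping or {}).items():
            self._names[key.casefold()] = value

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, local_id: str) -> bool:
        return local_id.casefold() in self._names

    def get(self, local_id: str) -> str:
        return self._names.get(local_id.casefold(), self.UNKNOWN)


def read_name_map(path: str | Path) -> NameMap:
    """Read a two-column ``drugbank_id<TAB>name`` TSV."""
    path = Path(path)
    mapping: dict[str, str] = {}
    seen: set[str] = set()
    dupes = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise MalformedLineError(f"{path}:{lineno}: expected 2 tab-separated columns")
            key = fields[0].strip()
            if key.casefold() in seen:
                dupes += 1
            seen.add(key.casefold())
            mapping[key] = fields[1].strip()
    if dupes:
        warnings.warn(f"{path}: {dupes} duplicate key(s), last value wins", stacklevel=2)
    return NameMap(mapping)
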