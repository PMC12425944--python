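"""Normalized Biolink-typed knowledge graph with KGX TSV serialization.

Nodes are identified by CURIEs (``PREFIX:LOCAL``) and typed with Biolink
classes; edges carry Biolink predicates plus the statistical and provenance
attributes of the assertion they came from. Parallel edges are preserved —
the same subject–predicate–object triple reported by two supplementary
tables is two edges, and "unique edges" is a view computed over canonical
keys, never a destructive merge. Assertions whose subject or object cannot
be resolved to a CURIE are dropped, but never silently: every drop lands in
a ledger with a reason.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional

from .transform import Assertion

CURIE_RE = re.compile(r"^[A-Za-z0-9.]+:\S+$")
CATEGORY_RE = re.compile(r"^biolink:[A-Z][A-Za-z]*$")
PREDICATE_RE = re.compile(r"^biolink:[a-z][a-z_]*$")

EDGE_COLUMNS = [
    "subject", "predicate", "object",
    "p_value", "adjusted_p", "correction_method", "effect_size",
    "effect_metric", "sample_size", "statistical_test", "nlp_type",
    "subject_map_db", "object_map_db", "significant", "score",
    "publication_id", "table_id", "caption", "notes",
]
NODE_COLUMNS = ["id", "category", "name"]

_EDGE_ATTR_COLUMNS = EDGE_COLUMNS[3:15]  # attribute slice of the edge row
_FLOAT_ATTRS = {"p_value", "adjusted_p", "effect_size", "score"}
_INT_ATTRS = {"sample_size"}
_BOOL_ATTRS = {"significant"}


class ValidationError(ValueError):
    """Graph structure violates an invariant (referential integrity, ...)."""


@dataclass(frozen=True)
class Node:
    curie: str
    category: str
    name: str

    def __post_init__(self) -> None:
        if not CURIE_RE.match(self.curie):
            raise ValidationError(f"malformed CURIE: {self.curie!r}")
        if not CATEGORY_RE.match(self.category):
            raise ValidationError(f"malformed Biolink class: {self.category!r}")


@dataclass
class Edge:
    subject: str
    predicate: str
    object: str
    attributes: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not PREDICATE_RE.match(self.predicate):
            raise ValidationError(f"malformed Biolink predicate: {self.predicate!r}")
        # a null attribute and an absent one are the same thing
        self.attributes = {k: v for k, v in self.attributes.items() if v is not None}
        score = self.attributes.get("score")
        if score is not None and not score > 0:
            raise ValidationError(f"edge score must be > 0, got {score}")

    @property
    def score(self) -> Optional[float]:
        return self.attributes.get("score")


class PredicateRegistry:
    """Predicate → symmetry map, seeded with the four core predicates.

    ``associated_with`` and ``correlated_with`` carry no inherent direction;
    ``affects`` and ``treats`` do. Extensible for graphs using further
    predicates.
    """

    _SEED = {
        "biolink:associated_with": True,
        "biolink:correlated_with": True,
        "biolink:affects": False,
        "biolink:treats": False,
    }

    def __init__(self, extra: dict[str, bool] | None = None) -> None:
        self._symmetric = dict(self._SEED)
        if extra:
            for pred, sym in extra.items():
                self.register(pred, symmetric=sym)

    def register(self, predicate: str, symmetric: bool) -> None:
        if not PREDICATE_RE.match(predicate):
            raise ValidationError(f"malformed predicate: {predicate!r}")
        self._symmetric[predicate] = bool(symmetric)

    def is_symmetric(self, predicate: str) -> bool:
        try:
            return self._symmetric[predicate]
        except KeyError:
            raise ValidationError(f"predicate not in registry: {predicate!r}") from None

    def __contains__(self, predicate: str) -> bool:
        return predicate in self._symmetric

    def predicates(self) -> list[str]:
        return sorted(self._symmetric)


class Resolver:
    """Local, deterministic label → CURIE lookup table.

    Keys are case-folded labels, optionally disambiguated by a Biolink
    category hint (a gene symbol and a taxon name may collide). Loaded from
    a five-column TSV: label, category_hint, curie, name, source_db. A label
    maps to at most one entry per category hint.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], tuple[str, str, str]] = {}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Resolver":
        resolver = cls()
        with open(path, "r", encoding="utf-8-sig", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None:
                return resolver
            for row in reader:
                if not row or all(not c for c in row):
                    continue
                label, hint, curie, name, source_db = (row + [""] * 5)[:5]
                resolver.add(label, curie, name, source_db, category_hint=hint)
        return resolver

    def add(
        self, label: str, curie: str, name: str, source_db: str,
        category_hint: str = "",
    ) -> None:
        key = (label.casefold(), category_hint)
        if key in self._entries and self._entries[key] != (curie, name, source_db):
            raise ValidationError(
                f"resolver conflict for label {label!r} (hint {category_hint!r})"
            )
        self._entries[key] = (curie, name, source_db)

    def resolve(
        self, label: str, category_hint: str = ""
    ) -> Optional[tuple[str, str, str]]:
        """Return (curie, canonical name, source_db) or None."""
        key = label.casefold()
        hit = self._entries.get((key, category_hint))
        if hit is None and category_hint:
            hit = self._entries.get((key, ""))
        return hit

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("label\tcategory_hint\tcurie\tname\tsource_db\n")
            for (label, hint), (curie, name, db) in sorted(self._entries.items()):
                fh.write(f"{label}\t{hint}\t{curie}\t{name}\t{db}\n")


@dataclass
class KnowledgeGraph:
    """Nodes keyed by CURIE plus an ordered multi-edge list."""

    nodes: dict[str, Node] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)

    def add_node(self, node: Node) -> None:
        existing = self.nodes.get(node.curie)
        if existing is not None and existing != node:
            raise ValidationError(
                f"conflicting node definitions for {node.curie}"
            )
        self.nodes[node.curie] = node

    def add_edge(self, edge: Edge) -> None:
        if edge.subject not in self.nodes or edge.object not in self.nodes:
            raise ValidationError(
                f"edge endpoints must be nodes: {edge.subject} -> {edge.object}"
            )
        self.edges.append(edge)

    def validate(self) -> None:
        for e in self.edges:
            if e.subject not in self.nodes or e.object not in self.nodes:
                raise ValidationError(
                    f"dangling edge endpoint: {e.subject} -> {e.object}"
                )

    def publication_ids(self) -> list[str]:
        return sorted({e.provenance.get("publication_id", "") for e in self.edges})


# ---------------------------------------------------------------------------
# Normalization


def normalize_assertions(
    assertions: Iterable[Assertion],
    resolver: Resolver,
    significance_alpha: float = 0.05,
) -> tuple[KnowledgeGraph, list[dict[str, str]]]:
    """Resolve assertion labels to CURIEs; unresolvable assertions are dropped.

    Returns the graph plus a drop ledger (one record per dropped assertion,
    with the raw labels and a reason). Emitted edges + dropped records always
    equals input assertions. Node names come from the resolver's canonical
    name, not the raw table label.
    """
    from .transform import flag_significance

    graph = KnowledgeGraph()
    dropped: list[dict[str, str]] = []
    for a in assertions:
        subj = resolver.resolve(a.subject_label, a.subject_category)
        obj = resolver.resolve(a.object_label, a.object_category)
        if subj is None or obj is None:
            reason = []
            if subj is None:
                reason.append("subject_unmapped")
            if obj is None:
                reason.append("object_unmapped")
            dropped.append(
                {
                    "subject_label": a.subject_label,
                    "object_label": a.object_label,
                    "predicate": a.predicate,
                    "reason": "+".join(reason),
                    "table_id": a.provenance.get("table_id", ""),
                }
            )
            continue
        s_curie, s_name, s_db = subj
        o_curie, o_name, o_db = obj
        graph.add_node(Node(s_curie, a.subject_category, s_name))
        graph.add_node(Node(o_curie, a.object_category, o_name))
        attrs = dict(a.attributes)
        attrs["subject_map_db"] = s_db
        attrs["object_map_db"] = o_db
        attrs["significant"] = flag_significance(a.attributes, significance_alpha)
        graph.add_edge(
            Edge(
                subject=s_curie,
                predicate=a.predicate,
                object=o_curie,
                attributes=attrs,
                provenance=dict(a.provenance),
            )
        )
    return graph, dropped


# ---------------------------------------------------------------------------
# Canonical edge identity


def canonical_edge_key(edge: Edge, registry: PredicateRegistry) -> tuple[str, str, str]:
    """Provenance-free identity of a triple.

    Symmetric predicates order endpoints lexicographically so that A–B and
    B–A coincide; directed predicates keep subject/object as-is.
    """
    if registry.is_symmetric(edge.predicate):
        lo, hi = sorted((edge.subject, edge.object))
        return (lo, edge.predicate, hi)
    return (edge.subject, edge.predicate, edge.object)


def unique_edge_count(graph: KnowledgeGraph, registry: PredicateRegistry) -> int:
    """Number of distinct canonical triples; always <= total edge count."""
    return len({canonical_edge_key(e, registry) for e in graph.edges})


# ---------------------------------------------------------------------------
# KGX TSV serialization


def _serialize_cell(v: Any) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        return repr(v)
    return str(v)


def _parse_attr(column: str, raw: str) -> Any:
    if raw == "":
        return None
    if column in _FLOAT_ATTRS:
        return float(raw)
    if column in _INT_ATTRS:
        return int(float(raw))
    if column in _BOOL_ATTRS:
        return raw == "true"
    return raw


def write_kgx(
    graph: KnowledgeGraph, nodes_path: str | Path, edges_path: str | Path
) -> None:
    """Write the graph as a KGX TSV pair (nodes.tsv + edges.tsv).

    Byte-stable: nodes sorted by CURIE, edges in insertion order, nulls as
    empty fields, UTF-8, ``\\n`` line ends.
    """
    graph.validate()
    with open(nodes_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(NODE_COLUMNS) + "\n")
        for curie in sorted(graph.nodes):
            n = graph.nodes[curie]
            fh.write(f"{n.curie}\t{n.category}\t{n.name}\n")
    with open(edges_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in graph.edges:
            cells = [e.subject, e.predicate, e.object]
            cells += [_serialize_cell(e.attributes.get(c)) for c in _EDGE_ATTR_COLUMNS]
            cells += [
                _serialize_cell(e.provenance.get("publication_id")),
                _serialize_cell(e.provenance.get("table_id")),
                _serialize_cell(e.attributes.get("caption")),
                _serialize_cell(e.attributes.get("notes")),
            ]
            fh.write("\t".join(cells) + "\n")


def read_kgx(nodes_path: str | Path, edges_path: str | Path) -> KnowledgeGraph:
    """Read a KGX TSV pair back into a graph; inverse of :func:`write_kgx`."""
    graph = KnowledgeGraph()
    with open(nodes_path, "r", encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != NODE_COLUMNS:
            raise ValidationError(f"unexpected nodes.tsv header: {header}")
        for i, row in enumerate(reader, start=2):
            if len(row) != len(NODE_COLUMNS):
                raise ValidationError(f"nodes.tsv row {i}: expected 3 fields")
            graph.add_node(Node(*row))
    with open(edges_path, "r", encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != EDGE_COLUMNS:
            raise ValidationError(f"unexpected edges.tsv header: {header}")
        for i, row in enumerate(reader, start=2):
            if len(row) != len(EDGE_COLUMNS):
                raise ValidationError(
                    f"edges.tsv row {i}: expected {len(EDGE_COLUMNS)} fields"
                )
            rec = dict(zip(EDGE_COLUMNS, row))
            attrs = {c: _parse_attr(c, rec[c]) for c in _EDGE_ATTR_COLUMNS}
            attrs["caption"] = rec["caption"] or None
            attrs["notes"] = rec["notes"] or None
            attrs = {k: v for k, v in attrs.items() if v is not None}
            # significant=False must survive the null-stripping above
            if rec["significant"] != "":
                attrs["significant"] = rec["significant"] == "true"
            if rec["subject"] not in graph.nodes or rec["object"] not in graph.nodes:
                raise ValidationError(
                    f"edges.tsv row {i}: endpoint not present in nodes.tsv"
                )
            graph.add_edge(
                Edge(
                    subject=rec["subject"],
                    predicate=rec["predicate"],
                    object=rec["object"],
                    attributes=attrs,
                    provenance={
                        "publication_id": rec["publication_id"],
                        "table_id": rec["table_id"],
                    },
                )
            )
    return graph
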