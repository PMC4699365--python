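"""In-memory property graph for high-content screen data.

The data model mirrors how a screen is organised: a single *grouping*
object kind (gene, strain, condition — the entity a perturbation targets),
one *descriptive* kind carrying the quantitative per-object measurements
(typically the cell), and any number of *metadata* kinds (images, wells,
experiments) that hang off the descriptive rows.  Nodes hold property
tuples (numeric features, text metadata, URL link-outs) plus a set of
binary labels; edges record membership/derivation links such as a cell
belonging to a gene or being extracted from an image.

The store is backend-agnostic and adjacency-indexed, with a JSON-lines
serialization for persistence.  External node identity is always the pair
``(kind, ordered ID property values)``; the integer ``node_id`` is an
internal surrogate.
"""

from __future__ import annotations

import enum
import json
import math
from collections import deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

from .errors import (
    DuplicateObjectError,
    GraphIntegrityError,
    ImportConflictError,
    LabelValueError,
    MissingNodeError,
    SchemaError,
)

__all__ = [
    "PropertyType",
    "Role",
    "ObjectKind",
    "Node",
    "Edge",
    "PropertyGraph",
]


class PropertyType(enum.Enum):
    """Column type in the screen import format.

    NUMBER is the only kind that becomes a queryable feature; TEXT and URL
    are stored as opaque metadata, ID columns define node identity.
    """

    TEXT = "TEXT"
    NUMBER = "NUMBER"
    ID = "ID"
    URL = "URL"

    @classmethod
    def parse(cls, token: str) -> "PropertyType":
        """Parse a type token case-insensitively; unknown tokens raise."""
        try:
            return cls[token.strip().upper()]
        except KeyError:
            raise SchemaError(
                f"unknown property type {token!r}; "
                f"expected one of TEXT, NUMBER, ID, URL"
            ) from None

    @property
    def queryable(self) -> bool:
        return self is PropertyType.NUMBER


class Role(enum.Enum):
    GROUPING = "grouping"
    DESCRIPTIVE = "descriptive"
    METADATA = "metadata"


@dataclass(frozen=True)
class ObjectKind:
    """A node type, e.g. Gene (grouping), Cell (descriptive), Image.

    When a screen has a single data layer the grouping kind carries the
    measurements itself; that is modelled as role=GROUPING with
    ``self_descriptive=True``.
    """

    name: str
    role: Role
    self_descriptive: bool = False


IdTuple = tuple[tuple[str, str], ...]  # ordered (ID property name, value)


@dataclass
class Node:
    kind: str
    node_id: int
    id_values: IdTuple
    properties: dict[str, float | str] = field(default_factory=dict)
    labels: set[str] = field(default_factory=set)

    @property
    def id_key(self) -> tuple[str, ...]:
        """The ordered ID values alone — the external identity within a kind."""
        return tuple(v for _, v in self.id_values)


@dataclass(frozen=True)
class Edge:
    source: int
    target: int
    relation: str


def _is_numeric(value) -> bool:
    return isinstance(value, (int, float)) and not isinstance(value, bool)


def _normalize_ids(id_values) -> IdTuple:
    return tuple((str(n), str(v)) for n, v in id_values)


class PropertyGraph:
    """Adjacency-indexed property-graph store; single-writer, no locking."""

    def __init__(self) -> None:
        self.kinds: dict[str, ObjectKind] = {}
        self._nodes: dict[int, Node] = {}
        self._index: dict[tuple[str, tuple[str, ...]], int] = {}
        self._out: dict[int, set[tuple[int, str]]] = {}
        self._in: dict[int, set[tuple[int, str]]] = {}
        self._edges: set[Edge] = set()
        self._feature_catalog: dict[str, set[str]] = {}
        self._label_catalog: dict[str, set[str]] = {}
        self._next_id = 0
        self._membership_cache: dict[int, list[int]] | None = None

    # -- kinds ------------------------------------------------------------

    def register_kind(self, kind: ObjectKind) -> ObjectKind:
        if kind.role is Role.GROUPING and any(
            k.role is Role.GROUPING for k in self.kinds.values()
            if k.name != kind.name
        ):
            raise SchemaError("a graph has exactly one grouping kind")
        self.kinds[kind.name] = kind
        self._feature_catalog.setdefault(kind.name, set())
        self._label_catalog.setdefault(kind.name, set())
        return kind

    def kind_of(self, name: str) -> ObjectKind:
        try:
            return self.kinds[name]
        except KeyError:
            raise SchemaError(f"unknown object kind {name!r}") from None

    @property
    def grouping_kind(self) -> ObjectKind:
        for k in self.kinds.values():
            if k.role is Role.GROUPING:
                return k
        raise SchemaError("graph has no grouping kind")

    @property
    def descriptive_kind(self) -> ObjectKind:
        for k in self.kinds.values():
            if k.role is Role.DESCRIPTIVE:
                return k
        g = self.grouping_kind
        if g.self_descriptive:
            return g
        raise SchemaError("graph has no descriptive kind")

    # -- nodes ------------------------------------------------------------

    def _check_properties(self, kind: str, properties: Mapping) -> None:
        for name, value in properties.items():
            if _is_numeric(value) and not math.isfinite(value):
                raise SchemaError(
                    f"non-finite NUMBER value for {kind}.{name}: {value!r}; "
                    "missing values must be omitted, not encoded"
                )

    def add_node(self, kind: str, id_values, properties=None) -> int:
        """Insert a new node; duplicates of (kind, IDs) raise.

        Use :meth:`merge_node` for the import path where repeated rows
        accumulate onto one node.
        """
        k = self.kind_of(kind)
        ids = _normalize_ids(id_values)
        if k.role is not Role.METADATA and not ids:
            raise SchemaError(
                f"{kind} nodes require at least one ID value")
        key = (kind, tuple(v for _, v in ids))
        if key in self._index:
            raise DuplicateObjectError(
                f"node already exists: {kind} {key[1]}")
        properties = dict(properties or {})
        self._check_properties(kind, properties)
        node_id = self._next_id
        self._next_id += 1
        node = Node(kind=kind, node_id=node_id, id_values=ids,
                    properties=properties)
        self._nodes[node_id] = node
        self._index[key] = node_id
        self._out[node_id] = set()
        self._in[node_id] = set()
        for name, value in properties.items():
            if _is_numeric(value):
                self._feature_catalog[kind].add(name)
        self._membership_cache = None
        return node_id

    def merge_node(self, kind: str, id_values, properties=None) -> int:
        """Insert, or fold properties into an existing (kind, IDs) node.

        New properties are added; a conflicting value for an existing
        property raises ImportConflictError.
        """
        ids = _normalize_ids(id_values)
        key = (kind, tuple(v for _, v in ids))
        existing = self._index.get(key)
        if existing is None:
            return self.add_node(kind, ids, properties)
        node = self._nodes[existing]
        properties = dict(properties or {})
        self._check_properties(kind, properties)
        for name, value in properties.items():
            if name in node.properties and node.properties[name] != value:
                raise ImportConflictError(
                    f"conflicting values for {kind}.{name} on {key[1]}: "
                    f"{node.properties[name]!r} vs {value!r}")
            node.properties[name] = value
            if _is_numeric(value):
                self._feature_catalog[kind].add(name)
        return existing

    def get_node(self, kind: str, id_key) -> Node:
        """Look up by kind and ordered ID values (names optional)."""
        if id_key and isinstance(id_key[0], (tuple, list)):
            id_key = tuple(str(v) for _, v in id_key)
        else:
            id_key = tuple(str(v) for v in id_key)
        node_id = self._index.get((kind, id_key))
        if node_id is None:
            raise MissingNodeError(f"no {kind} node with IDs {id_key}")
        return self._nodes[node_id]

    def has_node(self, kind: str, id_key) -> bool:
        try:
            self.get_node(kind, id_key)
            return True
        except MissingNodeError:
            return False

    def node(self, node_id: int) -> Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise MissingNodeError(f"no node with id {node_id}") from None

    def nodes_of_kind(self, kind: str) -> Iterator[Node]:
        self.kind_of(kind)
        for node in self._nodes.values():
            if node.kind == kind:
                yield node

    def node_count(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self._nodes)
        return sum(1 for _ in self.nodes_of_kind(kind))

    # -- edges ------------------------------------------------------------

    def connect(self, source_id: int, target_id: int, relation: str) -> Edge:
        """Add a directed edge; repeated identical edges collapse to one."""
        if source_id not in self._nodes:
            raise MissingNodeError(f"no node with id {source_id}")
        if target_id not in self._nodes:
            raise MissingNodeError(f"no node with id {target_id}")
        edge = Edge(source_id, target_id, relation)
        if edge not in self._edges:
            self._edges.add(edge)
            self._out[source_id].add((target_id, relation))
            self._in[target_id].add((source_id, relation))
            self._membership_cache = None
        return edge

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(self._edges)

    def edge_count(self) -> int:
        return len(self._edges)

    def neighbors(self, node_id: int) -> set[int]:
        """Targets of outgoing edges."""
        self.node(node_id)
        return {t for t, _ in self._out[node_id]}

    # -- traversal ---------------------------------------------------------

    def owning_group(self, node_id: int) -> int:
        """The unique grouping node a descriptive node belongs to.

        Follows outgoing edges (membership/derivation links point from the
        detailed object towards its context).  A self-descriptive grouping
        node owns itself.
        """
        node = self.node(node_id)
        kind = self.kind_of(node.kind)
        if kind.role is Role.GROUPING and kind.self_descriptive:
            return node_id
        if kind.role is not Role.DESCRIPTIVE:
            raise GraphIntegrityError(
                f"owning_group is defined on descriptive nodes, "
                f"not {kind.role.value} ({node.kind})")
        found: set[int] = set()
        seen = {node_id}
        queue = deque([node_id])
        while queue:
            current = queue.popleft()
            for target, _ in self._out[current]:
                if target in seen:
                    continue
                seen.add(target)
                if self.kind_of(self._nodes[target].kind).role is Role.GROUPING:
                    found.add(target)
                else:
                    queue.append(target)
        if len(found) != 1:
            raise GraphIntegrityError(
                f"descriptive node {node.kind} {node.id_key} reaches "
                f"{len(found)} grouping nodes (expected exactly 1)")
        return found.pop()

    def membership_map(self) -> dict[int, list[int]]:
        """grouping node_id -> member descriptive node_ids (cached)."""
        if self._membership_cache is None:
            mapping: dict[int, list[int]] = {}
            desc = self.descriptive_kind
            for node in self.nodes_of_kind(desc.name):
                mapping.setdefault(
                    self.owning_group(node.node_id), []).append(node.node_id)
            self._membership_cache = mapping
        return self._membership_cache

    # -- labels ------------------------------------------------------------

    def set_labels(self, kind: str, id_key,
                   label_assignments: Mapping[str, int]) -> Node:
        """Apply binary annotations: value 1 attaches the label, 0 does not.

        Any other value is rejected.  All assigned label names (including
        0-valued ones) are registered in the kind's label catalog.
        """
        node = self.get_node(kind, id_key)
        for name, value in label_assignments.items():
            if isinstance(value, bool):
                value = int(value)
            if value not in (0, 1):
                raise LabelValueError(
                    f"label {name!r} on {kind} {node.id_key} has value "
                    f"{value!r}; labels are binary (0 or 1)")
            self._label_catalog[kind].add(name)
            if value == 1:
                node.labels.add(name)
            else:
                node.labels.discard(name)
        return node

    # -- catalogs -----------------------------------------------------------

    def feature_catalog(self, kind: str) -> list[str]:
        self.kind_of(kind)
        return sorted(self._feature_catalog[kind])

    def label_catalog(self, kind: str) -> list[str]:
        self.kind_of(kind)
        return sorted(self._label_catalog[kind])

    def register_feature(self, kind: str, name: str) -> None:
        """Pre-register a NUMBER property (e.g. a schema column whose cells
        may all be missing)."""
        self.kind_of(kind)
        self._feature_catalog[kind].add(name)

    # -- serialization ------------------------------------------------------

    def _sorted_nodes(self) -> list[Node]:
        return sorted(self._nodes.values(),
                      key=lambda n: (n.kind, n.id_key))

    def serialize(self, stream: IO[str]) -> None:
        """Write the graph as JSON lines (UTF-8): kinds, catalogs, nodes,
        edges — each in a stable sorted order so equal graphs serialize
        byte-identically."""
        def dump(obj) -> None:
            stream.write(json.dumps(obj, sort_keys=True,
                                    separators=(",", ":")) + "\n")

        for name in sorted(self.kinds):
            k = self.kinds[name]
            dump({"record": "kind", "name": k.name, "role": k.role.value,
                  "self_descriptive": k.self_descriptive})
        for name in sorted(self.kinds):
            dump({"record": "catalog", "kind": name,
                  "features": self.feature_catalog(name),
                  "labels": self.label_catalog(name)})
        for node in self._sorted_nodes():
            dump({"record": "node", "kind": node.kind,
                  "ids": [list(pair) for pair in node.id_values],
                  "properties": node.properties,
                  "labels": sorted(node.labels)})
        edge_rows = []
        for edge in self._edges:
            s, t = self._nodes[edge.source], self._nodes[edge.target]
            edge_rows.append({"record": "edge",
                              "source": [s.kind, list(s.id_key)],
                              "target": [t.kind, list(t.id_key)],
                              "relation": edge.relation})
        for row in sorted(edge_rows, key=lambda r: (r["source"], r["target"],
                                                    r["relation"])):
            dump(row)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            self.serialize(fh)

    @classmethod
    def deserialize(cls, lines: Iterable[str]) -> "PropertyGraph":
        graph = cls()
        pending_catalogs = []
        for i, line in enumerate(lines, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"bad JSON on line {i}: {exc}") from exc
            kind_rec = rec.get("record")
            if kind_rec == "kind":
                graph.register_kind(ObjectKind(
                    rec["name"], Role(rec["role"]),
                    bool(rec.get("self_descriptive", False))))
            elif kind_rec == "catalog":
                pending_catalogs.append(rec)
            elif kind_rec == "node":
                nid = graph.add_node(rec["kind"],
                                     [tuple(p) for p in rec["ids"]],
                                     rec["properties"])
                graph.node(nid).labels.update(rec.get("labels", ()))
            elif kind_rec == "edge":
                s = graph.get_node(rec["source"][0], rec["source"][1])
                t = graph.get_node(rec["target"][0], rec["target"][1])
                graph.connect(s.node_id, t.node_id, rec["relation"])
            else:
                raise SchemaError(f"unknown record type on line {i}: "
                                  f"{kind_rec!r}")
        for rec in pending_catalogs:
            graph._feature_catalog[rec["kind"]].update(rec["features"])
            graph._label_catalog[rec["kind"]].update(rec["labels"])
        return graph

    @classmethod
    def load(cls, path) -> "PropertyGraph":
        with open(path, encoding="utf-8") as fh:
            return cls.deserialize(fh)
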