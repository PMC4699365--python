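"""Multi-level ad-hoc querying over a screen property graph.

A query is a declarative :class:`QueryState`: the level it runs at
(grouping, e.g. per-gene, or descriptive, e.g. per-cell), the features on
the axes, how descriptive values aggregate up to grouping objects, a
conjunction of filters that may target either level, axis transforms, and
an optional rectangular area selection (gating).  Queries evaluate to a
:class:`PointSet` — sorted, plot-ready records carrying entity IDs so a
grouping-level selection can be drilled down into its member cells.

Evaluation order: descriptive-level filters are applied to the raw
objects first, aggregation (grouping level only) second, grouping-level
filters third, axis transforms fourth, and the area selection last, in
displayed (post-transform) coordinates.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import MissingNodeError, QueryError, SchemaError, TransformError
from .model import IdTuple, Node, PropertyGraph, Role

__all__ = [
    "FilterClause",
    "QueryState",
    "PointRecord",
    "PointSet",
    "AGGREGATIONS",
    "aggregate_feature",
    "run_query",
    "drill_down",
    "list_catalog",
    "random_query_state",
    "canonical_dumps",
]

LEVELS = ("grouping", "descriptive")
AGGREGATIONS = ("mean", "median", "count", "min", "max")
TRANSFORMS = ("linear", "log10")
PREDICATES = ("label-presence", "label-absence", "numeric-range")


def canonical_dumps(obj) -> str:
    """Canonical JSON: UTF-8, sorted keys, no whitespace, shortest
    round-trip float representation (Python repr semantics)."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"),
                      ensure_ascii=False, allow_nan=False)


# --------------------------------------------------------------------------
# query state


@dataclass(frozen=True)
class FilterClause:
    """One conjunct: a label presence/absence test or a closed numeric
    range on a property, evaluated on nodes of ``target_kind``."""

    target_kind: str
    predicate: str            # one of PREDICATES
    name: str                 # label or property name
    low: float | None = None  # numeric-range only
    high: float | None = None

    def __post_init__(self) -> None:
        if self.predicate not in PREDICATES:
            raise QueryError(f"unknown predicate {self.predicate!r}")
        if self.predicate == "numeric-range":
            if self.low is None or self.high is None:
                raise QueryError("numeric-range requires low and high")

    def matches(self, node: Node) -> bool:
        if self.predicate == "label-presence":
            return self.name in node.labels
        if self.predicate == "label-absence":
            return self.name not in node.labels
        value = node.properties.get(self.name)
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            return False  # missing values never satisfy a range
        return self.low <= value <= self.high

    def to_json_obj(self) -> dict:
        obj = {"target_kind": self.target_kind, "predicate": self.predicate,
               "name": self.name}
        if self.predicate == "numeric-range":
            obj["low"] = self.low
            obj["high"] = self.high
        return obj

    @classmethod
    def from_json_obj(cls, obj: dict) -> "FilterClause":
        try:
            return cls(target_kind=obj["target_kind"],
                       predicate=obj["predicate"], name=obj["name"],
                       low=obj.get("low"), high=obj.get("high"))
        except KeyError as exc:
            raise QueryError(f"filter clause missing field {exc}") from None


@dataclass(frozen=True)
class Selection:
    """Closed axis-aligned rectangle in displayed coordinates."""
    x_min: float
    x_max: float
    y_min: float | None = None
    y_max: float | None = None

    def contains(self, x: float, y: float | None) -> bool:
        if not (self.x_min <= x <= self.x_max):
            return False
        if y is None or self.y_min is None or self.y_max is None:
            return True
        return self.y_min <= y <= self.y_max

    def to_json_obj(self) -> dict:
        return {"x_min": self.x_min, "x_max": self.x_max,
                "y_min": self.y_min, "y_max": self.y_max}


@dataclass(frozen=True)
class QueryState:
    """Complete, serializable description of one plot/query."""

    level: str
    x_feature: str
    y_feature: str | None = None          # None -> distribution query
    aggregation: str = "mean"             # grouping level only
    filters: tuple[FilterClause, ...] = ()
    x_transform: str = "linear"
    y_transform: str = "linear"
    selection: Selection | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise QueryError(f"unknown level {self.level!r}")
        if self.aggregation not in AGGREGATIONS:
            raise QueryError(f"unknown aggregation {self.aggregation!r}")
        for t in (self.x_transform, self.y_transform):
            if t not in TRANSFORMS:
                raise QueryError(f"unknown transform {t!r}")
        object.__setattr__(self, "filters", tuple(self.filters))

    def to_json_obj(self) -> dict:
        return {
            "level": self.level,
            "x_feature": self.x_feature,
            "y_feature": self.y_feature,
            "aggregation": self.aggregation,
            "filters": [f.to_json_obj() for f in self.filters],
            "x_transform": self.x_transform,
            "y_transform": self.y_transform,
            "selection": (self.selection.to_json_obj()
                          if self.selection else None),
        }

    def to_json(self) -> str:
        return canonical_dumps(self.to_json_obj())

    @classmethod
    def from_json_obj(cls, obj: dict) -> "QueryState":
        if not isinstance(obj, dict):
            raise QueryError("query state must be a JSON object")
        try:
            level = obj["level"]
            x_feature = obj["x_feature"]
        except KeyError as exc:
            raise QueryError(f"query state missing field {exc}") from None
        sel = obj.get("selection")
        selection = None
        if sel is not None:
            try:
                selection = Selection(x_min=sel["x_min"], x_max=sel["x_max"],
                                      y_min=sel.get("y_min"),
                                      y_max=sel.get("y_max"))
            except (KeyError, TypeError):
                raise QueryError("malformed selection") from None
        return cls(
            level=level,
            x_feature=x_feature,
            y_feature=obj.get("y_feature"),
            aggregation=obj.get("aggregation", "mean"),
            filters=tuple(FilterClause.from_json_obj(f)
                          for f in obj.get("filters", [])),
            x_transform=obj.get("x_transform", "linear"),
            y_transform=obj.get("y_transform", "linear"),
            selection=selection,
        )

    @classmethod
    def from_json(cls, text: str) -> "QueryState":
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise QueryError(f"invalid query JSON: {exc}") from exc
        return cls.from_json_obj(obj)


# --------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class PointRecord:
    entity_ids: IdTuple
    x: float
    y: float | None = None
    group_ids: IdTuple | None = None

    def to_json_obj(self) -> dict:
        obj = {"entity": [list(p) for p in self.entity_ids], "x": self.x,
               "y": self.y}
        if self.group_ids is not None:
            obj["group"] = [list(p) for p in self.group_ids]
        return obj


@dataclass
class PointSet:
    level: str
    x_feature: str
    y_feature: str | None
    records: list[PointRecord] = field(default_factory=list)
    dropped: int = 0          # records excluded for missing axis values
    provenance: QueryState | None = None

    def __len__(self) -> int:
        return len(self.records)

    def xs(self) -> np.ndarray:
        return np.array([r.x for r in self.records], dtype=float)

    def ys(self) -> np.ndarray:
        return np.array([r.y for r in self.records], dtype=float)

    def to_json_obj(self) -> dict:
        return {
            "level": self.level,
            "x_feature": self.x_feature,
            "y_feature": self.y_feature,
            "records": [r.to_json_obj() for r in self.records],
            "dropped": self.dropped,
            "provenance": (self.provenance.to_json_obj()
                           if self.provenance else None),
        }

    def to_json(self) -> str:
        return canonical_dumps(self.to_json_obj())


# --------------------------------------------------------------------------
# evaluation helpers


_AGG_FUNCS = {
    "mean": lambda v: float(np.mean(v)),
    "median": lambda v: float(np.median(v)),  # even n: mean of middle two
    "count": lambda v: float(len(v)),
    "min": lambda v: float(np.min(v)),
    "max": lambda v: float(np.max(v)),
}


def _validate_state(graph: PropertyGraph, state: QueryState) -> None:
    desc = graph.descriptive_kind.name
    features = set(graph.feature_catalog(desc))
    for axis, feat in (("x", state.x_feature), ("y", state.y_feature)):
        if axis == "y" and feat is None:
            continue
        if feat not in features:
            raise QueryError(f"unknown feature {feat!r} for {axis} axis "
                             f"(kind {desc})")
    grp = graph.grouping_kind.name
    for clause in state.filters:
        if clause.target_kind not in (grp, desc):
            raise QueryError(
                f"filters may target {grp!r} or {desc!r}, "
                f"not {clause.target_kind!r}")
        catalog = (graph.label_catalog(clause.target_kind)
                   if clause.predicate.startswith("label-")
                   else graph.feature_catalog(clause.target_kind))
        if clause.name not in catalog:
            what = ("label" if clause.predicate.startswith("label-")
                    else "feature")
            raise QueryError(
                f"unknown {what} {clause.name!r} for kind "
                f"{clause.target_kind!r}")


def _transform(values: Sequence[float], how: str, axis: str,
               entities: Sequence[IdTuple]) -> list[float]:
    if how == "linear":
        return list(values)
    bad = [e for e, v in zip(entities, values) if v <= 0]
    if bad:
        raise TransformError(
            f"log10 {axis}-axis undefined for {len(bad)} non-positive "
            f"value(s)", entities=bad)
    return [math.log10(v) for v in values]


def _filter_nodes(graph: PropertyGraph, nodes: Iterable[Node],
                  clauses: Sequence[FilterClause],
                  group_of: dict[int, int] | None) -> list[Node]:
    """Conjunction of clauses; grouping-kind clauses on descriptive nodes
    are evaluated on the owning grouping node."""
    grp = graph.grouping_kind.name
    out = []
    for node in nodes:
        ok = True
        for clause in clauses:
            if clause.target_kind == node.kind:
                target = node
            elif clause.target_kind == grp and group_of is not None:
                target = graph.node(group_of[node.node_id])
            else:
                ok = False
                break
            if not clause.matches(target):
                ok = False
                break
        if ok:
            out.append(node)
    return out


# --------------------------------------------------------------------------
# operations


def aggregate_feature(graph: PropertyGraph, feature: str,
                      method: str = "mean") -> dict[tuple[str, ...], float]:
    """Aggregate a descriptive feature up to grouping objects.

    Returns one value per grouping node having at least one member with a
    non-missing value; keys are the grouping nodes' ordered ID values.
    """
    desc = graph.descriptive_kind.name
    if feature not in graph.feature_catalog(desc):
        raise QueryError(f"unknown feature {feature!r} for kind {desc}")
    if method not in _AGG_FUNCS:
        raise QueryError(f"unknown aggregation {method!r}")
    agg = _AGG_FUNCS[method]
    result: dict[tuple[str, ...], float] = {}
    for group_id, members in graph.membership_map().items():
        values = [graph.node(m).properties[feature] for m in members
                  if feature in graph.node(m).properties]
        if values:
            result[graph.node(group_id).id_key] = agg(values)
    return result


def run_query(graph: PropertyGraph, state: QueryState) -> PointSet:
    """Evaluate a QueryState into a sorted, plot-ready PointSet."""
    _validate_state(graph, state)
    desc = graph.descriptive_kind.name
    grp = graph.grouping_kind.name
    membership = graph.membership_map()
    group_of = {m: g for g, ms in membership.items() for m in ms}

    desc_clauses = [c for c in state.filters if c.target_kind == desc]
    grp_clauses = [c for c in state.filters if c.target_kind == grp]
    if desc == grp:  # self-descriptive single layer
        desc_clauses, grp_clauses = list(state.filters), []

    want_y = state.y_feature is not None
    raw: list[tuple[IdTuple, float, float | None, IdTuple | None]] = []
    dropped = 0

    if state.level == "descriptive":
        nodes = _filter_nodes(graph, graph.nodes_of_kind(desc),
                              desc_clauses + grp_clauses, group_of)
        for node in nodes:
            x = node.properties.get(state.x_feature)
            y = node.properties.get(state.y_feature) if want_y else None
            if x is None or (want_y and y is None):
                dropped += 1
                continue
            gids = graph.node(group_of[node.node_id]).id_values \
                if node.node_id in group_of else node.id_values
            raw.append((node.id_values, x, y, gids))
    else:
        cells = _filter_nodes(graph, graph.nodes_of_kind(desc),
                              desc_clauses, group_of)
        per_group: dict[int, list[Node]] = {}
        for node in cells:
            per_group.setdefault(group_of[node.node_id], []).append(node)
        agg = _AGG_FUNCS[state.aggregation]
        candidates = []
        for group_id, members in per_group.items():
            xs = [m.properties[state.x_feature] for m in members
                  if state.x_feature in m.properties]
            if not xs:
                dropped += 1
                continue
            yv = None
            if want_y:
                ys = [m.properties[state.y_feature] for m in members
                      if state.y_feature in m.properties]
                if not ys:
                    dropped += 1
                    continue
                yv = agg(ys)
            candidates.append((graph.node(group_id), agg(xs), yv))
        kept = _filter_nodes(graph, [c[0] for c in candidates],
                             grp_clauses, None)
        kept_ids = {n.node_id for n in kept}
        for node, xv, yv in candidates:
            if node.node_id in kept_ids:
                raw.append((node.id_values, xv, yv, None))

    entities = [r[0] for r in raw]
    xs = _transform([r[1] for r in raw], state.x_transform, "x", entities)
    if want_y:
        ys = _transform([r[2] for r in raw], state.y_transform, "y", entities)
    else:
        ys = [None] * len(raw)

    records = []
    for (eid, _, _, gids), x, y in zip(raw, xs, ys):
        if state.selection is not None and not state.selection.contains(x, y):
            continue
        records.append(PointRecord(entity_ids=eid, x=x, y=y, group_ids=gids))
    records.sort(key=lambda r: r.entity_ids)
    return PointSet(level=state.level, x_feature=state.x_feature,
                    y_feature=state.y_feature, records=records,
                    dropped=dropped, provenance=state)


def drill_down(graph: PropertyGraph, grouping_ids: Sequence,
               feature_x: str, feature_y: str | None = None) -> PointSet:
    """Expand grouping-level selections into their member descriptive
    records, each tagged with its grouping IDs for downstream colouring.

    ``grouping_ids`` is a sequence of ID-value tuples (a bare string is
    accepted for single-ID-column graphs).  An empty sequence yields an
    empty PointSet.
    """
    desc = graph.descriptive_kind.name
    grp = graph.grouping_kind.name
    features = set(graph.feature_catalog(desc))
    for feat in (feature_x, feature_y):
        if feat is not None and feat not in features:
            raise QueryError(f"unknown feature {feat!r} for kind {desc}")
    want_y = feature_y is not None
    membership = graph.membership_map()
    records: list[PointRecord] = []
    dropped = 0
    for gid in grouping_ids:
        key = (gid,) if isinstance(gid, str) else tuple(gid)
        try:
            gnode = graph.get_node(grp, key)
        except MissingNodeError:
            raise QueryError(f"unknown {grp} IDs {key}") from None
        for member in membership.get(gnode.node_id, []):
            node = graph.node(member)
            x = node.properties.get(feature_x)
            y = node.properties.get(feature_y) if want_y else None
            if x is None or (want_y and y is None):
                dropped += 1
                continue
            records.append(PointRecord(entity_ids=node.id_values, x=x, y=y,
                                       group_ids=gnode.id_values))
    records.sort(key=lambda r: r.entity_ids)
    return PointSet(level="descriptive", x_feature=feature_x,
                    y_feature=feature_y, records=records, dropped=dropped)


def list_catalog(graph: PropertyGraph, kind: str) -> tuple[list[str],
                                                           list[str]]:
    """Sorted (features, labels) available on a kind — what a query form
    offers."""
    try:
        return graph.feature_catalog(kind), graph.label_catalog(kind)
    except SchemaError as exc:
        raise QueryError(str(exc)) from exc


# --------------------------------------------------------------------------
# fuzzing support


def random_query_state(graph: PropertyGraph, rng: random.Random,
                       max_filters: int = 3) -> QueryState:
    """Draw a random valid QueryState against a graph's catalogs.

    Used for fuzz/equivalence testing; draws level, axes, aggregation,
    up to ``max_filters`` random filters, transforms (log10 only where it
    cannot fail on typical positive features is NOT guaranteed — callers
    should be prepared for TransformError) and an occasional selection.
    """
    desc = graph.descriptive_kind.name
    grp = graph.grouping_kind.name
    features = graph.feature_catalog(desc)
    if not features:
        raise QueryError("graph has no queryable features")
    level = rng.choice(LEVELS)
    x = rng.choice(features)
    y = rng.choice([None] + features)
    filters: list[FilterClause] = []
    for _ in range(rng.randrange(max_filters + 1)):
        target = rng.choice([grp, desc])
        labels = graph.label_catalog(target)
        feats = graph.feature_catalog(target)
        options = []
        if labels:
            options += ["label-presence", "label-absence"]
        if feats:
            options.append("numeric-range")
        if not options:
            continue
        predicate = rng.choice(options)
        if predicate == "numeric-range":
            name = rng.choice(feats)
            values = [n.properties[name] for n in graph.nodes_of_kind(target)
                      if name in n.properties]
            lo, hi = (min(values), max(values)) if values else (0.0, 1.0)
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            filters.append(FilterClause(target, predicate, name,
                                        low=min(a, b), high=max(a, b)))
        else:
            filters.append(FilterClause(target, predicate,
                                        rng.choice(labels)))
    def axis_transform(feature: str) -> str:
        # offer log10 only when every observed value is positive, so random
        # states evaluate rather than raise
        if rng.random() < 0.3:
            values = [n.properties[feature]
                      for n in graph.nodes_of_kind(desc)
                      if feature in n.properties]
            if values and min(values) > 0:
                return "log10"
        return "linear"

    x_transform = axis_transform(x)
    y_transform = axis_transform(y) if y else "linear"

    def axis_bounds(feature: str, transform: str) -> tuple[float, float]:
        values = [n.properties[feature] for n in graph.nodes_of_kind(desc)
                  if feature in n.properties]
        if not values:
            return 0.0, 1.0
        lo, hi = min(values), max(values)
        if transform == "log10" and lo > 0:
            lo, hi = math.log10(lo), math.log10(hi)
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        return min(a, b), max(a, b)

    selection = None
    if rng.random() < 0.3:
        a, b = axis_bounds(x, x_transform)
        if y:
            c, d = axis_bounds(y, y_transform)
        else:
            c = d = None
        selection = Selection(x_min=a, x_max=b, y_min=c, y_max=d)
    return QueryState(level=level, x_feature=x, y_feature=y,
                      aggregation=rng.choice(AGGREGATIONS),
                      filters=tuple(filters),
                      x_transform=x_transform, y_transform=y_transform,
                      selection=selection)
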