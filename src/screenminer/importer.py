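"""Screen CSV and label CSV import.

The screen file dialect is RFC 4180 CSV (UTF-8) with three header rows:

1. column headers — the property names;
2. object names — which object of interest each column belongs to;
3. property types — one of ``TEXT``, ``NUMBER``, ``ID``, ``URL``
   (matched case-insensitively).

Every row after the third is one descriptive-object instance; the other
objects referenced in the row (the grouping object, images, wells, ...)
are merged into single nodes keyed by their ID columns, and the
descriptive node is linked to each of them.

The label file has one header row (ID column names, then label names);
its first *n* columns identify a grouping object and the remaining cells
are binary annotations (1 = the object possesses the label).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import (
    FormatError,
    LabelValueError,
    ScreenImportError,
    UnknownGroupWarning,
)
from .model import ObjectKind, PropertyGraph, PropertyType, Role

__all__ = [
    "SchemaColumn",
    "SchemaDescriptor",
    "LabelFileDescriptor",
    "LabelImportReport",
    "ValidationIssue",
    "ValidationReport",
    "parse_schema",
    "import_screen",
    "import_screen_file",
    "import_labels",
    "import_label_file",
    "validate_screen_file",
]

# relations the importer creates
BELONGS_TO = "BELONGS_TO"
LINKED_TO = "LINKED_TO"


@dataclass(frozen=True)
class SchemaColumn:
    header: str
    object_name: str
    ptype: PropertyType
    column_index: int  # 0-based


@dataclass
class SchemaDescriptor:
    columns: list[SchemaColumn]
    grouping_object: str
    descriptive_object: str

    @property
    def object_names(self) -> list[str]:
        """Distinct object names in first-column-appearance order."""
        seen: list[str] = []
        for col in self.columns:
            if col.object_name not in seen:
                seen.append(col.object_name)
        return seen

    def columns_of(self, object_name: str) -> list[SchemaColumn]:
        return [c for c in self.columns if c.object_name == object_name]

    def id_columns_of(self, object_name: str) -> list[SchemaColumn]:
        return [c for c in self.columns_of(object_name)
                if c.ptype is PropertyType.ID]


@dataclass
class LabelFileDescriptor:
    n_id_columns: int
    label_names: list[str]

    def __post_init__(self) -> None:
        if self.n_id_columns < 1:
            raise FormatError("label file needs at least one ID column")
        if not self.label_names:
            raise FormatError("label file defines no labels")
        if len(set(self.label_names)) != len(self.label_names):
            raise FormatError("duplicate label names in label file header")


@dataclass
class LabelImportReport:
    annotated: int                      # grouping nodes that gained >=1 label
    rows_applied: int
    warnings: list[UnknownGroupWarning] = field(default_factory=list)


@dataclass(frozen=True)
class ValidationIssue:
    row: int        # 1-based file line
    column: int | None  # 1-based, None for whole-row issues
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __iter__(self):
        return iter(self.issues)

    def __len__(self) -> int:
        return len(self.issues)


# --------------------------------------------------------------------------
# schema parsing


def _infer_roles(columns: Sequence[SchemaColumn],
                 grouping: str | None,
                 descriptive: str | None) -> tuple[str, str]:
    """Default operator choices: the object owning the first ID column is
    grouping; the object owning the most NUMBER columns is descriptive
    (first appearance breaks ties)."""
    if grouping is None:
        for col in columns:
            if col.ptype is PropertyType.ID:
                grouping = col.object_name
                break
        else:
            raise FormatError("schema has no ID column")
    if descriptive is None:
        counts: dict[str, int] = {}
        order: dict[str, int] = {}
        for col in columns:
            order.setdefault(col.object_name, col.column_index)
            if col.ptype is PropertyType.NUMBER:
                counts[col.object_name] = counts.get(col.object_name, 0) + 1
        if counts:
            descriptive = min(counts, key=lambda o: (-counts[o], order[o]))
        else:
            descriptive = grouping
    return grouping, descriptive


def parse_schema(first_three_rows: Sequence[Sequence[str]],
                 grouping_object: str | None = None,
                 descriptive_object: str | None = None) -> SchemaDescriptor:
    """Parse the three header rows into a SchemaDescriptor.

    ``grouping_object`` / ``descriptive_object`` are the operator-supplied
    object names; left unset, they are inferred (see :func:`_infer_roles`).
    """
    if len(first_three_rows) != 3:
        raise FormatError(
            f"expected 3 header rows (headers, object names, property "
            f"types), got {len(first_three_rows)}")
    headers, objects, types = first_three_rows
    if not (len(headers) == len(objects) == len(types)):
        raise FormatError(
            f"header rows disagree on column count: "
            f"{len(headers)}/{len(objects)}/{len(types)}")
    if not headers:
        raise FormatError("schema has no columns")
    columns = []
    for i, (h, o, t) in enumerate(zip(headers, objects, types)):
        h, o = h.strip(), o.strip()
        if not h:
            raise FormatError(f"empty column header at column {i + 1}")
        if not o:
            raise FormatError(f"empty object name at column {i + 1}")
        try:
            ptype = PropertyType.parse(t)
        except Exception:
            raise FormatError(
                f"unknown property type {t.strip()!r} at column {i + 1}"
            ) from None
        columns.append(SchemaColumn(h, o, ptype, i))

    grouping, descriptive = _infer_roles(columns, grouping_object,
                                         descriptive_object)
    names = {c.object_name for c in columns}
    for label, value in (("grouping", grouping), ("descriptive", descriptive)):
        if value not in names:
            raise FormatError(
                f"{label} object {value!r} does not appear in the schema's "
                f"object-name row")
    schema = SchemaDescriptor(columns, grouping, descriptive)
    for obj in schema.object_names:
        if not schema.id_columns_of(obj):
            raise FormatError(
                f"object {obj!r} has no ID column; its rows could not be "
                f"merged into nodes")
    return schema


# --------------------------------------------------------------------------
# screen import


def _parse_number(cell: str, row: int, column: int) -> float | None:
    cell = cell.strip()
    if not cell:
        return None  # missing, never coerced to 0
    try:
        value = float(cell)
    except ValueError:
        raise ScreenImportError(
            f"row {row}, column {column}: cannot parse NUMBER cell "
            f"{cell!r}", row=row, column=column) from None
    if not math.isfinite(value):
        raise ScreenImportError(
            f"row {row}, column {column}: non-finite NUMBER cell "
            f"{cell!r}", row=row, column=column)
    return value


def _row_objects(schema: SchemaDescriptor, row: Sequence[str],
                 file_row: int):
    """Split one data row into per-object (id_values, properties)."""
    for obj in schema.object_names:
        id_values = []
        properties = {}
        for col in schema.columns_of(obj):
            cell = row[col.column_index]
            if col.ptype is PropertyType.ID:
                id_values.append((col.header, cell.strip()))
            elif col.ptype is PropertyType.NUMBER:
                value = _parse_number(cell, file_row, col.column_index + 1)
                if value is not None:
                    properties[col.header] = value
            else:  # TEXT or URL, stored as text
                cell = cell.strip()
                if cell:
                    properties[col.header] = cell
        yield obj, id_values, properties


def import_screen(data_rows: Iterable[Sequence[str]],
                  schema: SchemaDescriptor,
                  first_data_row: int = 4) -> PropertyGraph:
    """Build a property graph from data rows under a parsed schema.

    One descriptive node per data row (descriptive IDs are expected to be
    unique per row; repeats merge).  Grouping and metadata objects merge
    across rows on their ID tuples, and the row's descriptive node is
    linked to each of them.
    """
    graph = PropertyGraph()
    if schema.grouping_object == schema.descriptive_object:
        graph.register_kind(ObjectKind(schema.grouping_object, Role.GROUPING,
                                       self_descriptive=True))
    else:
        graph.register_kind(ObjectKind(schema.grouping_object, Role.GROUPING))
        graph.register_kind(ObjectKind(schema.descriptive_object,
                                       Role.DESCRIPTIVE))
    for obj in schema.object_names:
        if obj not in graph.kinds:
            graph.register_kind(ObjectKind(obj, Role.METADATA))
        for col in schema.columns_of(obj):
            if col.ptype is PropertyType.NUMBER:
                graph.register_feature(obj, col.header)

    n_cols = len(schema.columns)
    for offset, row in enumerate(data_rows):
        file_row = first_data_row + offset
        if len(row) != n_cols:
            raise FormatError(
                f"row {file_row}: expected {n_cols} columns, got {len(row)}")
        descriptive_id = None
        linked: list[int] = []
        for obj, id_values, properties in _row_objects(schema, row, file_row):
            if all(not v for _, v in id_values):
                if obj in (schema.grouping_object, schema.descriptive_object):
                    raise ScreenImportError(
                        f"row {file_row}: empty ID for {obj}", row=file_row)
                continue  # metadata object absent from this row
            node_id = graph.merge_node(obj, id_values, properties)
            if obj == schema.descriptive_object:
                descriptive_id = node_id
            else:
                linked.append(node_id)
        for target in linked:
            relation = (BELONGS_TO
                        if graph.node(target).kind == schema.grouping_object
                        else LINKED_TO)
            if descriptive_id is not None and descriptive_id != target:
                graph.connect(descriptive_id, target, relation)
    return graph


def _reader(source):
    """csv.reader over a path or an open text stream."""
    if hasattr(source, "read"):
        return csv.reader(source), None
    fh = open(source, newline="", encoding="utf-8")
    return csv.reader(fh), fh


def import_screen_file(source,
                       grouping_object: str | None = None,
                       descriptive_object: str | None = None
                       ) -> PropertyGraph:
    """Import a screen CSV from a path or text stream."""
    reader, fh = _reader(source)
    try:
        rows = iter(reader)
        header = []
        for _ in range(3):
            try:
                header.append(next(rows))
            except StopIteration:
                break
        schema = parse_schema(header, grouping_object, descriptive_object)
        return import_screen(rows, schema)
    finally:
        if fh is not None:
            fh.close()


# --------------------------------------------------------------------------
# label import


def _parse_binary(cell, row: int, column: int) -> int:
    text = str(cell).strip()
    if text in ("0", "1"):
        return int(text)
    raise LabelValueError(
        f"row {row}, column {column}: label value {cell!r} is not binary "
        f"(expected 0 or 1)")


def import_labels(label_rows: Iterable[Sequence[str]],
                  descriptor: LabelFileDescriptor,
                  graph: PropertyGraph,
                  first_data_row: int = 2) -> LabelImportReport:
    """Attach binary labels to grouping nodes.

    Rows are matched on the first ``n_id_columns`` cells against the
    grouping nodes' ordered ID values.  Rows for unknown IDs are collected
    as warnings (screens routinely annotate objects absent from an
    imported subset); they never abort the import.
    """
    grouping = graph.grouping_kind.name
    n = descriptor.n_id_columns
    report = LabelImportReport(annotated=0, rows_applied=0)
    newly_labeled: set[int] = set()
    for offset, row in enumerate(label_rows):
        file_row = first_data_row + offset
        expected = n + len(descriptor.label_names)
        if len(row) != expected:
            raise FormatError(
                f"label row {file_row}: expected {expected} columns, "
                f"got {len(row)}")
        id_key = tuple(str(v).strip() for v in row[:n])
        if not graph.has_node(grouping, id_key):
            report.warnings.append(UnknownGroupWarning(
                f"label row {file_row}: no {grouping} node with IDs "
                f"{id_key}"))
            continue
        assignments = {
            name: _parse_binary(row[n + j], file_row, n + j + 1)
            for j, name in enumerate(descriptor.label_names)}
        node = graph.set_labels(grouping, id_key, assignments)
        report.rows_applied += 1
        if any(assignments.values()):
            newly_labeled.add(node.node_id)
    report.annotated = len(newly_labeled)
    return report


def import_label_file(source, graph: PropertyGraph,
                      n_id_columns: int | None = None) -> LabelImportReport:
    """Import a label CSV (one header row) from a path or stream.

    ``n_id_columns`` defaults to the number of ID columns of the graph's
    grouping kind (i.e. the length of its nodes' ID tuples).
    """
    if n_id_columns is None:
        grouping = graph.grouping_kind.name
        node = next(iter(graph.nodes_of_kind(grouping)), None)
        n_id_columns = len(node.id_values) if node is not None else 1
    reader, fh = _reader(source)
    try:
        rows = iter(reader)
        try:
            header = next(rows)
        except StopIteration:
            raise FormatError("label file is empty") from None
        if len(header) <= n_id_columns:
            raise FormatError(
                f"label file header has {len(header)} columns but "
                f"{n_id_columns} ID columns were expected")
        descriptor = LabelFileDescriptor(
            n_id_columns=n_id_columns,
            label_names=[h.strip() for h in header[n_id_columns:]])
        return import_labels(rows, descriptor, graph)
    finally:
        if fh is not None:
            fh.close()


# --------------------------------------------------------------------------
# validation


def validate_screen_file(source,
                         grouping_object: str | None = None,
                         descriptive_object: str | None = None
                         ) -> ValidationReport:
    """Dry-run check of a screen file; the report is empty exactly when
    :func:`import_screen_file` would succeed."""
    report = ValidationReport()
    reader, fh = _reader(source)
    try:
        rows = list(reader)
    except (OSError, csv.Error) as exc:
        raise IOError(f"cannot read screen file: {exc}") from exc
    finally:
        if fh is not None:
            fh.close()

    if len(rows) < 3:
        missing = ["column-header row", "object-name row",
                   "property-type row"][len(rows):]
        for i, name in enumerate(missing):
            report.issues.append(ValidationIssue(
                row=len(rows) + i + 1, column=None,
                code="missing-header-row", message=f"missing {name}"))
        return report

    try:
        schema = parse_schema(rows[:3], grouping_object, descriptive_object)
    except FormatError as exc:
        report.issues.append(ValidationIssue(
            row=3, column=None, code="bad-schema", message=str(exc)))
        return report

    n_cols = len(schema.columns)
    number_cols = [c for c in schema.columns
                   if c.ptype is PropertyType.NUMBER]
    for offset, row in enumerate(rows[3:]):
        file_row = 4 + offset
        if len(row) != n_cols:
            report.issues.append(ValidationIssue(
                row=file_row, column=None, code="ragged-row",
                message=f"expected {n_cols} columns, got {len(row)}"))
            continue
        for col in number_cols:
            try:
                _parse_number(row[col.column_index], file_row,
                              col.column_index + 1)
            except ScreenImportError as exc:
                report.issues.append(ValidationIssue(
                    row=file_row, column=col.column_index + 1,
                    code="bad-number-cell", message=str(exc)))
        for obj in (schema.grouping_object, schema.descriptive_object):
            ids = [row[c.column_index].strip()
                   for c in schema.id_columns_of(obj)]
            if all(not v for v in ids):
                report.issues.append(ValidationIssue(
                    row=file_row, column=None, code="empty-id",
                    message=f"row {file_row}: empty ID for {obj}"))
    return report


def validate_screen_text(text: str, **kwargs) -> ValidationReport:
    return validate_screen_file(io.StringIO(text), **kwargs)
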