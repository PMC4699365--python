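"""Reproducibility surface: CSV raw-data export, SVG plot export and
self-contained shareable query tokens.

Share tokens encode the canonical JSON of a :class:`QueryState` with
deflate compression and URL-safe base64, prefixed with a version tag
(``v1.<payload>``), so a plot — including every filter applied — can be
replayed from nothing but the link.
"""

from __future__ import annotations

import base64
import csv
import io
import json
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass

from .analytics import DensityCurve, HistogramResult
from .errors import ExportError, ShareTokenError
from .model import PropertyGraph
from .query import PointSet, QueryState

__all__ = [
    "ShareToken",
    "export_csv",
    "export_level_csv",
    "export_svg",
    "encode_share",
    "decode_share",
]

TOKEN_VERSION = 1


# --------------------------------------------------------------------------
# CSV export


def _render_number(value) -> str:
    # repr round-trips floats exactly; integers print without .0
    if isinstance(value, float) and value.is_integer():
        return repr(value)
    return repr(value) if isinstance(value, float) else str(value)


def export_csv(points: PointSet) -> str:
    """Raw data values of a query as RFC 4180 CSV text.

    Header: entity ID column names, the axis features, then the grouping
    ID columns when records carry them (descriptive level).
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    first = points.records[0] if points.records else None
    id_names = [n for n, _ in first.entity_ids] if first else ["id"]
    header = list(id_names) + [points.x_feature]
    if points.y_feature is not None:
        header.append(points.y_feature)
    has_groups = first is not None and first.group_ids is not None
    if has_groups:
        header += [n for n, _ in first.group_ids]
    writer.writerow(header)
    for rec in points.records:
        row = [v for _, v in rec.entity_ids] + [_render_number(rec.x)]
        if points.y_feature is not None:
            row.append(_render_number(rec.y))
        if has_groups:
            row += [v for _, v in rec.group_ids]
        writer.writerow(row)
    return buf.getvalue()


def export_level_csv(graph: PropertyGraph, kind: str) -> str:
    """Every node of a kind as CSV: ID columns then all catalog features
    (sorted); missing feature values export as empty cells.

    Numbers render with repr fidelity, so re-importing reproduces the
    parsed values exactly.
    """
    nodes = sorted(graph.nodes_of_kind(kind), key=lambda n: n.id_key)
    features = graph.feature_catalog(kind)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    id_names = [n for n, _ in nodes[0].id_values] if nodes else ["id"]
    writer.writerow(list(id_names) + features)
    for node in nodes:
        row = [v for _, v in node.id_values]
        for feat in features:
            value = node.properties.get(feat)
            row.append("" if value is None else _render_number(value))
        writer.writerow(row)
    return buf.getvalue()


# --------------------------------------------------------------------------
# SVG export

_WIDTH, _HEIGHT = 640, 480
_MARGIN = 60


def _svg_root() -> ET.Element:
    return ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "width": str(_WIDTH), "height": str(_HEIGHT),
        "viewBox": f"0 0 {_WIDTH} {_HEIGHT}",
    })


def _scale(lo: float, hi: float, pixel_lo: float, pixel_hi: float):
    span = hi - lo
    if span == 0:
        lo, hi, span = lo - 0.5, hi + 0.5, 1.0
    return lambda v: pixel_lo + (v - lo) / span * (pixel_hi - pixel_lo)


def _axes(root: ET.Element, x_label: str, y_label: str | None) -> None:
    plot_bottom = _HEIGHT - _MARGIN
    ET.SubElement(root, "line", {
        "class": "axis", "x1": str(_MARGIN), "y1": str(plot_bottom),
        "x2": str(_WIDTH - _MARGIN), "y2": str(plot_bottom),
        "stroke": "black"})
    ET.SubElement(root, "line", {
        "class": "axis", "x1": str(_MARGIN), "y1": str(_MARGIN),
        "x2": str(_MARGIN), "y2": str(plot_bottom), "stroke": "black"})
    xl = ET.SubElement(root, "text", {
        "class": "axis-label", "x": str(_WIDTH / 2),
        "y": str(_HEIGHT - _MARGIN / 4), "text-anchor": "middle"})
    xl.text = x_label
    if y_label:
        yl = ET.SubElement(root, "text", {
            "class": "axis-label", "x": str(_MARGIN / 4),
            "y": str(_HEIGHT / 2), "text-anchor": "middle",
            "transform": f"rotate(-90 {_MARGIN / 4} {_HEIGHT / 2})"})
        yl.text = y_label


def _svg_scatter(points: PointSet) -> ET.Element:
    root = _svg_root()
    xs, ys = points.xs(), points.ys()
    y_label = points.y_feature
    if points.y_feature is None:
        ys = [0.0] * len(points)
        y_label = ""
    sx = _scale(min(xs), max(xs), _MARGIN, _WIDTH - _MARGIN)
    sy = _scale(min(ys), max(ys), _HEIGHT - _MARGIN, _MARGIN)
    _axes(root, points.x_feature, y_label)
    for rec, x, y in zip(points.records, xs, ys):
        ET.SubElement(root, "circle", {
            "class": "point", "r": "3",
            "cx": f"{sx(x):.2f}", "cy": f"{sy(y):.2f}",
            "data-entity": "/".join(v for _, v in rec.entity_ids)})
    return root


def _svg_histogram(hist: HistogramResult,
                   options: dict | None = None) -> ET.Element:
    options = options or {}
    root = _svg_root()
    edges = hist.bin_edges
    max_count = max(max(c) for c in hist.counts.values()) or 1
    sx = _scale(edges[0], edges[-1], _MARGIN, _WIDTH - _MARGIN)
    sy = _scale(0, max_count, _HEIGHT - _MARGIN, _MARGIN)
    _axes(root, options.get("x_label", "value"), "count")
    n_series = len(hist.series_names)
    for s_idx, name in enumerate(hist.series_names):
        for i, count in enumerate(hist.counts[name]):
            # side-by-side sub-bars for multihistograms
            left, right = sx(edges[i]), sx(edges[i + 1])
            width = (right - left) / n_series
            ET.SubElement(root, "rect", {
                "class": "bar", "data-series": name,
                "x": f"{left + s_idx * width:.2f}",
                "y": f"{sy(count):.2f}",
                "width": f"{max(width, 0.1):.2f}",
                "height": f"{(_HEIGHT - _MARGIN) - sy(count):.2f}"})
    return root


def _svg_density(curve: DensityCurve,
                 options: dict | None = None) -> ET.Element:
    options = options or {}
    root = _svg_root()
    sx = _scale(curve.grid[0], curve.grid[-1], _MARGIN, _WIDTH - _MARGIN)
    sy = _scale(0, max(curve.density) or 1, _HEIGHT - _MARGIN, _MARGIN)
    _axes(root, options.get("x_label", "value"), "density")
    d = " ".join(
        f"{'M' if i == 0 else 'L'} {sx(g):.2f} {sy(v):.2f}"
        for i, (g, v) in enumerate(zip(curve.grid, curve.density)))
    ET.SubElement(root, "path", {"class": "density", "d": d,
                                 "fill": "none", "stroke": "black"})
    return root


def export_svg(result, options: dict | None = None) -> str:
    """Render a PointSet scatter, a histogram or a density curve as a
    standalone SVG 1.1 document.

    Data elements are queryable by class: ``point`` (circles), ``bar``
    (rects), ``density`` (path); axes carry the feature names.
    """
    if isinstance(result, PointSet):
        if not result.records:
            raise ExportError("cannot render an empty point set")
        root = _svg_scatter(result)
    elif isinstance(result, HistogramResult):
        if not result.series_names:
            raise ExportError("cannot render an empty histogram")
        root = _svg_histogram(result, options)
    elif isinstance(result, DensityCurve):
        if not result.grid:
            raise ExportError("cannot render an empty density curve")
        root = _svg_density(result, options)
    else:
        raise ExportError(
            f"cannot render object of type {type(result).__name__}")
    return ('<?xml version="1.0" encoding="UTF-8"?>\n'
            + ET.tostring(root, encoding="unicode"))


# --------------------------------------------------------------------------
# share tokens


@dataclass(frozen=True)
class ShareToken:
    payload: str   # URL-safe base64 of deflated canonical QueryState JSON
    version: int = TOKEN_VERSION

    def __str__(self) -> str:
        return f"v{self.version}.{self.payload}"

    @classmethod
    def from_string(cls, text: str) -> "ShareToken":
        version, sep, payload = text.partition(".")
        if not sep or not version.startswith("v") or not payload:
            raise ShareTokenError(f"malformed share token {text!r}")
        try:
            number = int(version[1:])
        except ValueError:
            raise ShareTokenError(
                f"malformed token version {version!r}") from None
        return cls(payload=payload, version=number)


def encode_share(state: QueryState) -> ShareToken:
    """Serialize a query state into a URL-safe, self-contained token."""
    raw = state.to_json().encode("utf-8")
    compressed = zlib.compress(raw, level=9)
    payload = base64.urlsafe_b64encode(compressed).decode("ascii")
    payload = payload.rstrip("=")  # padding would need percent-encoding
    return ShareToken(payload=payload)


def decode_share(token: ShareToken | str) -> QueryState:
    """Recover the query state; tampered or future-version tokens fail
    loudly with ShareTokenError."""
    if isinstance(token, str):
        token = ShareToken.from_string(token)
    if token.version != TOKEN_VERSION:
        raise ShareTokenError(
            f"unsupported share-token version v{token.version} "
            f"(this build reads v{TOKEN_VERSION})")
    padded = token.payload + "=" * (-len(token.payload) % 4)
    try:
        compressed = base64.urlsafe_b64decode(padded.encode("ascii"))
        raw = zlib.decompress(compressed)
        obj = json.loads(raw.decode("utf-8"))
    except Exception as exc:
        raise ShareTokenError(f"cannot decode share token: {exc}") from exc
    try:
        return QueryState.from_json_obj(obj)
    except Exception as exc:
        raise ShareTokenError(
            f"token decodes to an invalid query state: {exc}") from exc
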