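"""Read-only JSON-over-HTTP query API.

The service exposes the library's query and analytics operations so any
language that speaks HTTP and JSON can drive an instance; every response
is an envelope ``{"status": "ok", "payload": ...}`` or
``{"status": "error", "message": ...}`` in canonical JSON.

Routes
------
* ``GET  /health`` — liveness and instance summary
* ``GET  /catalog/{kind}`` — features and labels available on a kind
* ``POST /query`` — body: QueryState JSON; payload: PointSet
* ``POST /histogram`` — body: ``{"query": <state>, "axis": "x"|"y",
  "bins": int?}``; payload: HistogramResult
* ``POST /kde`` — body: ``{"query": <state>, "axis": ..., "bandwidth":
  number?}``; payload: DensityCurve
* ``POST /regression`` — body: ``{"query": <state>}``; payload:
  RegressionFit
* ``POST /compare`` — body: ``{"a": <state>, "b": <state>}``; payload:
  ComparisonResult
* ``GET  /share/{token}`` — replay a share token; payload: PointSet

The route layout is this package's own reconstruction of a programmatic
screen-query API; no endpoint mutates the instance.
"""

from __future__ import annotations

import json
import threading
from wsgiref.simple_server import (
    WSGIRequestHandler,
    WSGIServer,
    make_server,
)

from . import analytics
from .errors import (
    AnalyticsError,
    QueryError,
    ScreenMinerError,
    ShareTokenError,
    TransformError,
)
from .export_share import decode_share
from .model import PropertyGraph
from .query import QueryState, canonical_dumps, run_query

__all__ = ["make_app", "serve", "start_background", "ServiceHandle"]


def _ok(payload) -> tuple[str, str]:
    return "200 OK", canonical_dumps({"status": "ok", "payload": payload})


def _error(status: str, message: str) -> tuple[str, str]:
    return status, canonical_dumps({"status": "error", "message": message})


def _read_json_body(environ) -> dict:
    try:
        length = int(environ.get("CONTENT_LENGTH") or 0)
    except ValueError:
        length = 0
    body = environ["wsgi.input"].read(length) if length else b""
    if not body:
        raise ValueError("empty request body")
    return json.loads(body.decode("utf-8"))


def _axis_values(points, axis: str):
    if axis not in ("x", "y"):
        raise QueryError(f"axis must be 'x' or 'y', not {axis!r}")
    if axis == "y":
        if points.y_feature is None:
            raise QueryError("query has no y axis")
        return points.ys(), points.y_feature
    return points.xs(), points.x_feature


def make_app(graph: PropertyGraph):
    """Build the WSGI application for a loaded instance (read-only)."""

    def handle(method: str, path: str, environ) -> tuple[str, str]:
        parts = [p for p in path.split("/") if p]
        if method == "GET" and parts == ["health"]:
            return _ok({"instance": {
                "kinds": sorted(graph.kinds),
                "nodes": graph.node_count(),
                "edges": graph.edge_count()}})
        if method == "GET" and len(parts) == 2 and parts[0] == "catalog":
            features, labels = graph.feature_catalog(parts[1]), None
            labels = graph.label_catalog(parts[1])
            return _ok({"kind": parts[1], "features": features,
                        "labels": labels})
        if method == "GET" and len(parts) == 2 and parts[0] == "share":
            state = decode_share(parts[1])
            return _ok(run_query(graph, state).to_json_obj())
        if method == "POST" and parts == ["query"]:
            state = QueryState.from_json_obj(_read_json_body(environ))
            return _ok(run_query(graph, state).to_json_obj())
        if method == "POST" and parts == ["histogram"]:
            body = _read_json_body(environ)
            state = QueryState.from_json_obj(body.get("query"))
            values, _ = _axis_values(run_query(graph, state),
                                     body.get("axis", "x"))
            hist = analytics.histogram(values, body.get("bins"))
            return _ok(hist.to_json_obj())
        if method == "POST" and parts == ["kde"]:
            body = _read_json_body(environ)
            state = QueryState.from_json_obj(body.get("query"))
            values, _ = _axis_values(run_query(graph, state),
                                     body.get("axis", "x"))
            curve = analytics.kde(values, body.get("bandwidth"))
            return _ok(curve.to_json_obj())
        if method == "POST" and parts == ["regression"]:
            body = _read_json_body(environ)
            state = QueryState.from_json_obj(body.get("query"))
            fit = analytics.fit_regression(run_query(graph, state))
            return _ok(fit.to_json_obj())
        if method == "POST" and parts == ["compare"]:
            body = _read_json_body(environ)
            a = run_query(graph, QueryState.from_json_obj(body.get("a")))
            b = run_query(graph, QueryState.from_json_obj(body.get("b")))
            return _ok(analytics.compare_plots(a, b).to_json_obj())
        return _error("404 Not Found", f"no route {method} {path}")

    def app(environ, start_response):
        method = environ.get("REQUEST_METHOD", "GET")
        path = environ.get("PATH_INFO", "/")
        try:
            status, body = handle(method, path, environ)
        except (json.JSONDecodeError, ValueError) as exc:
            status, body = _error("400 Bad Request",
                                  f"malformed request body: {exc}")
        except (QueryError, AnalyticsError, TransformError,
                ShareTokenError) as exc:
            status, body = _error("422 Unprocessable Entity", str(exc))
        except ScreenMinerError as exc:
            status, body = _error("422 Unprocessable Entity", str(exc))
        payload = body.encode("utf-8")
        start_response(status, [
            ("Content-Type", "application/json; charset=utf-8"),
            ("Content-Length", str(len(payload)))])
        return [payload]

    return app


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, format, *args):  # noqa: A002 - wsgiref signature
        pass


class ServiceHandle:
    """A running service: the bound address plus shutdown control."""

    def __init__(self, server: WSGIServer, thread: threading.Thread | None):
        self.server = server
        self.thread = thread

    @property
    def address(self) -> tuple[str, int]:
        return self.server.server_address[:2]

    @property
    def url(self) -> str:
        host, port = self.address
        return f"http://{host}:{port}"

    def shutdown(self) -> None:
        self.server.shutdown()
        if self.thread is not None:
            self.thread.join(timeout=5)
        self.server.server_close()


def _load(instance_path) -> PropertyGraph:
    try:
        return PropertyGraph.load(instance_path)
    except (OSError, ScreenMinerError) as exc:
        raise ScreenMinerError(
            f"cannot load instance {instance_path}: {exc}") from exc


def serve(instance_path, host: str = "127.0.0.1", port: int = 8080) -> None:
    """Load an instance file and serve it until interrupted."""
    graph = _load(instance_path)
    with make_server(host, port, make_app(graph)) as server:
        server.serve_forever()





def start_background(graph: PropertyGraph, host: str = "127.0.0.1",
                     port: int = 0) -> ServiceHandle:
    """Start the service on a daemon thread (port 0 picks a free port);
    used by tests and embedding callers."""
    server = make_server(host, port, make_app(graph),
                         handler_class=_QuietHandler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return ServiceHandle(server, thread)
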