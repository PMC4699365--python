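"""Post-query analytics: histograms, kernel density estimates, regression
lines and plot comparison.

These operate on plain value arrays or :class:`~screenminer.query.PointSet`
results, and return data objects (never rendered images); SVG rendering is
a thin layer in :mod:`screenminer.export_share`.

Conventions (overridable where noted):

* histograms use equal-width bins over ``[min, max]``; the last bin is
  right-closed, the others right-open; the default bin count is Sturges'
  rule ``ceil(log2 n) + 1``;
* the KDE uses a Gaussian kernel with Silverman's rule-of-thumb bandwidth
  ``0.9 * min(sd, IQR/1.34) * n**(-1/5)`` and a 256-point grid spanning
  ``[min - 3h, max + 3h]``;
* regression is ordinary least squares on the coordinates as displayed
  (i.e. after any axis transform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import AnalyticsError
from .query import PointSet, canonical_dumps

__all__ = [
    "HistogramResult",
    "DensityCurve",
    "RegressionFit",
    "ComparisonResult",
    "histogram",
    "multihistogram",
    "kde",
    "silverman_bandwidth",
    "fit_regression",
    "compare_plots",
    "sturges_bins",
]


@dataclass
class HistogramResult:
    bin_edges: list[float]                 # length k+1, strictly increasing
    counts: dict[str, list[int]]           # series name -> length-k counts
    series_names: list[str]

    @property
    def k(self) -> int:
        return len(self.bin_edges) - 1

    def to_json_obj(self) -> dict:
        return {"bin_edges": self.bin_edges,
                "counts": {k: v for k, v in sorted(self.counts.items())},
                "series_names": self.series_names}

    def to_json(self) -> str:
        return canonical_dumps(self.to_json_obj())


@dataclass
class DensityCurve:
    grid: list[float]
    density: list[float]
    bandwidth: float

    def to_json_obj(self) -> dict:
        return {"grid": self.grid, "density": self.density,
                "bandwidth": self.bandwidth}

    def to_json(self) -> str:
        return canonical_dumps(self.to_json_obj())

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    degenerate: bool = False   # SS_tot == 0 (constant y): r^2 declared 0

    def to_json_obj(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "n_points": self.n_points,
                "degenerate": self.degenerate}

    def to_json(self) -> str:
        return canonical_dumps(self.to_json_obj())


@dataclass
class ComparisonResult:
    """Paired layout for two point sets on the same axes: shared (union)
    axis ranges, per-set summaries and their differences (b minus a)."""

    x_feature: str
    y_feature: str | None
    x_range: tuple[float, float]
    y_range: tuple[float, float] | None
    summary_a: dict = field(default_factory=dict)
    summary_b: dict = field(default_factory=dict)
    deltas: dict = field(default_factory=dict)

    def to_json_obj(self) -> dict:
        return {"x_feature": self.x_feature, "y_feature": self.y_feature,
                "x_range": list(self.x_range),
                "y_range": list(self.y_range) if self.y_range else None,
                "summary_a": self.summary_a, "summary_b": self.summary_b,
                "deltas": self.deltas}

    def to_json(self) -> str:
        return canonical_dumps(self.to_json_obj())


# --------------------------------------------------------------------------
# histograms


def sturges_bins(n: int) -> int:
    return max(1, math.ceil(math.log2(n)) + 1) if n > 1 else 1


def _finite(values) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    return arr[np.isfinite(arr)]


def _edges(lo: float, hi: float, k: int) -> np.ndarray:
    if lo == hi:
        # constant data: one unit-width bin centred on the value
        return np.array([lo - 0.5, lo + 0.5])
    return np.linspace(lo, hi, k + 1)


def histogram(values: Sequence[float],
              k_bins: int | None = None) -> HistogramResult:
    """Equal-width histogram; ``k_bins`` defaults to Sturges' rule."""
    arr = _finite(values)
    if arr.size == 0:
        raise AnalyticsError("histogram requires at least one finite value")
    k = k_bins if k_bins is not None else sturges_bins(arr.size)
    if k < 1:
        raise AnalyticsError(f"invalid bin count {k}")
    edges = _edges(float(arr.min()), float(arr.max()), k)
    counts, _ = np.histogram(arr, bins=edges)
    return HistogramResult(bin_edges=[float(e) for e in edges],
                           counts={"values": [int(c) for c in counts]},
                           series_names=["values"])


def multihistogram(series: Sequence[tuple[str, Sequence[float]]],
                   k_bins: int | None = None) -> HistogramResult:
    """Shared-bin histogram of several named series over the pooled range."""
    if not series:
        raise AnalyticsError("multihistogram requires at least one series")
    cleaned = []
    for name, values in series:
        arr = _finite(values)
        if arr.size == 0:
            raise AnalyticsError(
                f"series {name!r} has no finite values")
        cleaned.append((name, arr))
    pooled = np.concatenate([arr for _, arr in cleaned])
    k = k_bins if k_bins is not None else sturges_bins(pooled.size)
    edges = _edges(float(pooled.min()), float(pooled.max()), k)
    counts = {}
    for name, arr in cleaned:
        c, _ = np.histogram(arr, bins=edges)
        counts[name] = [int(v) for v in c]
    return HistogramResult(bin_edges=[float(e) for e in edges],
                           counts=counts,
                           series_names=[n for n, _ in cleaned])


# --------------------------------------------------------------------------
# kernel density estimation


def silverman_bandwidth(values: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    When the IQR is zero (heavily tied data) the spread term falls back to
    the standard deviation alone, so the rule stays positive whenever the
    sample has two distinct values.
    """
    n = values.size
    sd = float(np.std(values, ddof=1))
    q1, q3 = np.percentile(values, [25, 75])
    iqr = float(q3 - q1)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * n ** (-1 / 5)


def kde(values: Sequence[float], bandwidth: float | None = None,
        grid_size: int = 256,
        grid: Sequence[float] | None = None) -> DensityCurve:
    """Gaussian-kernel density estimate on a regular grid.

    Automatic bandwidth (Silverman) requires at least two distinct finite
    values; an explicit ``bandwidth`` permits any non-empty sample.  An
    explicit ``grid`` overrides the default ``grid_size`` points over
    ``[min - 3h, max + 3h]`` (e.g. to evaluate the estimate at the data
    points themselves).
    """
    arr = _finite(values)
    if arr.size == 0:
        raise AnalyticsError("kde requires at least one finite value")
    h = bandwidth
    if h is None:
        if np.unique(arr).size < 2:
            raise AnalyticsError(
                "automatic bandwidth requires >= 2 distinct values")
        h = silverman_bandwidth(arr)
    if not (h > 0) or not math.isfinite(h):
        raise AnalyticsError(f"bandwidth must be positive, got {h!r}")
    if grid is None:
        lo, hi = float(arr.min()) - 3 * h, float(arr.max()) + 3 * h
        grid = np.linspace(lo, hi, grid_size)
    else:
        grid = np.asarray(list(grid), dtype=float)
    z = (grid[:, None] - arr[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (arr.size * h
                                                  * math.sqrt(2 * math.pi))
    return DensityCurve(grid=[float(g) for g in grid],
                        density=[float(d) for d in density],
                        bandwidth=float(h))


# --------------------------------------------------------------------------
# regression


def _xy(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, PointSet):
        if points.y_feature is None:
            raise AnalyticsError("regression requires a y axis")
        return points.xs(), points.ys()
    x, y = points
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def fit_regression(points) -> RegressionFit:
    """Ordinary least squares line through a PointSet (or an ``(x, y)``
    array pair), on the coordinates as displayed."""
    x, y = _xy(points)
    if x.size < 2:
        raise AnalyticsError("regression requires at least 2 points")
    if np.all(x == x[0]):
        raise AnalyticsError("regression undefined for constant x "
                             "(vertical line)")
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    ss_res = float(np.sum(residuals ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return RegressionFit(slope=float(slope), intercept=float(intercept),
                             r_squared=0.0, n_points=int(x.size),
                             degenerate=True)
    r2 = 1.0 - ss_res / ss_tot
    return RegressionFit(slope=float(slope), intercept=float(intercept),
                         r_squared=float(min(max(r2, 0.0), 1.0)),
                         n_points=int(x.size))


# --------------------------------------------------------------------------
# plot comparison


def _axis_summary(values: np.ndarray) -> dict:
    return {"n": int(values.size),
            "mean": float(values.mean()) if values.size else None,
            "min": float(values.min()) if values.size else None,
            "max": float(values.max()) if values.size else None}


def _summarize(points: PointSet) -> dict:
    out = {"n": len(points), "x": _axis_summary(points.xs())}
    if points.y_feature is not None:
        out["y"] = _axis_summary(points.ys())
    return out


def compare_plots(a: PointSet, b: PointSet) -> ComparisonResult:
    """Side-by-side comparison of two queries plotted on the same axes."""
    if a.level != b.level:
        raise AnalyticsError(
            f"cannot compare plots at different levels: "
            f"{a.level} vs {b.level}")
    if a.x_feature != b.x_feature or a.y_feature != b.y_feature:
        raise AnalyticsError(
            f"cannot compare plots with different axes: "
            f"({a.x_feature}, {a.y_feature}) vs "
            f"({b.x_feature}, {b.y_feature})")
    sa, sb = _summarize(a), _summarize(b)

    def union(lo_hi_a, lo_hi_b):
        pairs = [p for p in (lo_hi_a, lo_hi_b) if p[0] is not None]
        if not pairs:
            return (0.0, 0.0)
        return (min(p[0] for p in pairs), max(p[1] for p in pairs))

    x_range = union((sa["x"]["min"], sa["x"]["max"]),
                    (sb["x"]["min"], sb["x"]["max"]))
    y_range = None
    if a.y_feature is not None:
        y_range = union((sa["y"]["min"], sa["y"]["max"]),
                        (sb["y"]["min"], sb["y"]["max"]))

    def delta(field_a, field_b):
        if field_a is None or field_b is None:
            return None
        return field_b - field_a

    deltas = {"n": sb["n"] - sa["n"],
              "x_mean": delta(sa["x"]["mean"], sb["x"]["mean"])}
    if y_range is not None:
        deltas["y_mean"] = delta(sa["y"]["mean"], sb["y"]["mean"])
    return ComparisonResult(x_feature=a.x_feature, y_feature=a.y_feature,
                            x_range=x_range, y_range=y_range,
                            summary_a=sa, summary_b=sb, deltas=deltas)
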