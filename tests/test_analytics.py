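import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from screenminer import (
    FilterClause,
    QueryState,
    compare_plots,
    fit_regression,
    histogram,
    kde,
    multihistogram,
    run_query,
)
from screenminer.analytics import silverman_bandwidth, sturges_bins
from screenminer.errors import AnalyticsError
from screenminer.query import PointRecord, PointSet


def points(xy, x_feature="x", y_feature="y", level="descriptive"):
    return PointSet(
        level=level, x_feature=x_feature, y_feature=y_feature,
        records=[PointRecord(entity_ids=((("id"), str(i)),), x=x, y=y)
                 for i, (x, y) in enumerate(xy)])


class TestHistogram:
    def test_last_bin_right_closed(self):
        h = histogram([0.0, 0.5, 1.0], k_bins=2)
        assert h.bin_edges == [0.0, 0.5, 1.0]
        assert h.counts["values"] == [1, 2]

    def test_constant_input_single_unit_bin(self):
        h = histogram([3.0, 3.0, 3.0], k_bins=1)
        assert h.bin_edges == [2.5, 3.5]
        assert h.counts["values"] == [3]

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(42)
        values = rng.uniform(0, 1, size=1000)
        h = histogram(values, k_bins=10)
        # independent binning: loop placement with right-open bins,
        # last bin right-closed
        edges = h.bin_edges
        expected = [0] * 10
        for v in values:
            for b in range(10):
                right_closed = b == 9
                if edges[b] <= v < edges[b + 1] or \
                        (right_closed and v == edges[10]):
                    expected[b] += 1
                    break
        assert h.counts["values"] == expected

    def test_sturges_default(self):
        h = histogram(list(range(100)))
        assert h.k == sturges_bins(100) == 8

    def test_empty_input_rejected(self):
        with pytest.raises(AnalyticsError):
            histogram([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200),
           st.integers(1, 20))
    def test_counts_conserve_n(self, values, k):
        h = histogram(values, k_bins=k)
        assert sum(h.counts["values"]) == len(values)
        assert all(a < b for a, b in zip(h.bin_edges, h.bin_edges[1:]))


class TestMultihistogram:
    def test_identical_series_identical_counts(self):
        data = [1.0, 2.0, 2.5, 4.0]
        h = multihistogram([("a", data), ("b", list(data))], k_bins=3)
        assert h.counts["a"] == h.counts["b"]

    def test_shared_edges_over_pooled_range(self):
        h = multihistogram([("A", [0.0, 1.0]), ("B", [2.0, 3.0])],
                           k_bins=2)
        assert h.bin_edges == [0.0, 1.5, 3.0]
        assert h.counts["A"] == [2, 0]
        assert h.counts["B"] == [0, 2]
        assert sum(h.counts["A"]) == sum(h.counts["B"]) == 2

    def test_planted_shift_separates_hit_mass(self, screen):
        """Hit vs non-hit distributions of the shifted feature differ in
        the planted direction (compared against the generator's truth)."""
        generated, graph = screen
        truth = generated.truth
        feature = next(iter(truth.effect_sizes))[1]
        hit = QueryState(
            level="grouping", x_feature=feature,
            filters=(FilterClause("Gene", "label-presence", "hit"),))
        non = QueryState(
            level="grouping", x_feature=feature,
            filters=(FilterClause("Gene", "label-absence", "hit"),))
        hx = run_query(graph, hit).xs()
        nx = run_query(graph, non).xs()
        h = multihistogram([("hit", hx), ("non", nx)], k_bins=8)
        centers = (np.array(h.bin_edges[:-1]) +
                   np.array(h.bin_edges[1:])) / 2

        def mass_center(name):
            c = np.array(h.counts[name], dtype=float)
            return float((centers * c).sum() / c.sum())
        planted = next(iter(truth.effect_sizes.values()))
        assert (mass_center("hit") - mass_center("non")) * planted > 0

    def test_empty_series_named_in_error(self):
        with pytest.raises(AnalyticsError, match="b"):
            multihistogram([("a", [1.0]), ("b", [])])


class TestKde:
    def test_single_point_gaussian_peak(self):
        h = 0.7
        curve = kde([5.0], bandwidth=h, grid=[5.0, 5.0 + h])
        peak = curve.density[0]
        assert peak == pytest.approx(1 / (h * math.sqrt(2 * math.pi)),
                                     rel=1e-9)
        # one bandwidth away: exp(-1/2) of the peak
        assert curve.density[1] == pytest.approx(
            peak * math.exp(-0.5), rel=1e-9)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(7)
        curve = kde(rng.standard_normal(500))
        assert 0.99 <= curve.integral() <= 1.01

    def test_close_to_true_normal_density(self):
        rng = np.random.default_rng(12345)
        curve = kde(rng.standard_normal(10_000))
        grid = np.array(curve.grid)
        true_pdf = np.exp(-0.5 * grid ** 2) / math.sqrt(2 * math.pi)
        assert np.max(np.abs(np.array(curve.density) - true_pdf)) < 0.05

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(2.0, 1.5, size=80)
        h = silverman_bandwidth(x)
        c = 17.25
        a = kde(x, bandwidth=h)
        b = kde(x + c, bandwidth=h)
        assert np.allclose(np.array(b.grid) - c, a.grid, atol=1e-9)
        assert np.allclose(b.density, a.density, atol=1e-9)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(9)
        curve = kde(rng.standard_normal(200))
        assert min(curve.density) >= 0

    def test_silverman_iqr_term(self):
        x = np.random.default_rng(1).standard_normal(400)
        sd = np.std(x, ddof=1)
        q1, q3 = np.percentile(x, [25, 75])
        expected = 0.9 * min(sd, (q3 - q1) / 1.34) * 400 ** (-0.2)
        assert silverman_bandwidth(x) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(AnalyticsError):
            kde([])
        with pytest.raises(AnalyticsError):
            kde([1.0, 1.0, 1.0])  # no spread, automatic bandwidth
        with pytest.raises(AnalyticsError):
            kde([1.0, 2.0], bandwidth=0.0)


class TestRegression:
    def test_exact_line_recovered(self):
        ps = points([(x, 2 * x + 1) for x in [0.0, 1.0, 2.0, 3.0]])
        fit = fit_regression(ps)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y_degenerate(self):
        fit = fit_regression(points([(0.0, 5.0), (1.0, 5.0), (2.0, 5.0)]))
        assert fit.slope == pytest.approx(0.0)
        assert fit.degenerate and fit.r_squared == 0.0

    def test_constant_x_rejected(self):
        with pytest.raises(AnalyticsError):
            fit_regression(points([(1.0, 0.0), (1.0, 2.0)]))

    def test_matches_normal_equations_on_noisy_line(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 10, size=200)
        y = 3 * x + rng.normal(0, 0.1, size=200)
        fit = fit_regression((x, y))
        # independent oracle: closed-form normal equations
        sxx = np.sum((x - x.mean()) ** 2)
        slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
        intercept = float(y.mean() - slope * x.mean())
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)
        assert 2.9 <= fit.slope <= 3.1

    def test_r_squared_affine_invariant(self):
        rng = np.random.default_rng(19)
        x = rng.uniform(0, 5, size=60)
        y = 1.5 * x + rng.normal(0, 0.5, size=60)
        base = fit_regression((x, y)).r_squared
        for a, b, c, d in [(2.0, 1.0, 3.0, -4.0), (0.1, -2.0, 10.0, 0.0)]:
            scaled = fit_regression((a * x + b, c * y + d)).r_squared
            assert scaled == pytest.approx(base, rel=1e-9)

    def test_slope_recovery_across_seeds(self):
        """Slope and intercept land within 3 standard errors of truth in
        >=95% of simulated linear datasets."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 10, size=100)
            y = 3 * x + rng.normal(0, 0.5, size=100)
            fit = fit_regression((x, y))
            resid = y - (fit.slope * x + fit.intercept)
            se = math.sqrt(resid @ resid / (len(x) - 2)
                           / np.sum((x - x.mean()) ** 2))
            if abs(fit.slope - 3.0) <= 3 * se:
                hits += 1
        assert hits >= 95


class TestComparePlots:
    def test_self_comparison_zero_deltas(self):
        ps = points([(0.0, 1.0), (2.0, 3.0)])
        cmp = compare_plots(ps, ps)
        assert cmp.deltas["n"] == 0
        assert cmp.deltas["x_mean"] == 0.0
        assert cmp.deltas["y_mean"] == 0.0

    def test_shift_reflected_in_mean_delta(self):
        a = points([(0.0, 1.0), (2.0, 3.0)])
        b = points([(1.0, 1.0), (3.0, 3.0)])
        cmp = compare_plots(a, b)
        assert cmp.deltas["x_mean"] == pytest.approx(1.0)
        assert cmp.x_range == (0.0, 3.0)

    def test_filtered_query_is_subset_of_unfiltered(self, screen):
        _, graph = screen
        full = run_query(graph, QueryState(
            level="grouping", x_feature="feat_01", y_feature="feat_02"))
        filtered = run_query(graph, QueryState(
            level="grouping", x_feature="feat_01", y_feature="feat_02",
            filters=(FilterClause("Gene", "label-presence", "hit"),)))
        cmp = compare_plots(full, filtered)
        assert cmp.deltas["n"] == len(filtered) - len(full) <= 0
        assert set(r.entity_ids for r in filtered.records) \
            <= set(r.entity_ids for r in full.records)

    def test_mismatched_axes_rejected(self):
        a = points([(0.0, 1.0)])
        b = points([(0.0, 1.0)], x_feature="other")
        with pytest.raises(AnalyticsError):
            compare_plots(a, b)

    def test_mismatched_levels_rejected(self):
        a = points([(0.0, 1.0)])
        b = points([(0.0, 1.0)], level="grouping")
        with pytest.raises(AnalyticsError):
            compare_plots(a, b)
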