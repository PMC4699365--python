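import random

import pytest

from screenminer import (
    FilterClause,
    QueryState,
    Selection,
    aggregate_feature,
    drill_down,
    list_catalog,
    run_query,
)
from screenminer.errors import QueryError, TransformError

from oracles import load_frames, oracle_aggregate, oracle_run_query
from screenminer.query import random_query_state


class TestAggregateFeature:
    def test_mean_per_gene(self, toy_graph):
        assert aggregate_feature(toy_graph, "len", "mean") \
            == {("g1",): 2.0, ("g2",): 15.0}

    def test_count_skips_missing(self, toy_graph):
        # g2 has two cells but only one non-missing width
        assert aggregate_feature(toy_graph, "width", "count") \
            == {("g1",): 3.0, ("g2",): 1.0}

    def test_unknown_feature_rejected(self, toy_graph):
        with pytest.raises(QueryError):
            aggregate_feature(toy_graph, "volume", "mean")

    @pytest.mark.parametrize("method", ["mean", "median", "count",
                                        "min", "max"])
    def test_matches_bruteforce_on_fixture(self, screen, method):
        generated, graph = screen
        df, _ = load_frames(generated.data_path, generated.label_path)
        for feature in graph.feature_catalog("Cell"):
            got = aggregate_feature(graph, feature, method)
            expected = oracle_aggregate(df, feature, method)
            assert got.keys() == expected.keys()
            for key in expected:
                assert got[key] == pytest.approx(expected[key],
                                                 rel=1e-12, abs=0)


class TestRunQuery:
    def test_grouping_level_means(self, toy_graph):
        state = QueryState(level="grouping", x_feature="len",
                           y_feature="width")
        ps = run_query(toy_graph, state)
        assert [(r.entity_ids[0][1], r.x, r.y) for r in ps.records] \
            == [("g1", 2.0, 5.0), ("g2", 15.0, 1.0)]

    def test_label_filter_restricts_genes(self, toy_graph):
        state = QueryState(
            level="grouping", x_feature="len", y_feature="width",
            filters=(FilterClause("Gene", "label-presence", "hit"),))
        ps = run_query(toy_graph, state)
        assert [r.entity_ids[0][1] for r in ps.records] == ["g1"]

    def test_cell_range_filter_applies_before_aggregation(self, toy_graph):
        state = QueryState(
            level="grouping", x_feature="len",
            filters=(FilterClause("Cell", "numeric-range", "len",
                                  low=2.0, high=30.0),))
        ps = run_query(toy_graph, state)
        # g1 keeps cells len=2,3 -> mean 2.5; g2 keeps 10,20 -> mean 15
        assert [(r.entity_ids[0][1], r.x) for r in ps.records] \
            == [("g1", 2.5), ("g2", 15.0)]

    def test_descriptive_level_carries_group_ids(self, toy_graph):
        state = QueryState(level="descriptive", x_feature="len")
        ps = run_query(toy_graph, state)
        assert len(ps) == 5
        by_cell = {r.entity_ids[0][1]: r.group_ids[0][1]
                   for r in ps.records}
        assert by_cell["c1"] == "g1" and by_cell["c4"] == "g2"

    def test_gene_filter_at_cell_level(self, toy_graph):
        state = QueryState(
            level="descriptive", x_feature="len",
            filters=(FilterClause("Gene", "label-presence", "hit"),))
        ps = run_query(toy_graph, state)
        assert sorted(r.entity_ids[0][1] for r in ps.records) \
            == ["c1", "c2", "c3"]

    def test_missing_values_dropped_and_counted(self, toy_graph):
        state = QueryState(level="descriptive", x_feature="len",
                           y_feature="width")
        ps = run_query(toy_graph, state)
        assert len(ps) == 4 and ps.dropped == 1

    def test_log10_transform(self, toy_graph):
        state = QueryState(level="grouping", x_feature="len",
                           x_transform="log10", aggregation="max")
        ps = run_query(toy_graph, state)
        import math
        assert ps.records[1].x == pytest.approx(math.log10(20.0))

    def test_log10_of_nonpositive_raises_with_entities(self, toy_graph):
        bad = toy_graph.add_node("Cell", [("cellID", "c6")],
                                 {"len": -1.0})
        toy_graph.connect(bad, toy_graph.get_node("Gene", ("g2",)).node_id,
                          "BELONGS_TO")
        state = QueryState(level="descriptive", x_feature="len",
                           x_transform="log10")
        with pytest.raises(TransformError) as exc:
            run_query(toy_graph, state)
        assert (("cellID", "c6"),) in exc.value.entities

    def test_unknown_label_rejected(self, toy_graph):
        state = QueryState(
            level="grouping", x_feature="len",
            filters=(FilterClause("Gene", "label-presence", "nope"),))
        with pytest.raises(QueryError, match="nope"):
            run_query(toy_graph, state)

    def test_selection_closed_region(self, toy_graph):
        state = QueryState(level="descriptive", x_feature="len",
                           selection=Selection(x_min=2.0, x_max=10.0))
        ps = run_query(toy_graph, state)
        # boundary points 2.0 and 10.0 included
        assert sorted(r.x for r in ps.records) == [2.0, 3.0, 10.0]

    def test_full_range_selection_is_identity(self, screen):
        _, graph = screen
        base = QueryState(level="descriptive", x_feature="feat_01",
                          y_feature="feat_02")
        full = run_query(graph, base)
        sel = QueryState(
            level="descriptive", x_feature="feat_01", y_feature="feat_02",
            selection=Selection(
                x_min=min(r.x for r in full.records),
                x_max=max(r.x for r in full.records),
                y_min=min(r.y for r in full.records),
                y_max=max(r.y for r in full.records)))
        assert run_query(graph, sel).records == full.records


class TestQueryProperties:
    def test_filter_order_independence(self, screen):
        """Conjunction: permuting the filter list never changes the
        result."""
        _, graph = screen
        rng = random.Random(23)
        tested = 0
        while tested < 15:
            state = random_query_state(graph, rng)
            if len(state.filters) < 2:
                continue
            tested += 1
            shuffled = list(state.filters)
            rng.shuffle(shuffled)
            permuted = QueryState(
                level=state.level, x_feature=state.x_feature,
                y_feature=state.y_feature, aggregation=state.aggregation,
                filters=tuple(shuffled), x_transform=state.x_transform,
                y_transform=state.y_transform, selection=state.selection)
            assert run_query(graph, permuted).records \
                == run_query(graph, state).records

    def test_adding_filter_never_adds_records(self, screen):
        _, graph = screen
        rng = random.Random(29)
        for _ in range(15):
            state = random_query_state(graph, rng)
            base = run_query(graph, state)
            extra = FilterClause("Gene", "label-absence", "hit")
            narrowed = QueryState(
                level=state.level, x_feature=state.x_feature,
                y_feature=state.y_feature, aggregation=state.aggregation,
                filters=state.filters + (extra,),
                x_transform=state.x_transform,
                y_transform=state.y_transform, selection=state.selection)
            assert len(run_query(graph, narrowed)) <= len(base)

    def test_matches_sequential_oracle(self, screen):
        """Graph evaluation equals a literal step-by-step pandas
        re-implementation on the raw CSV."""
        generated, graph = screen
        df, labels = load_frames(generated.data_path, generated.label_path)
        rng = random.Random(31)
        for _ in range(25):
            state = random_query_state(graph, rng)
            expected, errored = oracle_run_query(df, labels, state)
            if errored:
                with pytest.raises(TransformError):
                    run_query(graph, state)
                continue
            ps = run_query(graph, state)
            got = [(tuple(v for _, v in r.entity_ids), r.x, r.y)
                   for r in ps.records]
            assert len(got) == len(expected)
            for (gk, gx, gy), (ek, ex, ey) in zip(got, expected):
                assert gk == ek
                assert gx == pytest.approx(ex, rel=1e-9)
                if ey is None:
                    assert gy is None
                else:
                    assert gy == pytest.approx(ey, rel=1e-9)


class TestDrillDown:
    def test_member_cells_tagged_with_gene(self, toy_graph):
        ps = drill_down(toy_graph, [("g1",)], "len", "width")
        assert len(ps) == 3
        assert {r.group_ids[0][1] for r in ps.records} == {"g1"}

    def test_selection_counts_sum_per_gene(self, screen):
        generated, graph = screen
        counts = generated.truth.cell_counts()
        genes = list(counts)[:5]
        ps = drill_down(graph, [(g,) for g in genes], "feat_01")
        missing = sum(
            1 for g in genes
            for m in graph.membership_map()[
                graph.get_node("Gene", (g,)).node_id]
            if "feat_01" not in graph.node(m).properties)
        assert len(ps) + missing == sum(counts[g] for g in genes)
        assert ps.dropped == missing

    def test_empty_selection_empty_result(self, toy_graph):
        ps = drill_down(toy_graph, [], "len")
        assert len(ps) == 0

    def test_unknown_gene_rejected(self, toy_graph):
        with pytest.raises(QueryError):
            drill_down(toy_graph, [("gX",)], "len")


class TestListCatalog:
    def test_cell_features_sorted(self, toy_graph):
        features, labels = list_catalog(toy_graph, "Cell")
        assert features == ["len", "width"]
        assert labels == []

    def test_gene_labels_after_import(self, toy_graph):
        features, labels = list_catalog(toy_graph, "Gene")
        assert features == []
        assert labels == ["hit"]

    def test_unknown_kind_rejected(self, toy_graph):
        with pytest.raises(QueryError):
            list_catalog(toy_graph, "Plasmid")
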