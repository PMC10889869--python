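"""Ingestion, thresholding, dyad and component structure."""

import io
import itertools

import networkx as nx
import numpy as np
import pytest

from triadflow import (
    ConfigurationError,
    DataError,
    aggregate_periods,
    apply_flow_threshold,
    build_graph,
    component_report,
    dyad_decomposition,
    low_order_summary,
    read_flow_table,
    volume_vs_edges,
)
from triadflow.synthetic import gen_refugee_like_flows, refugee_spec

from conftest import weighted_table


def _csv(text):
    return io.StringIO(text)


class TestReadFlowTable:
    def test_self_flows_dropped(self):
        t = read_flow_table(_csv("origin,destination,year,flow\nA,B,1995,250\nB,A,1995,40\nA,A,1995,9\n"))
        assert len(t) == 2
        assert set(zip(t.df["origin"], t.df["destination"])) == {("A", "B"), ("B", "A")}

    def test_duplicate_keys_summed(self):
        t = read_flow_table(_csv("origin,destination,year,flow\nA,B,1995,100\nA,B,1995,50\n"))
        assert len(t) == 1
        assert t.df["flow"].iloc[0] == 150

    def test_missing_flow_column_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="flow"):
            read_flow_table(_csv("origin,destination,year\nA,B,1995\n"))

    def test_negative_flow_names_the_row(self):
        with pytest.raises(DataError, match="row 3"):
            read_flow_table(_csv("origin,destination,year,flow\nA,B,1995,5\nB,C,1995,-1\n"))

    def test_empty_after_cleaning_is_data_error(self):
        with pytest.raises(DataError):
            read_flow_table(_csv("origin,destination,year,flow\nA,A,1995,10\n"))

    def test_dialect_maps_column_names(self):
        t = read_flow_table(
            _csv("src,dst,yr,n\nA,B,2000,7\n"),
            dialect={"origin": "src", "destination": "dst", "year": "yr", "flow": "n"},
        )
        assert list(t.df.loc[0, ["origin", "destination", "period"]]) == ["A", "B", 2000]


class TestAggregatePeriods:
    def test_five_year_summation(self):
        rows = "".join(f"A,B,{y},100\n" for y in range(1996, 2001))
        t = read_flow_table(_csv("origin,destination,year,flow\n" + rows))
        agg = aggregate_periods(t, 5)
        assert agg.periods == [1995, 2000]
        assert agg.df.loc[agg.df["period"] == 1995, "flow"].iloc[0] == 400  # 1996-99
        assert agg.df.loc[agg.df["period"] == 2000, "flow"].iloc[0] == 100

    def test_partial_window_lands_in_single_bin(self):
        # six records spread over 1991-1993 all fall into the 1990 bin
        rows = (
            "A,B,1991,10\nA,B,1992,20\nA,B,1993,30\n"
            "B,C,1991,5\nB,C,1993,15\nC,A,1992,40\n"
        )
        t = read_flow_table(_csv("origin,destination,year,flow\n" + rows))
        agg = aggregate_periods(t, 5)
        assert agg.periods == [1990]
        flows = dict(zip(zip(agg.df["origin"], agg.df["destination"]), agg.df["flow"]))
        assert flows == {("A", "B"): 60, ("B", "C"): 20, ("C", "A"): 40}

    def test_years_before_window_are_excluded(self):
        t = read_flow_table(_csv("origin,destination,year,flow\nA,B,1980,10\nA,B,1991,20\n"))
        agg = aggregate_periods(t, 5)
        assert agg.df["flow"].tolist() == [20]

    def test_empty_input_empty_output(self):
        t = read_flow_table(_csv("origin,destination,year,flow\nA,B,1980,10\n"))
        agg = aggregate_periods(t, 5)
        assert len(agg) == 0 and agg.span == 5


class TestThreshold:
    def test_five_year_cutoff_is_inclusive(self):
        t = weighted_table([("A", "B", 1995, 500), ("C", "D", 1995, 499)], span=5)
        kept = apply_flow_threshold(t, 100)
        assert list(zip(kept.df["origin"], kept.df["destination"])) == [("A", "B")]

    def test_zero_threshold_is_identity(self, toy_table):
        assert apply_flow_threshold(toy_table, 0).df.equals(toy_table.df)

    def test_monotone_in_threshold(self, rng):
        t = gen_refugee_like_flows(refugee_spec(3, n_periods=3))
        sizes = [len(apply_flow_threshold(t, thr)) for thr in (0, 50, 100, 200, 400)]
        assert sizes == sorted(sizes, reverse=True)

    def test_aggregate_then_threshold_equals_500_cutoff(self):
        """100/yr on 5-year bins is the same filter as a flat 500 cutoff."""
        rng = np.random.default_rng(7)
        rows = [
            ("N%d" % rng.integers(8), "N%d" % rng.integers(8), int(y), int(rng.integers(1, 300)))
            for y in rng.integers(1990, 2000, size=60)
        ]
        rows = [(o, d, y, f) for o, d, y, f in rows if o != d]
        csv = "origin,destination,year,flow\n" + "".join(
            f"{o},{d},{y},{f}\n" for o, d, y, f in rows
        )
        agg = aggregate_periods(read_flow_table(_csv(csv)), 5)
        via_rate = apply_flow_threshold(agg, 100)
        flat = agg.df[agg.df["flow"] >= 500].reset_index(drop=True)
        assert via_rate.df.equals(flat)


class TestBuildGraph:
    def test_arcs_match_records(self, toy_table):
        g = build_graph(toy_table, 1995)
        assert set(g.edges) == {("A", "B"), ("B", "A"), ("A", "C"), ("C", "D")}
        assert g.number_of_nodes() == 4  # no isolated nodes

    def test_weights_attached_on_request(self, toy_table):
        g = build_graph(toy_table, 1995, keep_weights=True)
        assert g["A"]["C"]["weight"] == 600

    def test_unknown_period_raises(self, toy_table):
        with pytest.raises(KeyError):
            build_graph(toy_table, 1800)


class TestDyadDecomposition:
    def test_definition_example(self, toy_graph):
        d = dyad_decomposition(toy_graph)
        assert (d.n_nodes, d.n_mutual, d.n_asym) == (3, 1, 1)
        assert d.m == pytest.approx(1 / 3) and d.a == pytest.approx(1 / 3)
        assert d.overall == pytest.approx(2 / 3)

    def test_complete_bidirectional(self):
        g = nx.complete_graph(4, create_using=nx.DiGraph)
        d = dyad_decomposition(g)
        assert d.m == 1.0 and d.a == 0.0

    def test_against_bruteforce_pair_classification(self, rng):
        from conftest import random_digraph

        g = random_digraph(rng, n=20)
        d = dyad_decomposition(g)
        m = a = 0
        for u, v in itertools.combinations(sorted(g.nodes), 2):
            uv, vu = g.has_edge(u, v), g.has_edge(v, u)
            m += uv and vu
            a += uv != vu
        assert (d.n_mutual, d.n_asym) == (m, a)
        assert 2 * d.n_mutual + d.n_asym == g.number_of_edges()

    def test_degenerate_input(self):
        g = nx.DiGraph()
        g.add_node("A")
        with pytest.raises(ValueError):
            dyad_decomposition(g)


class TestComponentReport:
    def test_sizes_and_ordering(self):
        g = nx.DiGraph([("A", "B"), ("C", "D"), ("X", "Y"), ("Y", "Z"), ("Z", "X")])
        rep = component_report(g)
        assert rep.n_components == 3
        assert rep.component_sizes == [3, 2, 2]
        assert set(rep.largest_component.nodes) == {"X", "Y", "Z"}

    def test_flow_fractions(self):
        g = nx.DiGraph()
        g.add_weighted_edges_from(
            [("X", "Y", 500), ("Y", "Z", 500), ("Z", "X", 500), ("A", "B", 100), ("C", "D", 100)]
        )
        rep = component_report(g)
        assert rep.flow_fraction_largest == pytest.approx(1500 / 1700)
        assert rep.flow_fraction_second == pytest.approx(100 / 1700)
        assert sum(rep.component_flows) == pytest.approx(1.0)

    def test_connected_graph(self):
        g = nx.DiGraph()
        g.add_weighted_edges_from([("A", "B", 10), ("B", "C", 5)])
        rep = component_report(g)
        assert rep.n_components == 1
        assert rep.flow_fraction_largest == 1.0
        assert rep.flow_fraction_second is None

    def test_size_tie_broken_by_flow_then_label(self):
        g = nx.DiGraph()
        g.add_weighted_edges_from([("A", "B", 10), ("C", "D", 99)])
        rep = component_report(g)
        assert set(rep.largest_component.nodes) == {"C", "D"}

    def test_component_sizes_partition_nodes(self, rng):
        from conftest import random_digraph

        g = random_digraph(rng, n=30, p=0.04)
        rep = component_report(g)
        assert sum(rep.component_sizes) == g.number_of_nodes()


class TestVolumeAndSummary:
    def test_volume_vs_edges_counts(self):
        t = weighted_table(
            [("A", "B", 2000, 600), ("B", "C", 2000, 400), ("C", "A", 2000, 50)]
        )
        row = volume_vs_edges(t, 100).iloc[0]
        assert row["total_flow"] == 1050
        assert row["n_arcs_raw"] == 3 and row["n_arcs_thresholded"] == 2

    def test_zero_threshold_keeps_all_arcs(self, toy_table):
        tab = volume_vs_edges(toy_table, 0)
        assert (tab["n_arcs_raw"] == tab["n_arcs_thresholded"]).all()

    def test_thresholded_never_exceeds_raw_on_synthetic_series(self):
        t = gen_refugee_like_flows(refugee_spec(11, n_periods=4))
        tab = volume_vs_edges(t, 100)
        assert (tab["n_arcs_thresholded"] <= tab["n_arcs_raw"]).all()

    def test_low_order_summary_example(self, toy_graph):
        s = low_order_summary(toy_graph)
        assert s["n_nodes"] == 3 and s["n_arcs"] == 3
        assert s["reciprocity"] == pytest.approx(2 / 3)

    def test_low_order_summary_against_recomputation(self, rng):
        from conftest import random_digraph

        g = random_digraph(rng, n=30)
        s = low_order_summary(g)
        # independent recomputation from raw adjacency lists
        n = len(g)
        arcs = sum(len(list(g.successors(u))) for u in g)
        mut = sum(
            1 for u in g for v in g.successors(u) if g.has_edge(v, u)
        )
        assert s["n_arcs"] == arcs
        assert s["density"] == pytest.approx(arcs / (n * (n - 1)))
        assert s["reciprocity"] == pytest.approx(mut / arcs)
        assert s["mean_out_degree"] == pytest.approx(arcs / n)
        assert s["n_components"] == nx.number_weakly_connected_components(g)
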