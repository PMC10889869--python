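"""Weighted flow-table ingestion and low-order network structure.

Flow data arrive as long-format CSV records (origin, destination, year, flow
count).  They are normalized (self-flows dropped, duplicate keys summed),
optionally aggregated to multi-year periods, thresholded to "substantial"
flows (at least ``min_flow_per_year`` people per year, inclusive), and turned
into simple unweighted digraphs for the topological analysis.  Low-order
structure — the mutual/asymmetric/null dyad decomposition and weak-component
fragmentation — is computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DataError",
    "FlowTable",
    "DyadStats",
    "ComponentReport",
    "read_flow_table",
    "write_flow_csv",
    "aggregate_periods",
    "apply_flow_threshold",
    "build_graph",
    "dyad_decomposition",
    "component_report",
    "volume_vs_edges",
    "low_order_summary",
]

logger = logging.getLogger(__name__)

#: default column-name map for flow CSVs
DEFAULT_DIALECT = {
    "origin": "origin",
    "destination": "destination",
    "year": "year",
    "flow": "flow",
}


class ConfigurationError(Exception):
    """The input cannot be read with the given configuration (e.g. a missing column)."""


class DataError(Exception):
    """The input violates the data contract (negative flow, empty table, ...)."""


@dataclass
class FlowTable:
    """Normalized long-format flow records.

    ``df`` has columns origin, destination, period, flow, at most one row per
    (origin, destination, period); ``span`` is the common period length in
    years and ``period`` labels are period start years.
    """

    df: pd.DataFrame
    span: int = 1

    def __post_init__(self):
        if self.span not in (1, 5):
            raise ValueError("period span must be 1 or 5 years")

    @property
    def periods(self) -> list:
        return sorted(self.df["period"].unique().tolist())

    def __len__(self) -> int:
        return len(self.df)


def read_flow_table(source, dialect: dict | None = None, span: int = 1) -> FlowTable:
    """Read and normalize a flow CSV (path or open text stream).

    ``dialect`` maps the logical names origin/destination/year/flow to the
    file's column names.  Self-flows are dropped (with a logged count),
    duplicate (origin, destination, year) keys are summed, and years become
    periods of the given ``span`` (pass ``span=5`` for a file whose year
    column holds 5-year bin start years).  Node labels are kept as opaque
    strings.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(source)
    for logical in ("origin", "destination", "year", "flow"):
        col = dialect[logical]
        if col not in raw.columns:
            raise ConfigurationError(
                f"input lacks column {col!r} (mapped from {logical!r}); "
                f"columns present: {list(raw.columns)}"
            )
    df = pd.DataFrame(
        {
            "origin": raw[dialect["origin"]].astype(str),
            "destination": raw[dialect["destination"]].astype(str),
            "period": raw[dialect["year"]].astype(int),
            "flow": pd.to_numeric(raw[dialect["flow"]], errors="coerce"),
        }
    )
    bad = df.index[df["flow"].isna() | (df["flow"] < 0)]
    if len(bad):
        # +2: header line and 1-based numbering
        raise DataError(f"negative or unparseable flow at row {int(bad[0]) + 2}")
    self_loops = int((df["origin"] == df["destination"]).sum())
    if self_loops:
        logger.info("dropping %d self-flow record(s)", self_loops)
        df = df[df["origin"] != df["destination"]]
    if df.empty:
        raise DataError("flow table is empty after cleaning")
    df = (
        df.groupby(["origin", "destination", "period"], as_index=False)["flow"]
        .sum()
        .sort_values(["period", "origin", "destination"], ignore_index=True)
    )
    return FlowTable(df, span=span)


def write_flow_csv(t: FlowTable, path) -> None:
    """Write a FlowTable in the long CSV format :func:`read_flow_table` reads
    (period labels under the ``year`` column)."""
    t.df.rename(columns={"period": "year"}).to_csv(path, index=False)


def aggregate_periods(
    t: FlowTable,
    span_years: int,
    window_start: int = 1990,
    window_end: int | None = None,
) -> FlowTable:
    """Sum annual flows into ``span_years``-wide bins labelled by start year.

    Bins are half-open ``[start, start + span)`` anchored at ``window_start``
    (default 1990, matching the 5-year analysis windows 1990-94, 1995-99,
    ...).  Years before ``window_start`` or at/after ``window_end`` are
    excluded with a logged count.
    """
    if t.span != 1:
        raise ValueError("aggregation expects an annual (span-1) table")
    df = t.df
    keep = df["period"] >= window_start
    if window_end is not None:
        keep &= df["period"] < window_end
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluding %d record(s) outside the analysis window", dropped)
    df = df[keep].copy()
    if df.empty:
        return FlowTable(df.reset_index(drop=True), span=span_years)
    df["period"] = window_start + ((df["period"] - window_start) // span_years) * span_years
    df = (
        df.groupby(["origin", "destination", "period"], as_index=False)["flow"]
        .sum()
        .sort_values(["period", "origin", "destination"], ignore_index=True)
    )
    return FlowTable(df, span=span_years)


def apply_flow_threshold(t: FlowTable, min_flow_per_year: float) -> FlowTable:
    """Keep records with flow >= ``min_flow_per_year`` x span (inclusive).

    "100 or more per year" on a 5-year bin means a cutoff of 500 for the
    period total; a flow exactly at the cutoff survives.
    """
    if min_flow_per_year < 0:
        raise ValueError("threshold must be nonnegative")
    cutoff = min_flow_per_year * t.span
    df = t.df[t.df["flow"] >= cutoff].reset_index(drop=True)
    logger.info(
        "threshold %g/yr (cutoff %g): %d of %d records retained",
        min_flow_per_year, cutoff, len(df), len(t.df),
    )
    return FlowTable(df, span=t.span)


def build_graph(t: FlowTable, period, keep_weights: bool = False) -> nx.DiGraph:
    """Digraph of one period: an arc per record, isolated nodes absent."""
    if period not in set(t.periods):
        raise KeyError(f"period {period!r} not present (have {t.periods})")
    rows = t.df[t.df["period"] == period]
    g = nx.DiGraph()
    if keep_weights:
        g.add_weighted_edges_from(
            zip(rows["origin"], rows["destination"], rows["flow"].astype(float))
        )
    else:
        g.add_edges_from(zip(rows["origin"], rows["destination"]))
    return g


@dataclass(frozen=True)
class DyadStats:
    """Mutual/asymmetric/null decomposition of a digraph's node pairs.

    Densities are fractions of the N(N-1)/2 unordered pairs: ``m`` mutual
    (arcs both ways), ``a`` asymmetric (exactly one way), ``overall`` their
    sum (the fraction of pairs connected at all).
    """

    n_nodes: int
    n_mutual: int
    n_asym: int

    @property
    def n_pairs(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def m(self) -> float:
        return self.n_mutual / self.n_pairs

    @property
    def a(self) -> float:
        return self.n_asym / self.n_pairs

    @property
    def overall(self) -> float:
        return self.m + self.a


def dyad_decomposition(g: nx.DiGraph) -> DyadStats:
    """Classify every unordered node pair as mutual, asymmetric, or null."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("dyad decomposition needs at least 2 nodes")
    mutual = sum(1 for u, v in g.edges if g.has_edge(v, u)) // 2
    asym = g.number_of_edges() - 2 * mutual
    return DyadStats(n, mutual, asym)


@dataclass
class ComponentReport:
    """Weak-connectivity structure of a (possibly weighted) digraph.

    Components are sorted by node count, ties broken by total internal flow
    then by the lexicographically smallest node label.  Flow fractions are
    per-component shares of total arc weight (``None`` without weights;
    ``flow_fraction_second`` is ``None`` for connected graphs).
    """

    n_components: int
    component_sizes: list
    largest_component: nx.DiGraph
    flow_fraction_largest: float | None = None
    flow_fraction_second: float | None = None
    component_flows: list | None = None


def _has_weights(g: nx.DiGraph) -> bool:
    return g.number_of_edges() > 0 and all(
        "weight" in d for _, _, d in g.edges(data=True)
    )


def component_report(g: nx.DiGraph) -> ComponentReport:
    """Weak components of ``g``, deterministically ordered."""
    if g.number_of_nodes() == 0:
        raise ValueError("component report needs a non-empty graph")
    weighted = _has_weights(g)
    comps = []
    for nodes in nx.weakly_connected_components(g):
        sub = g.subgraph(nodes)
        flow = (
            sum(d["weight"] for _, _, d in sub.edges(data=True)) if weighted else 0.0
        )
        comps.append((len(nodes), flow, min(str(n) for n in nodes), nodes))
    comps.sort(key=lambda c: (-c[0], -c[1], c[2]))
    sizes = [c[0] for c in comps]
    largest = g.subgraph(comps[0][3]).copy()
    flows = [c[1] for c in comps]
    total = sum(flows)
    frac_largest = frac_second = None
    comp_flows = None
    if weighted and total > 0:
        comp_flows = [f / total for f in flows]
        frac_largest = comp_flows[0]
        frac_second = comp_flows[1] if len(comp_flows) > 1 else None
    return ComponentReport(
        len(comps), sizes, largest, frac_largest, frac_second, comp_flows
    )


def volume_vs_edges(t: FlowTable, min_flow_per_year: float) -> pd.DataFrame:
    """Per period: total flow volume, raw arc count, and post-threshold arc count.

    Separates changes in how much moves (volume) from changes in where it
    moves (topology): the two need not track each other.
    """
    if t.df.empty:
        raise ValueError("flow table is empty")
    cutoff = min_flow_per_year * t.span
    rows = []
    for period, grp in t.df.groupby("period"):
        rows.append(
            {
                "period": period,
                "total_flow": float(grp["flow"].sum()),
                "n_arcs_raw": int(len(grp)),
                "n_arcs_thresholded": int((grp["flow"] >= cutoff).sum()),
            }
        )
    return pd.DataFrame(rows).sort_values("period", ignore_index=True)


def low_order_summary(g: nx.DiGraph) -> dict:
    """Basic graph-theoretic metrics of a digraph (one flat record).

    Covers size, arc density, the reciprocity fraction 2M/(2M+A), mean
    degrees, and fragmentation; total flow appears only when every arc is
    weighted.  Extensible superset of the usual low-order summaries.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("summary needs a non-empty graph")
    n = g.number_of_nodes()
    arcs = g.number_of_edges()
    d = dyad_decomposition(g) if n >= 2 else None
    comp_sizes = sorted((len(c) for c in nx.weakly_connected_components(g)), reverse=True)
    out = {
        "n_nodes": n,
        "n_arcs": arcs,
        "density": arcs / (n * (n - 1)) if n > 1 else float("nan"),
        "reciprocity": (2 * d.n_mutual / arcs) if (d and arcs) else float("nan"),
        "mean_in_degree": arcs / n,
        "mean_out_degree": arcs / n,
        "n_components": len(comp_sizes),
        "largest_component_size": comp_sizes[0],
    }
    if _has_weights(g):
        out["total_flow"] = float(
            sum(w for _, _, w in g.edges(data="weight"))
        )
    return out
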