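import io

import networkx as nx
import numpy as np
import pytest

from triadflow import FlowTable, read_flow_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def toy_graph():
    """A ⇄ B plus A → C: one mutual pair, one asymmetric arc."""
    g = nx.DiGraph()
    g.add_edges_from([("A", "B"), ("B", "A"), ("A", "C")])
    return g


@pytest.fixture
def toy_table():
    csv = io.StringIO(
        "origin,destination,year,flow\n"
        "A,B,1995,250\n"
        "B,A,1995,40\n"
        "A,C,1995,600\n"
        "C,D,1995,120\n"
    )
    return read_flow_table(csv)


def random_digraph(rng, n=None, p=None, bias=None) -> nx.DiGraph:
    """Random digraph with varied size, density and reciprocity."""
    n = n if n is not None else int(rng.integers(3, 41))
    p = p if p is not None else float(rng.uniform(0.02, 0.5))
    bias = bias if bias is not None else float(rng.uniform(0.0, 0.9))
    adj = rng.random((n, n)) < p
    np.fill_diagonal(adj, False)
    asym = adj & ~adj.T
    adj = adj | (asym & (rng.random((n, n)) < bias)).T
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, np.argwhere(adj)))
    return g


def weighted_table(records, span=1) -> FlowTable:
    import pandas as pd

    df = pd.DataFrame(records, columns=["origin", "destination", "period", "flow"])
    return FlowTable(df, span=span)
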