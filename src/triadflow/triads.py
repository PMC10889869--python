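"""Catalog of the 13 connected directed triad classes and the triad census.

A *triad* is a set of three nodes together with all arcs the digraph induces
among them (induced-subgraph semantics, so the classes are mutually exclusive
and partition the connected triples).  Simple digraphs admit 16 isomorphism
classes of 3-node subgraphs; 13 of them are weakly connected and those are the
classes whose frequencies make up a triad significance profile.

The catalog index order (1..13) follows the standard significance-profile
ordering: the three mutual-free 2-arc classes first (divergent, convergent,
chain), then the single-mutual 2-arc classes, the double-mutual "frustration"
class, the two all-asymmetric 3-arc classes (feed-forward, cycle), the three
single-mutual 3-arc classes, and the two densest classes.  Holland-Leinhardt
MAN codes are carried for interoperability with other triad-census tooling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

from ._kernels import census_kernel

__all__ = [
    "TriadClass",
    "TRIAD_CATALOG",
    "DISCONNECTED",
    "canonical_triad_class",
    "TriadCensus",
    "census",
    "census_bruteforce",
]

#: class label returned for triples whose induced subgraph is not weakly
#: connected (the 3 disconnected isomorphism classes: empty, single-arc,
#: single-mutual — each possibly padded with an isolated third node).
DISCONNECTED = "disconnected"


@dataclass(frozen=True)
class TriadClass:
    """One of the 13 connected triad isomorphism classes."""

    index: int  # 1..13, significance-profile order
    man_code: str  # Holland–Leinhardt MAN code (networkx-compatible)
    label: str
    arcs: frozenset  # canonical representative on nodes 0, 1, 2
    #: (mutual, asymmetric, null) dyad counts
    dyads: tuple = field(init=False)

    def __post_init__(self):
        m = a = 0
        for u, v in itertools.combinations(range(3), 2):
            has_uv = (u, v) in self.arcs
            has_vu = (v, u) in self.arcs
            if has_uv and has_vu:
                m += 1
            elif has_uv or has_vu:
                a += 1
        object.__setattr__(self, "dyads", (m, a, 3 - m - a))


def _cls(index, man, label, arcs):
    return TriadClass(index, man, label, frozenset(arcs))


#: Source-of-truth table for the 13 connected classes.  Representatives are
#: explicit arc patterns on the ordered node triple (0, 1, 2).
TRIAD_CATALOG: tuple = (
    _cls(1, "021D", "divergent", [(0, 1), (0, 2)]),
    _cls(2, "021U", "convergent", [(1, 0), (2, 0)]),
    _cls(3, "021C", "chain", [(0, 1), (1, 2)]),
    _cls(4, "111D", "mutual-in", [(0, 1), (1, 0), (2, 0)]),
    _cls(5, "111U", "mutual-out", [(0, 1), (1, 0), (0, 2)]),
    _cls(6, "201", "frustration", [(0, 1), (1, 0), (0, 2), (2, 0)]),
    _cls(7, "030T", "feed-forward", [(0, 1), (1, 2), (0, 2)]),
    _cls(8, "030C", "cycle", [(0, 1), (1, 2), (2, 0)]),
    _cls(9, "120D", "mutual-pair-fed", [(0, 1), (1, 0), (2, 0), (2, 1)]),
    _cls(10, "120U", "mutual-pair-feeding", [(0, 1), (1, 0), (0, 2), (1, 2)]),
    _cls(11, "120C", "mutual-pair-bridged", [(0, 1), (1, 0), (0, 2), (2, 1)]),
    _cls(12, "210", "near-clique", [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2)]),
    _cls(13, "300", "clique", [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]),
)

_PAIR_BITS = {(0, 1): 1, (1, 0): 2, (0, 2): 4, (2, 0): 8, (1, 2): 16, (2, 1): 32}


def _code_of(arcs) -> int:
    return sum(_PAIR_BITS[a] for a in arcs)


def _arcs_of(code: int):
    return frozenset(p for p, b in _PAIR_BITS.items() if code & b)


def _permute(arcs, perm):
    return frozenset((perm[u], perm[v]) for u, v in arcs)


def _connected3(arcs) -> bool:
    und = {frozenset(a) for a in arcs}
    # 3 nodes are weakly connected iff >=2 distinct support pairs
    return len(und) >= 2


def _build_code_table() -> np.ndarray:
    """Map every 6-bit arc code on an ordered triple to its class (0 = disconnected)."""
    table = np.zeros(64, np.int8)
    perms = list(itertools.permutations(range(3)))
    for code in range(64):
        arcs = _arcs_of(code)
        if not _connected3(arcs):
            continue
        hits = [
            c.index
            for c in TRIAD_CATALOG
            if any(_permute(arcs, perm) == c.arcs for perm in perms)
        ]
        if len(hits) != 1:  # pragma: no cover - catalog integrity guard
            raise RuntimeError(f"code {code} matched classes {hits}")
        table[code] = hits[0]
    return table


#: 64-entry lookup: arc code of an ordered triple -> class index (0 = disconnected).
CODE_TABLE: np.ndarray = _build_code_table()


def canonical_triad_class(
    arcs: Iterable[tuple], nodes: Sequence[Hashable] | None = None
) -> int | str:
    """Classify the induced subgraph on three distinguished nodes.

    Parameters
    ----------
    arcs
        Ordered pairs among the three nodes (no self-loops).
    nodes
        The node triple; required when some of the three nodes carry no arcs
        (they cannot be inferred from ``arcs`` alone).

    Returns
    -------
    The class index 1..13, or ``"disconnected"``.  Classification is
    isomorphism-invariant: relabelling the nodes never changes the class.
    """
    arcs = list(arcs)
    seen = {n for a in arcs for n in a}
    if nodes is None:
        nodes = sorted(seen, key=repr)
    nodes = list(nodes)
    if len(set(nodes)) != 3:
        raise ValueError("a triad needs exactly 3 distinct nodes")
    if not seen <= set(nodes):
        raise ValueError("arc endpoint outside the node triple")
    if any(u == v for u, v in arcs):
        raise ValueError("self-loops are not allowed in a triad")
    idx = {n: i for i, n in enumerate(nodes)}
    cls = CODE_TABLE[_code_of({(idx[u], idx[v]) for u, v in arcs})]
    return DISCONNECTED if cls == 0 else int(cls)


@dataclass
class TriadCensus:
    """Counts of the 13 connected triad classes in a digraph.

    ``counts[i - 1]`` is the number of unordered node triples whose induced
    subgraph belongs to class ``i``.
    """

    counts: np.ndarray  # shape (13,), int64
    n_nodes: int
    too_small: bool = False  # fewer than 3 nodes: census is trivially zero

    @property
    def n_connected_triples(self) -> int:
        return int(self.counts.sum())

    @property
    def n_triples_total(self) -> int:
        n = self.n_nodes
        return n * (n - 1) * (n - 2) // 6

    def __getitem__(self, class_index: int) -> int:
        """Count for catalog class ``class_index`` (1..13)."""
        if not 1 <= class_index <= 13:
            raise KeyError(class_index)
        return int(self.counts[class_index - 1])

    def as_dict(self) -> dict:
        return {f"t{i}": int(self.counts[i - 1]) for i in range(1, 14)}


def graph_to_arrays(g: nx.DiGraph, nodelist=None):
    """Dense bool adjacency + node list for kernel consumption."""
    if nodelist is None:
        nodelist = sorted(g.nodes, key=repr)
    idx = {n: i for i, n in enumerate(nodelist)}
    n = len(nodelist)
    adj = np.zeros((n, n), np.bool_)
    for u, v in g.edges:
        if u == v:
            raise ValueError("self-loops are not supported")
        adj[idx[u], idx[v]] = True
    return adj, nodelist


def census_from_adj(adj: np.ndarray) -> np.ndarray:
    """13-vector of triad counts from a dense bool adjacency matrix."""
    supp = adj | adj.T
    iu, iv = np.nonzero(np.triu(supp, 1))
    edges = np.column_stack([iu, iv]).astype(np.int64)
    if edges.size == 0:
        return np.zeros(13, np.int64)
    indptr = np.zeros(adj.shape[0] + 1, np.int64)
    counts_per_row = supp.sum(axis=1)
    np.cumsum(counts_per_row, out=indptr[1:])
    indices = np.nonzero(supp)[1].astype(np.int64)
    raw = census_kernel(adj, edges, indptr, indices, CODE_TABLE)
    return raw[1:14].copy()


def census(g: nx.DiGraph) -> TriadCensus:
    """Tally the 13 connected triad classes of a simple digraph.

    The enumeration walks connected triples through the adjacency structure
    (each support edge proposes its neighbours' triples, deduplicated by the
    triple's lexicographically smallest support edge), so the all-triples
    space C(N, 3) is never materialized.
    """
    n = g.number_of_nodes()
    if n < 3:
        return TriadCensus(np.zeros(13, np.int64), n, too_small=True)
    adj, _ = graph_to_arrays(g)
    return TriadCensus(census_from_adj(adj), n)


def census_bruteforce(g: nx.DiGraph, cap: int = 60) -> TriadCensus:
    """O(N^3) oracle: classify every one of the C(N, 3) triples directly.

    Same contract as :func:`census`; refuses graphs above ``cap`` nodes.
    """
    n = g.number_of_nodes()
    if n > cap:
        raise ValueError(f"brute-force census capped at {cap} nodes (got {n})")
    counts = np.zeros(13, np.int64)
    if n < 3:
        return TriadCensus(counts, n, too_small=True)
    nodes = sorted(g.nodes, key=repr)
    for triple in itertools.combinations(nodes, 3):
        tset = set(triple)
        arcs = [
            (u, v)
            for u in triple
            for v in g.successors(u)
            if v in tset
        ]
        cls = canonical_triad_class(arcs, nodes=triple)
        if cls != DISCONNECTED:
            counts[cls - 1] += 1
    return TriadCensus(counts, n)


def iter_connected_triples(g: nx.DiGraph):
    """Yield ``(triple, class_index)`` for every connected triple.

    Pure-Python companion to :func:`census` used where the triples themselves
    are needed (exemplar extraction); same dedup rule as the kernel.
    """
    nodes = sorted(g.nodes, key=repr)
    idx = {n: i for i, n in enumerate(nodes)}
    und = {n: set() for n in nodes}
    for u, v in g.edges:
        und[u].add(v)
        und[v].add(u)

    def pos(x, y):
        a, b = idx[x], idx[y]
        return (a, b) if a < b else (b, a)

    for u in nodes:
        for v in und[u]:
            if idx[v] <= idx[u]:
                continue
            for w in und[u] | und[v]:
                if w == u or w == v:
                    continue
                e_uv = (idx[u], idx[v])
                if w in und[u] and pos(u, w) < e_uv:
                    continue
                if w in und[v] and pos(v, w) < e_uv:
                    continue
                triple = (u, v, w)
                arcs = [
                    (x, y)
                    for x in triple
                    for y in triple
                    if x != y and g.has_edge(x, y)
                ]
                cls = canonical_triad_class(arcs, nodes=triple)
                if cls != DISCONNECTED:  # pragma: no branch
                    yield triple, cls
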