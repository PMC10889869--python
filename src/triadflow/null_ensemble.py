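"""Degree- and reciprocity-preserving rewiring null model.

The randomization repeatedly picks two arcs of the same dyadic type — either
asymmetric (nonreciprocal) or mutual (reciprocal) — cuts them, and swaps their
endpoints.  A proposal is rejected whenever it would create a self-loop,
duplicate an arc, or change any dyad's type, so after any number of swaps the
node set, every node's in-degree and out-degree, and every node's counts of
incident mutual and asymmetric arcs are exactly those of the input graph.
Only structure of triadic and higher order is randomized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._kernels import rewire_kernel
from .triads import census_from_adj, graph_to_arrays

__all__ = [
    "RewireConfig",
    "EnsembleCensus",
    "classify_arcs",
    "attempt_swap",
    "rewire",
    "ensemble_census",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RewireConfig:
    """Knobs of the switching chain and the null ensemble.

    attempts_per_arc
        Swap proposals per arc of the graph; 100 proposals/arc drives even a
        few-hundred-arc network through tens of thousands of switches, far
        past the mixing point of the chain for desk-scale graphs.
    ensemble_size
        Number of independently rewired networks (200 by default).
    seed
        Root seed; ensemble member ``k`` uses the numpy child stream
        ``SeedSequence([seed, k])`` so runs parallelize reproducibly.
    max_consecutive_failures
        Safeguard: abort a chain stuck rejecting this many proposals in a row
        (pathologically constrained graphs), flagging the result.
    """

    attempts_per_arc: float = 100.0
    ensemble_size: int = 200
    seed: int = 0
    max_consecutive_failures: int = 100_000

    def __post_init__(self):
        if self.attempts_per_arc <= 0 or self.ensemble_size <= 0:
            raise ValueError("attempts_per_arc and ensemble_size must be positive")


def classify_arcs(g: nx.DiGraph):
    """Partition the arc set into mutual dyads and asymmetric arcs.

    Returns ``(mutual, asymmetric)`` where ``mutual`` is a set of unordered
    ``frozenset`` pairs and ``asymmetric`` a set of ordered ``(tail, head)``
    arcs.  Every arc falls in exactly one category:
    ``2 * len(mutual) + len(asymmetric) == g.number_of_edges()``.
    """
    mutual = set()
    asymmetric = set()
    for u, v in g.edges:
        if g.has_edge(v, u):
            mutual.add(frozenset((u, v)))
        else:
            asymmetric.add((u, v))
    return mutual, asymmetric


def _arc_arrays(adj: np.ndarray):
    """(M, 2) mutual dyads and (A, 2) asymmetric arcs from an adjacency matrix."""
    both = adj & adj.T
    iu, iv = np.nonzero(np.triu(both, 1))
    mut = np.column_stack([iu, iv]).astype(np.int64)
    only = adj & ~adj.T
    iu, iv = np.nonzero(only)
    asym = np.column_stack([iu, iv]).astype(np.int64)
    return mut, asym


def _predraw(rng: np.random.Generator, n_att: int, n_asym: int, n_mut: int):
    """Pre-draw every random decision of a chain of ``n_att`` proposals."""
    total = n_asym + 2 * n_mut
    if n_asym >= 2 and n_mut >= 2:
        kinds = (rng.random(n_att) < (2 * n_mut) / total).astype(np.uint8)
    elif n_mut >= 2:
        kinds = np.ones(n_att, np.uint8)
    else:
        kinds = np.zeros(n_att, np.uint8)
    ia = rng.integers(0, max(n_asym, 1), size=(n_att, 2))
    im = rng.integers(0, max(n_mut, 1), size=(n_att, 2))
    flips = rng.integers(0, 2, size=(n_att, 2))
    return kinds, ia, im, flips


def _rewire_arrays(adj, mut, asym, cfg: RewireConfig, rng: np.random.Generator):
    """Run one chain in place on the array state; returns diagnostics."""
    n_arcs = int(adj.sum())
    n_att = int(round(cfg.attempts_per_arc * n_arcs))
    kinds, ia, im, flips = _predraw(rng, n_att, asym.shape[0], mut.shape[0])
    acc_a, att_a, acc_m, att_m, aborted = rewire_kernel(
        adj, asym, mut, kinds, ia, im, flips, cfg.max_consecutive_failures
    )
    return {
        "attempts": n_att,
        "accepted": acc_a + acc_m,
        "accepted_asym": acc_a,
        "attempted_asym": att_a,
        "accepted_mutual": acc_m,
        "attempted_mutual": att_m,
        "acceptance_rate": (acc_a + acc_m) / n_att if n_att else 0.0,
        "aborted": bool(aborted),
    }


def attempt_swap(g: nx.DiGraph, kind: str, rng: np.random.Generator) -> bool:
    """Propose one cut-and-swap of the given kind, mutating ``g`` if accepted.

    ``kind`` is ``"mutual"`` or ``"asymmetric"``.  Returns the success flag;
    on rejection (self-loop, duplicate arc, dyad-type change, or fewer than 2
    candidate edges) the graph is untouched.
    """
    mutual, asymmetric = classify_arcs(g)
    if kind == "asymmetric":
        arcs = sorted(asymmetric, key=repr)
        if len(arcs) < 2:
            logger.debug("fewer than 2 asymmetric arcs; no swap possible")
            return False
        i, j = rng.integers(0, len(arcs), size=2)
        if i == j:
            return False
        (u, v), (x, y) = arcs[i], arcs[j]
        bad = (
            u == y
            or x == v
            or g.has_edge(u, y)
            or g.has_edge(x, v)
            or g.has_edge(y, u)
            or g.has_edge(v, x)
        )
        if bad:
            return False
        g.remove_edges_from([(u, v), (x, y)])
        g.add_edges_from([(u, y), (x, v)])
        return True
    if kind == "mutual":
        dyads = sorted((sorted(d, key=repr) for d in mutual), key=repr)
        if len(dyads) < 2:
            logger.debug("fewer than 2 mutual dyads; no swap possible")
            return False
        i, j = rng.integers(0, len(dyads), size=2)
        if i == j:
            return False
        fi, fj = rng.integers(0, 2, size=2)
        u, v = dyads[i][fi], dyads[i][1 - fi]
        x, y = dyads[j][fj], dyads[j][1 - fj]
        bad = (
            u == y
            or x == v
            or g.has_edge(u, y)
            or g.has_edge(y, u)
            or g.has_edge(x, v)
            or g.has_edge(v, x)
        )
        if bad:
            return False
        g.remove_edges_from([(u, v), (v, u), (x, y), (y, x)])
        g.add_edges_from([(u, y), (y, u), (x, v), (v, x)])
        return True
    raise ValueError(f"unknown swap kind {kind!r}")


def rewire(
    g: nx.DiGraph, cfg: RewireConfig, rng: np.random.Generator | None = None
) -> nx.DiGraph:
    """Return a randomized copy of ``g`` after a full switching chain.

    The output has the same node set and, per node, identical in-degree,
    out-degree, and incident mutual/asymmetric arc counts.  Arc weights are
    not carried over (they are meaningless after switching).  Diagnostics
    (acceptance rates, warnings) are attached to ``result.graph``.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot rewire an empty graph")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    adj, nodelist = graph_to_arrays(g)
    mut, asym = _arc_arrays(adj)
    out = nx.DiGraph()
    out.add_nodes_from(nodelist)
    if mut.shape[0] < 2 and asym.shape[0] < 2:
        out.add_edges_from(g.edges)
        out.graph["rewire_warning"] = "no swappable arc pairs; returned a copy"
        logger.warning("graph has no swappable arc pairs; rewire is a no-op")
        return out
    diag = _rewire_arrays(adj, mut, asym, cfg, rng)
    iu, iv = np.nonzero(adj)
    out.add_edges_from((nodelist[a], nodelist[b]) for a, b in zip(iu, iv))
    out.graph["rewire_diagnostics"] = diag
    if diag["aborted"]:
        out.graph["rewire_warning"] = "chain aborted after max consecutive failures"
        logger.warning("rewiring chain aborted early (stuck rejecting)")
    return out


@dataclass
class EnsembleCensus:
    """Triad censuses of an ensemble of rewired networks.

    ``member_counts`` is an (ensemble_size, 13) matrix; ``mean`` and ``sd``
    are its per-class column statistics (population sd, ddof=0 — the ensemble
    IS the reference population the z-scores are taken against).
    """

    member_counts: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def mean(self) -> np.ndarray:
        return self.member_counts.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.member_counts.std(axis=0, ddof=0)

    @property
    def size(self) -> int:
        return self.member_counts.shape[0]


def ensemble_census(
    g: nx.DiGraph, cfg: RewireConfig, census_fn=None
) -> EnsembleCensus:
    """Census the ensemble of ``cfg.ensemble_size`` independent rewirings.

    Each member starts from a fresh copy of ``g`` and is censused whole (no
    re-extraction of components, preserving node/arc comparability with the
    empirical census).  Members are streamed: only their 13-vectors are kept.
    ``census_fn`` may override the census (``graph -> TriadCensus``), at the
    cost of materializing each member as a graph.
    """
    adj0, nodelist = graph_to_arrays(g)
    mut0, asym0 = _arc_arrays(adj0)
    n_members = cfg.ensemble_size
    counts = np.zeros((n_members, 13), np.int64)
    acc_rates = np.zeros(n_members)
    n_aborted = 0
    trivial = mut0.shape[0] < 2 and asym0.shape[0] < 2
    for k in range(n_members):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, k]))
        adj = adj0.copy()
        if trivial:
            diag = {"acceptance_rate": 0.0, "aborted": False}
        else:
            diag = _rewire_arrays(adj, mut0.copy(), asym0.copy(), cfg, rng)
        if census_fn is None:
            counts[k] = census_from_adj(adj)
        else:
            member = nx.DiGraph()
            member.add_nodes_from(nodelist)
            iu, iv = np.nonzero(adj)
            member.add_edges_from(
                (nodelist[a], nodelist[b]) for a, b in zip(iu, iv)
            )
            counts[k] = census_fn(member).counts
        acc_rates[k] = diag["acceptance_rate"]
        n_aborted += diag["aborted"]
    diagnostics = {
        "mean_acceptance_rate": float(acc_rates.mean()),
        "n_aborted": int(n_aborted),
        "trivial": trivial,
        "seed": cfg.seed,
    }
    if trivial:
        logger.warning("no swappable arc pairs: ensemble members all equal the input")
    return EnsembleCensus(counts, diagnostics)
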