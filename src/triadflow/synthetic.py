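"""Synthetic flow tables and digraphs with the structure the analysis assumes.

Two families of fixtures are produced:

* graph generators (`gen_directed_er`, `gen_reciprocal_social`,
  `gen_layered_feedforward`) emit digraphs whose triad structure carries a
  known signature — reciprocity-neutral noise, clique-rich social closure
  ("a friend of a friend is also a friend"), and layered feed-forward
  (origin -> transit -> destination) enrichment respectively;

* flow-table generators (`gen_refugee_like_flows`, `gen_migrant_like_flows`)
  emit long-format weighted flow records emulating the two regimes the
  pipeline distinguishes: a fragmented, predominantly asymmetric,
  heavy-tailed, fast-churning network versus a single-component, dense,
  reciprocity-rich, temporally stable one.

All generators are pure functions of their parameters and seed.  The flow
generators are mechanism-inspired, not calibrated to any real dataset: they
reproduce the qualitative contrasts (reciprocity, fragmentation, stability)
directionally.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .flow_network import FlowTable

__all__ = [
    "SyntheticSpec",
    "refugee_spec",
    "migrant_spec",
    "gen_directed_er",
    "gen_reciprocal_social",
    "gen_layered_feedforward",
    "gen_refugee_like_flows",
    "gen_migrant_like_flows",
]


def _rng_of(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def country_codes(n: int) -> list:
    """Deterministic ISO-alpha-3-looking labels: AAA, AAB, AAC, ..."""
    letters = string.ascii_uppercase
    codes = []
    for triple in itertools.product(letters, repeat=3):
        codes.append("".join(triple))
        if len(codes) == n:
            return codes
    raise ValueError("too many nodes for 3-letter codes")


# ---------------------------------------------------------------------------
# graph generators
# ---------------------------------------------------------------------------

def gen_directed_er(
    n: int,
    p: float,
    reciprocity_bias: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> nx.DiGraph:
    """Directed Erdős–Rényi graph with tunable reciprocity.

    Every ordered pair gets an arc independently at rate ``p``; afterwards
    each asymmetric arc is reciprocated with probability ``reciprocity_bias``,
    raising the expected fraction of arcs in mutual dyads without touching
    the rest of the structure.  Nodes are ``0..n-1`` (isolates included).
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    rng = _rng_of(seed, rng)
    base = rng.random((n, n)) < p
    np.fill_diagonal(base, False)
    if reciprocity_bias > 0:
        asym = base & ~base.T
        add = asym & (rng.random((n, n)) < reciprocity_bias)
        base = base | add.T
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, np.argwhere(base)))
    return g


def gen_reciprocal_social(
    n: int = 80,
    mean_degree: float = 8.0,
    reciprocation_prob: float = 0.9,
    closure_prob: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> nx.DiGraph:
    """Growth process producing clique-rich, highly reciprocal graphs.

    Ties accumulate until the mean degree target is met; each new tie is
    reciprocated with ``reciprocation_prob`` and, with ``closure_prob``,
    chosen to close an open two-path (triadic closure) instead of landing on
    a uniformly random partner.  With both probabilities at 0 this collapses
    to a plain random asymmetric graph.
    """
    if n < 3 or mean_degree <= 0:
        raise ValueError("need n >= 3 and positive mean_degree")
    rng = _rng_of(seed, rng)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    und: list = [set() for _ in range(n)]
    target = int(round(n * mean_degree))
    attempts = 0
    while g.number_of_edges() < target and attempts < 60 * target:
        attempts += 1
        u = int(rng.integers(n))
        w = None
        if und[u] and rng.random() < closure_prob:
            nb = sorted(und[u])
            v = nb[rng.integers(len(nb))]
            nb2 = sorted(und[v] - {u})
            if nb2:
                w = nb2[rng.integers(len(nb2))]
        if w is None:
            w = int(rng.integers(n))
        if w == u or g.has_edge(u, w):
            continue
        g.add_edge(u, w)
        und[u].add(w)
        und[w].add(u)
        if not g.has_edge(w, u) and rng.random() < reciprocation_prob:
            g.add_edge(w, u)
    return g


def gen_layered_feedforward(
    n_layers: int = 3,
    per_layer: int = 25,
    p_forward: float = 0.15,
    p_skip: float = 0.55,
    p_reciprocate: float = 0.12,
    p_reciprocate_double: float = 0.06,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> nx.DiGraph:
    """Layered transit digraph enriched in feed-forward triads.

    Forward arcs run from layer l to l+1 (each pair at rate ``p_forward``).
    Skip arcs run from l to l+2, but only along *realized* transit routes:
    each two-path u -> v -> w is closed by a direct arc u -> w with
    probability ``p_skip`` (an established corridor acquires a direct
    connection), which is exactly what makes the feed-forward triad — not
    mere degree structure — abundant.  Return ties are then laid down inside
    feed-forward triads: per triad, the first leg is reciprocated with
    probability ``p_reciprocate`` (yielding the mutual-pair-feeding class,
    type 10) or both legs with ``p_reciprocate_double``, so mutual dyads sit
    in closed neighbourhoods rather than dangling.  With ``p_skip = 0`` no
    feed-forward triad can form at all.
    """
    if n_layers < 3:
        raise ValueError("need at least 3 layers")
    rng = _rng_of(seed, rng)
    g = nx.DiGraph()
    n = n_layers * per_layer
    g.add_nodes_from(range(n))
    layer = lambda l: range(l * per_layer, (l + 1) * per_layer)  # noqa: E731
    for l in range(n_layers - 1):
        for u in layer(l):
            for v in layer(l + 1):
                if rng.random() < p_forward:
                    g.add_edge(u, v)
    for l in range(n_layers - 2):
        for u in layer(l):
            for v in list(g.successors(u)):
                if v // per_layer != l + 1:
                    continue
                for w in list(g.successors(v)):
                    if w // per_layer != l + 2:
                        continue
                    if not g.has_edge(u, w) and rng.random() < p_skip:
                        g.add_edge(u, w)
    if p_reciprocate > 0 or p_reciprocate_double > 0:
        ffls = []
        for u, v in sorted(g.edges):
            for w in sorted(set(g.successors(v)) & set(g.successors(u))):
                ffls.append((u, v, w))
        for u, v, w in ffls:
            r = rng.random()
            if r < p_reciprocate:
                g.add_edge(v, u)
            elif r < p_reciprocate + p_reciprocate_double:
                g.add_edge(v, u)
                g.add_edge(w, v)
    return g


# ---------------------------------------------------------------------------
# flow-table generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic flow-network series.

    ``mean_degree`` sets the within-component arc count target; ``reciprocity``
    is the probability a fresh arc is immediately reciprocated; ``closure``
    the probability a fresh arc closes an open two-path instead of landing on
    a random partner (community structure — mutual ties clustering into
    cliques); ``closure_reciprocity`` optionally overrides ``reciprocity``
    for closure-placed ties (community ties reciprocate more than long-range
    ones); ``persistence`` the probability an arc (with its flow) survives
    into the next period; ``reciprocity_drift`` the per-period probability an
    asymmetric arc gains a return flow (mutual density rising over time).
    Period flows are log-normal, ``exp(N(flow_mu, flow_sigma))`` people per
    period, fixed at arc birth; ``subthreshold_rate`` adds that fraction of
    extra one-period arcs with flows strictly below 100/year, so thresholding
    is a non-trivial filter.
    """

    n_nodes: int
    n_periods: int
    mean_degree: float
    reciprocity: float
    flow_mu: float
    flow_sigma: float
    persistence: float
    n_components: int = 1
    component_weights: tuple | None = None
    subthreshold_rate: float = 0.3
    reciprocity_drift: float = 0.0
    closure: float = 0.0
    closure_reciprocity: float | None = None
    span: int = 1
    start_year: int = 1990
    seed: int = 0

    def __post_init__(self):
        for name in (
            "reciprocity", "persistence", "subthreshold_rate",
            "reciprocity_drift", "closure", "closure_reciprocity",
        ):
            value = getattr(self, name)
            if value is not None and not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_nodes < 2 * self.n_components or self.n_components < 1:
            raise ValueError("components need at least 2 nodes each")


def refugee_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Fragmented, asymmetric, fast-churning annual series (refugee-like)."""
    spec = SyntheticSpec(
        n_nodes=60,
        n_periods=10,
        mean_degree=4.0,
        reciprocity=0.1,
        flow_mu=math.log(300.0),
        flow_sigma=1.2,
        persistence=0.3,
        n_components=4,
        component_weights=(0.4, 0.25, 0.2, 0.15),
        subthreshold_rate=0.4,
        span=1,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def migrant_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Single-component, reciprocal, stable 5-year series (migrant-like)."""
    spec = SyntheticSpec(
        n_nodes=150,
        n_periods=6,
        mean_degree=8.0,
        reciprocity=0.4,
        flow_mu=math.log(3000.0),
        flow_sigma=1.5,
        persistence=0.95,
        n_components=1,
        subthreshold_rate=0.3,
        reciprocity_drift=0.12,
        closure=0.6,
        closure_reciprocity=1.0,
        span=5,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def _blocks(spec: SyntheticSpec, codes: list) -> list:
    """Partition node labels into the spec's weakly-connected blocks."""
    k = spec.n_components
    w = np.asarray(spec.component_weights or [1.0 / k] * k, dtype=float)
    if len(w) != k:
        raise ValueError("component_weights length must equal n_components")
    w = w / w.sum()
    sizes = np.maximum(2, np.floor(w * spec.n_nodes).astype(int))
    while sizes.sum() > spec.n_nodes:
        sizes[int(np.argmax(sizes))] -= 1
    sizes[0] += spec.n_nodes - sizes.sum()
    out, at = [], 0
    for s in sizes:
        out.append(codes[at : at + int(s)])
        at += int(s)
    return out


def _draw_flow(spec: SyntheticSpec, rng) -> int:
    return max(1, int(round(math.exp(rng.normal(spec.flow_mu, spec.flow_sigma)))))


def _grow_block_arcs(spec, rng, block, arcs):
    """Top ``arcs`` up to the block's arc-count target.

    New ties land with probability ``spec.closure`` on the far end of an open
    two-path through the block's *mutual* ties (friend-of-a-friend closure in
    the reciprocated sense, clustering mutual dyads into cliques) and are
    immediately reciprocated with probability ``spec.reciprocity`` —
    ``spec.closure_reciprocity`` for closure-placed ties.
    """
    members = set(block)
    nb = len(block)
    target = int(round(nb * spec.mean_degree))
    count = sum(1 for (u, v) in arcs if u in members)
    und = {n: set() for n in block}
    for u, v in arcs:
        if u in members and (v, u) in arcs:
            und[u].add(v)
    attempts = 0
    while count < target and attempts < 60 * target:
        attempts += 1
        u = block[int(rng.integers(nb))]
        w = None
        via_closure = False
        if und[u] and rng.random() < spec.closure:
            nb1 = sorted(und[u])
            v = nb1[rng.integers(len(nb1))]
            nb2 = sorted(und[v] - {u})
            if nb2:
                w = nb2[rng.integers(len(nb2))]
                via_closure = True
        if w is None:
            w = block[int(rng.integers(nb))]
        if w == u or (u, w) in arcs:
            continue
        arcs[(u, w)] = _draw_flow(spec, rng)
        count += 1
        p_rec = spec.reciprocity
        if via_closure and spec.closure_reciprocity is not None:
            p_rec = spec.closure_reciprocity
        if (w, u) in arcs:
            und[u].add(w)
            und[w].add(u)
        elif rng.random() < p_rec:
            arcs[(w, u)] = _draw_flow(spec, rng)
            und[u].add(w)
            und[w].add(u)
            count += 1


def _evolve_flows(spec: SyntheticSpec) -> FlowTable:
    """Shared temporal mechanism behind both flow-table generators."""
    rng = np.random.default_rng(spec.seed)
    codes = country_codes(spec.n_nodes)
    blocks = _blocks(spec, codes)
    arcs: dict = {}
    records = []
    sub_cutoff = 100 * spec.span  # noise flows sit strictly below 100/year
    for t in range(spec.n_periods):
        period = spec.start_year + spec.span * t
        if t > 0:
            arcs = {a: f for a, f in arcs.items() if rng.random() < spec.persistence}
        for block in blocks:
            _grow_block_arcs(spec, rng, block, arcs)
        if t > 0 and spec.reciprocity_drift > 0:
            for (u, v) in list(arcs):
                if (v, u) not in arcs and rng.random() < spec.reciprocity_drift:
                    arcs[(v, u)] = _draw_flow(spec, rng)
        for (u, v), f in arcs.items():
            records.append((u, v, period, f))
        # one-period sub-threshold noise arcs, within blocks
        n_noise = int(round(spec.subthreshold_rate * len(arcs)))
        placed = 0
        guard = 0
        noise_pairs: set = set()
        while placed < n_noise and guard < 20 * n_noise:
            guard += 1
            block = blocks[int(rng.integers(len(blocks)))]
            i, j = rng.integers(0, len(block), size=2)
            u, v = block[int(i)], block[int(j)]
            if u == v or (u, v) in arcs or (u, v) in noise_pairs:
                continue
            noise_pairs.add((u, v))
            records.append((u, v, period, int(rng.integers(1, sub_cutoff))))
            placed += 1
    df = pd.DataFrame(records, columns=["origin", "destination", "period", "flow"])
    df = (
        df.groupby(["origin", "destination", "period"], as_index=False)["flow"]
        .sum()
        .sort_values(["period", "origin", "destination"], ignore_index=True)
    )
    return FlowTable(df, span=spec.span)


def gen_refugee_like_flows(spec: SyntheticSpec | None = None, seed: int = 0) -> FlowTable:
    """Fragmented, low-reciprocity annual flow series.

    Defaults (see :func:`refugee_spec`): 4 disjoint blocks, ~10% immediate
    reciprocation, heavy-tailed flows straddling the 100/year threshold, and
    weak arc persistence — the thresholded graphs stay fragmented and churn
    from year to year.
    """
    spec = spec or refugee_spec(seed)
    return _evolve_flows(spec)


def gen_migrant_like_flows(spec: SyntheticSpec | None = None, seed: int = 0) -> FlowTable:
    """Single-component, reciprocity-rich, stable 5-year flow series.

    Defaults (see :func:`migrant_spec`): one dense block, ~55% immediate
    reciprocation with an upward drift (mutual density rises across periods),
    95% arc persistence, and flows well above the 500-per-period cutoff for
    most arcs.
    """
    spec = spec or migrant_spec(seed)
    return _evolve_flows(spec)
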