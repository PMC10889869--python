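# Methods

## The statistic

`triadflow` measures the higher-order structure of directed flow networks
through the **triad significance profile (TSP)**.  A triad is a set of three
nodes together with all arcs among them; for simple digraphs there are 16
isomorphism classes of three-node subgraphs, 13 of them weakly connected.
The package counts induced occurrences of each connected class i (so the 13
counts partition the connected triples) and scores them against a randomized
ensemble:

    Z_i = (n_i,E − ⟨n_i,R⟩) / σ_i,R
    z_i = Z_i / (Σ_j Z_j²)^½

where n_i,E is the empirical count and ⟨n_i,R⟩, σ_i,R are the mean and
(population, ddof = 0) standard deviation of the count across an ensemble of
rewired networks — 200 members by default.  The unit-norm vector z is the
TSP; its sign pattern, not its magnitude, carries the signal.  Networks with
similar TSP shapes form *superfamilies*: social-type networks over-represent
the fully reciprocated clique triad (class 13) and under-represent the
"frustration" triad (class 6, two mutual dyads with an open third pair);
information-processing networks over-represent the feed-forward classes
(7 and its reciprocated variant 10) and under-represent classes 1–6.

Class indices follow the standard significance-profile glyph order.  The
catalog (one source-of-truth table in `triads.py`, with Holland–Leinhardt
MAN codes for interoperability) is: 1 divergent (021D), 2 convergent (021U),
3 chain (021C), 4/5 single-mutual two-arc classes (111D/111U),
6 frustration (201), 7 feed-forward (030T), 8 cycle (030C), 9–11 the
single-mutual three-arc classes (120D/120U/120C), 12 near-clique (210),
13 clique (300).

## The null model

The reference ensemble preserves, per node, the in-degree, the out-degree,
and the counts of incident mutual and asymmetric arcs.  It is generated by
cut-and-swap switching: repeatedly pick two arcs of the same dyadic type
(both asymmetric or both mutual dyads), cut them and swap their endpoints;
reject any proposal that would create a self-loop, duplicate an arc, or
change a dyad's type.  The proposal kind is drawn proportionally to the arc
mass in each category (2M vs A).  The chain runs `attempts_per_arc` (default
100) proposals per arc, so even a few-hundred-arc network receives tens of
thousands of switches — far past the observable mixing point at these sizes
(a graph drawn from the null and scored against a fresh ensemble shows
median |Z| well below 1).  Acceptance rates are recorded so pathologically
constrained graphs are visible; a graph with no swappable pair at all is
returned unchanged with a warning flag.

Ensemble member k draws its randomness from the numpy child stream
`SeedSequence([seed, k])`, so ensembles are reproducible and parallelizable.
Rewired members are censused whole, even if switching fragments them,
preserving node/arc comparability with the empirical census.

Degenerate classes (σ_i = 0) score Z_i = 0 when the empirical count equals
the constant ensemble count, otherwise sign × cap (default 10) with a
`capped` flag — profiles stay finite while degeneracy is loudly marked.

## Census algorithms

The production census walks connected triples through the adjacency
structure: every support (undirected) edge proposes the triples through its
endpoints' neighbourhoods, and a triple is classified only from its
lexicographically smallest support edge, so each connected triple is
visited once and the C(N,3) triple space is never materialized.  Triple
classification is a 64-entry table lookup on the 6-bit arc code; the table
is built at import time from the catalog by explicit isomorphism matching.
The hot loops (census and switching) are numba-jitted; all randomness is
pre-drawn with numpy Generators outside the kernels.

Two independent checks guard the census: a pure-Python O(N³) brute-force
oracle (`census_bruteforce`, capped at 60 nodes) classifying every triple
through `canonical_triad_class`, and networkx's 16-class `triadic_census`
mapped through the MAN codes.  The test suite requires exact agreement of
all three on random graphs spanning sparse/dense and low/high reciprocity.

## Flow-network pipeline

Input is a long-format CSV of weighted directed flows (origin, destination,
year, count).  Normalization drops self-flows and sums duplicate keys;
annual records can be aggregated into half-open 5-year bins anchored at a
configurable window start (default 1990).  The topological analysis uses
unweighted graphs obtained by an **inclusive** threshold of
`min_flow_per_year × span` (default 100/year, hence a 500 cutoff on 5-year
bins): an arc surviving the threshold enters the graph, isolated nodes do
not.  Node counts and dyad densities therefore refer to nodes actually
involved in above-threshold flows in that period.

Low-order structure is reported per period: the dyad decomposition — M
mutual and A asymmetric pairs out of N(N−1)/2, densities m, a, and m + a —
and the weak-component structure (weak connectivity is the right notion
here: predominantly asymmetric flow networks have near-trivial strong
components).  Components are ordered by size, then total internal flow, then
smallest node label, and the per-component share of total flow weight is
recorded.  When a period's graph is fragmented the TSP is computed on the
largest weak component only (configurable: `auto`/`always`/`never`); the
ensemble rewires that component, never a re-extracted sub-component.

Superfamily calls apply the sign patterns above with a dead-band
|z_i| ≥ 0.05 so noise is never read as over/under-representation.  The two
patterns are not mutually exclusive: any clustered reciprocal network also
mildly enriches the feed-forward classes, so a profile can satisfy both sets
of necessary conditions.  When that happens the call goes to the clearly
dominant signature — the weakest supporting score (social: min(z13, −z6);
information-processing: min(z7, z10)) must be at least twice the rival's —
and is `indeterminate` when the two are comparable.  This keeps textbook
clique-dominated profiles from being vetoed by an incidental feed-forward
co-match while still refusing genuinely ambiguous profiles.  Optional
user-supplied reference profiles are compared by Pearson correlation; no
literature reference vectors are hard-coded.

Exemplar triads — the concrete country triples behind an over-represented
class — are extracted per class by maximum total arc weight, with
deterministic tie-breaking on sorted node labels.  The default selection
rule is z_i ≥ 0.1 (configurable); it is a package convention, not an
empirical constant.

Every run writes tidy CSV/JSON tables plus a manifest (seed, config hash —
excluding the output directory — and library versions).  A run is a pure
function of (input, config, seed): re-running reproduces every output file
byte for byte.

## Synthetic data

No real mobility data ship with the package; generators reproduce the
*mechanisms* the analysis is sensitive to, so what the tests demonstrate is
that the machinery detects those mechanisms — not that any real network has
them.

* `gen_directed_er(n, p, reciprocity_bias)` — independent arcs, then each
  asymmetric arc reciprocated with the bias probability.  The neutral
  fixture: its profiles are unit-norm noise, and its superfamily call is
  mostly indeterminate (a random direction on the 13-sphere still crosses a
  0.05 dead-band with random signs, so chance matches occur in a minority of
  seeds — the battery test asserts the modal call, not a rate).
* `gen_reciprocal_social(n=80, mean_degree=8, reciprocation_prob=0.9,
  closure_prob=0.5)` — growth with immediate reciprocation and triadic
  closure; clique-rich by construction.  Mean degree 8 is a typical
  social-network value.
* `gen_layered_feedforward(3 layers × 25, p_forward=0.15, p_skip=0.55,
  p_reciprocate=0.12, p_reciprocate_double=0.06)` — forward arcs between
  adjacent layers; skip arcs close *realized* two-paths (an established
  origin→transit→destination corridor acquires a direct link), which is what
  enriches the feed-forward triad against a degree-preserving null; return
  ties are laid inside feed-forward triads (first leg → class 10, both
  legs → class 12) so mutual dyads sit in closed neighbourhoods.  A purely
  pair-probability layered model does not work: at workable densities the
  degree-preserving null closes two-paths more often than random skip arcs
  do, and intra-layer star pairs are never closed empirically, so classes
  1–3 come out over-represented — the closure-targeted mechanism is what
  makes the information-processing signature expressible.  Three layers keep
  every two-path closable (with more layers, skip+forward chains two layers
  long are unclosable and inflate the chain class).
* `gen_refugee_like_flows` / `gen_migrant_like_flows` — temporal flow-table
  series built on one mechanism with two presets.  Arcs live inside
  prescribed weakly-connected blocks (4 blocks for the refugee preset, 1 for
  the migrant), grow to a mean-degree target, persist to the next period
  with probability `persistence` (0.3 refugee, 0.95 migrant), and carry
  log-normal flows fixed at arc birth (median 300/year, σ=1.2 refugee;
  median 3000/5 years, σ=1.5 migrant — heavy tails straddling the threshold,
  so thresholding is a real filter), plus a fraction of strictly
  sub-threshold one-period noise arcs.  New ties reciprocate immediately
  with probability `reciprocity` (0.1 refugee, 0.4 migrant); in the migrant
  preset new ties additionally close open two-paths through *mutual* ties
  (closure 0.6) and closure-placed ties always reciprocate — community
  structure in the reciprocated sense, which is what produces the social
  z13/z6 signature (plain reciprocity without closure measurably does not).
  A per-period drift reciprocates 12% of asymmetric arcs, so mutual density
  rises over the series.  What these generators do **not** emulate: real
  marginals (country sizes, flow magnitudes), geography, covariate-driven
  dynamics, or cross-component flows; conclusions about real UNDESA/UNHCR
  data require running the pipeline on those data.

## Problem sizes and numerical choices

Default study conditions: 200-member ensembles at 100 swap attempts per arc;
signature batteries use 20 seeded replicates (80-node social graphs,
75-node layered graphs); null recovery uses 20 replicates of a 100-node
graph; flow series use 60 nodes × 10 annual periods (refugee-like) and
150 nodes × 6 five-year periods (migrant-like).  These sizes give stable
sign statistics for desk-scale experimentation; everything scales through
configuration.  Normalization is exact (unit norm verified to 1e−12);
censuses and dyad counts are integer-exact; the only stochastic quantities
are ensemble means/σ and anything downstream of them.  Degenerate inputs
(fewer than 3 nodes, no connected triple, no swappable pair) yield flagged
zero results rather than errors, so fragmented periods degrade gracefully.

## Known limitations

* Adjacency is held as a dense boolean matrix inside the kernels — right for
  country-scale networks (N ≲ a few thousand), wrong for million-node
  graphs.
* The switching chain's mixing is assessed empirically (null
  self-consistency), not proven; `attempts_per_arc` is a documented stand-in
  for "until thoroughly rewired".
* Superfamily calls are rule-based sign reads with a fixed dead-band; they
  classify clear profiles and refuse ambiguous ones, but they are not a
  statistical test, and only the two patterns the package targets are
  built in.
* Period spans other than 1 and 5 years are not supported by `FlowTable`.
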