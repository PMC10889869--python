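# triadflow

Triad significance profiles for directed flow networks — built for weighted
origin→destination flow tables such as international migrant and refugee
flows, where nodes are countries and an arc means people moved.

Low-order properties (density, degree, reciprocity) miss what three-node
structure reveals: whether a network closes triangles into reciprocated
cliques the way social systems do, or routes flows through feed-forward
origin→transit→destination patterns the way information-processing systems
(including many biological networks) do.  `triadflow` measures exactly that.

## The statistic

Connected three-node subgraphs of a simple digraph fall into 13 isomorphism
classes.  For a network of interest, the count n<sub>i,E</sub> of each class
*i* is compared with its distribution over an ensemble of randomized
networks (200 by default) that preserve every node's in-degree, out-degree,
and incident mutual/asymmetric arc counts (cut-and-swap rewiring of
same-type arc pairs):

> Z<sub>i</sub> = (n<sub>i,E</sub> − ⟨n<sub>i,R</sub>⟩) / σ<sub>i,R</sub>,  z<sub>i</sub> = Z<sub>i</sub> / (Σ<sub>j</sub> Z<sub>j</sub>²)<sup>½</sup>

The unit-norm vector **z** is the triad significance profile (TSP).  Its
sign pattern assigns the network to a superfamily: over-represented clique
(class 13) with under-represented "frustration" (class 6) reads *social*;
over-represented feed-forward classes (7, 10) with classes 1–6 suppressed
reads *information-processing*.

The pipeline around the statistic handles the flow-data realities: weighted
long-format CSV ingestion, aggregation of annual flows to 5-year bins, an
inclusive threshold of 100 people/year (500 per 5-year bin) to keep only
substantial flows, dyad densities and fragmentation reports, automatic
largest-component extraction for fragmented periods, and exemplar-triad
extraction (the concrete highest-volume triples behind an over-represented
class).  See `docs/methods.md` for the full model description.

## Worked example

No real mobility data are bundled; the `simulate` subcommand writes
synthetic flow series with controlled structure (see `docs/methods.md` for
what they do and do not emulate).  A stable, reciprocity-rich,
closure-driven "migrant-like" series, end to end:

```
$ triadflow simulate --preset migrant --seed 0 -o migrant.csv
wrote migrant series: 9644 records, 6 period(s), span 5 -> migrant.csv

$ triadflow report --input migrant.csv --span 5 --seed 10 --outdir bundle
{"superfamily": {"1990": "social", "1995": "social", "2000": "social",
 "2005": "social", "2010": "social", "2015": "social"},
 "config_hash": "f5566c2ae8f4a21f"}
```

`bundle/` now holds tidy per-stage tables (`dyads.csv`, `components.csv`,
`census.csv`, `tsp.csv`, `exemplars.csv`, `volume_vs_edges.csv`,
`superfamily.json`) plus a `manifest.json` that makes the run reproducible
bit for bit.  The profile columns that drive the call:

```
 period    z6   z7  z13
   1990 -0.67 0.01 0.63
   1995 -0.65 0.06 0.58
   2000 -0.60 0.04 0.48
   2005 -0.58 0.04 0.46
   2010 -0.52 0.11 0.37
   2015 -0.49 0.15 0.38
```

Every period over-represents the clique triad (z13 ≫ 0) and suppresses the
frustration triad (z6 ≪ 0) relative to the degree- and
reciprocity-preserving null — the social-superfamily signature.  The
fragmented, asymmetric, fast-churning counterpart is
`--preset refugee`; scored per period on its largest weak component it
trends toward the feed-forward side instead.

The same stages are available as library functions:

```python
import triadflow as tf

g = tf.gen_reciprocal_social(n=80, seed=0)          # clique-rich fixture
profile = tf.compute_tsp(g, tf.RewireConfig(seed=1000))
print(profile.z.round(2)[[5, 6, 12]])                # z6, z7, z13
# [-0.61 -0.02  0.58]
print(tf.classify_superfamily(profile).label)
# social
```

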