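"""Triad significance profiles and superfamily classification.

For each connected triad class i, the raw score compares the empirical count
n_i with its distribution across the rewired ensemble,

    Z_i = (n_{i,E} - <n_{i,R}>) / sigma_{i,R},

and the profile is the unit-norm rescaling z_i = Z_i / (sum_j Z_j^2)^{1/2}.
The *shape* of z over the 13 classes — which classes are over- and which
under-represented — is what places a network in a superfamily: social-like
networks over-represent the fully reciprocated clique triad (type 13) and
under-represent the "frustration" triad (type 6); information-processing
networks over-represent the feed-forward classes (types 7 and 10) while
under-representing all of types 1-6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .null_ensemble import EnsembleCensus, RewireConfig, ensemble_census
from .triads import TRIAD_CATALOG, TriadCensus, census, iter_connected_triples

__all__ = [
    "TSProfile",
    "SuperfamilyCall",
    "ExemplarTriad",
    "z_scores",
    "normalize_profile",
    "compute_tsp",
    "classify_superfamily",
    "exemplar_triads",
    "profile_table",
]

logger = logging.getLogger(__name__)

#: default |Z| assigned when sigma = 0 but the empirical count deviates
SIGMA_ZERO_CAP = 10.0


@dataclass
class TSProfile:
    """A network's triad significance profile and its ingredients."""

    period: object
    counts: np.ndarray  # empirical 13-vector n_{i,E}
    Z: np.ndarray
    z: np.ndarray
    ensemble_mean: np.ndarray
    ensemble_sd: np.ndarray
    #: per-class marker sets; possible markers: sd_zero, capped, zero_profile,
    #: too_small (graph had no connected triple)
    flags: list = field(default_factory=lambda: [set() for _ in range(13)])

    def flagged(self, marker: str) -> list:
        """Class indices (1..13) carrying ``marker``."""
        return [i + 1 for i, f in enumerate(self.flags) if marker in f]


def z_scores(
    empirical: TriadCensus | np.ndarray,
    ens: EnsembleCensus,
    cap: float = SIGMA_ZERO_CAP,
):
    """Raw scores Z_i against the ensemble, with the sigma=0 convention.

    Where the ensemble is degenerate (sigma_i = 0): Z_i = 0 if the empirical
    count equals the constant ensemble count, else sign(n_E - mean) * cap,
    flagged ``capped``.  Returns ``(Z, flags)``.
    """
    counts = empirical.counts if isinstance(empirical, TriadCensus) else np.asarray(empirical)
    mean = ens.mean
    sd = ens.sd
    Z = np.zeros(13)
    flags = [set() for _ in range(13)]
    for i in range(13):
        dev = counts[i] - mean[i]
        if sd[i] > 0:
            Z[i] = dev / sd[i]
        else:
            flags[i].add("sd_zero")
            if dev != 0:
                Z[i] = np.sign(dev) * cap
                flags[i].add("capped")
    return Z, flags


def normalize_profile(Z: np.ndarray):
    """Rescale to the unit-norm profile z = Z / ||Z||.

    A zero Z-vector maps to the zero profile with a ``zero_profile`` flag on
    every class (the graph is indistinguishable from its own null).
    Returns ``(z, flags)``.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z must be finite")
    norm = float(np.sqrt((Z**2).sum()))
    flags = [set() for _ in range(13)]
    if norm == 0.0:
        for f in flags:
            f.add("zero_profile")
        return np.zeros_like(Z), flags
    return Z / norm, flags


def compute_tsp(
    g: nx.DiGraph,
    cfg: RewireConfig,
    period: object = None,
    cap: float = SIGMA_ZERO_CAP,
) -> TSProfile:
    """Full profile of a graph: census -> null ensemble -> Z -> z.

    ``g`` is expected to be the analysis graph (the pipeline reduces a
    fragmented network to its largest weak component before calling this).
    All intermediates are recorded on the returned profile.
    """
    emp = census(g)
    if emp.too_small or emp.n_connected_triples == 0:
        flags = [{"too_small"} for _ in range(13)]
        zeros = np.zeros(13)
        logger.warning("graph has no connected triple; profile is all-zero")
        return TSProfile(period, emp.counts, zeros, zeros.copy(), zeros.copy(), zeros.copy(), flags)
    ens = ensemble_census(g, cfg)
    Z, zflags = z_scores(emp, ens, cap=cap)
    z, nflags = normalize_profile(Z)
    flags = [a | b for a, b in zip(zflags, nflags)]
    return TSProfile(period, emp.counts.copy(), Z, z, ens.mean, ens.sd, flags)


@dataclass
class SuperfamilyCall:
    """Outcome of matching a profile against the superfamily sign patterns."""

    label: str  # social | information-processing | indeterminate | user-reference:<name>
    evidence: dict
    correlation: float | None = None


def classify_superfamily(
    p: TSProfile,
    refs: dict | None = None,
    z_min: float = 0.05,
) -> SuperfamilyCall:
    """Read the superfamily from the profile's sign pattern.

    A sign only counts when |z_i| >= ``z_min`` (dead-band; keeps noise from
    being read as over/under-representation).  Patterns:

    * social: z13 positive and z6 negative;
    * information-processing: z7 and z10 positive, z1..z6 all negative.

    Neither matching yields ``indeterminate``.  The patterns are not mutually
    exclusive — clustered reciprocal networks enrich the feed-forward classes
    mildly too — so when both match, the call goes to the clearly dominant
    signature (weakest supporting score at least twice the rival's; the
    clique class z13 vs the feed-forward classes z7/z10 is what genuinely
    separates the two superfamilies) and is ``indeterminate`` only when the
    two are comparable.  When reference profiles are supplied (name ->
    13-vector), the best Pearson match is reported, and names an otherwise
    indeterminate profile.
    """
    z = p.z
    pos = z >= z_min
    neg = z <= -z_min
    social = bool(pos[12] and neg[5])
    info = bool(pos[6] and pos[9] and neg[0:6].all())
    evidence = {
        "z13_over": bool(pos[12]),
        "z6_under": bool(neg[5]),
        "z7_over": bool(pos[6]),
        "z10_over": bool(pos[9]),
        "z1_6_under": bool(neg[0:6].all()),
        "social_pattern": social,
        "information_processing_pattern": info,
    }
    if social and info:
        strength_social = min(z[12], -z[5])
        strength_info = min(z[6], z[9])
        evidence["social_strength"] = float(strength_social)
        evidence["information_processing_strength"] = float(strength_info)
        if strength_social >= 2 * strength_info:
            label = "social"
        elif strength_info >= 2 * strength_social:
            label = "information-processing"
        else:
            label = "indeterminate"
    elif social:
        label = "social"
    elif info:
        label = "information-processing"
    else:
        label = "indeterminate"
    correlation = None
    if refs:
        best, best_r = None, -np.inf
        for name in sorted(refs):
            ref = np.asarray(refs[name], dtype=float)
            if ref.shape != (13,):
                raise ValueError(f"reference {name!r} must be a 13-vector")
            r = float(np.corrcoef(z, ref)[0, 1])
            if r > best_r:
                best, best_r = name, r
        correlation = best_r
        evidence["best_reference"] = best
        if label == "indeterminate":
            label = f"user-reference:{best}"
    return SuperfamilyCall(label, evidence, correlation)


@dataclass(frozen=True)
class ExemplarTriad:
    """A concrete triad of a given class, ranked by its flow volume."""

    class_index: int
    nodes: tuple  # in canonical role order for the class
    roles: tuple
    volume: float


_ROLE_NAMES = {
    7: ("origin", "transit", "destination"),
    10: ("origin", "transit", "destination"),
    11: ("origin", "destination", "transit"),
}


def _role_order(g: nx.DiGraph, triple, cls: int):
    """Permute ``triple`` onto the catalog representative of ``cls``."""
    import itertools

    rep = TRIAD_CATALOG[cls - 1].arcs
    for perm in itertools.permutations(triple):
        pos = {n: i for i, n in enumerate(perm)}
        arcs = {
            (pos[u], pos[v])
            for u in triple
            for v in triple
            if u != v and g.has_edge(u, v)
        }
        if arcs == rep:
            return perm
    raise AssertionError("triple does not belong to the stated class")


def exemplar_triads(
    g: nx.DiGraph, classes, top_k: int = 1
) -> dict:
    """Highest-volume concrete triads per requested class.

    Volume is the sum of flow weights on the triad's induced arcs; ``g`` must
    carry a ``weight`` on every arc.  Returns ``{class_index: [ExemplarTriad,
    ...]}``, each list sorted by descending volume (ties broken on the sorted
    node labels); classes absent from the graph map to empty lists.
    """
    classes = set(classes)
    if not classes:
        raise ValueError("no triad classes requested")
    found = {c: [] for c in classes}
    for triple, cls in iter_connected_triples(g):
        if cls not in classes:
            continue
        volume = 0.0
        for u in triple:
            for v in triple:
                if u != v and g.has_edge(u, v):
                    w = g[u][v].get("weight")
                    if w is None:
                        raise ValueError("exemplar search needs arc weights")
                    volume += w
        ordered = _role_order(g, triple, cls)
        found[cls].append(
            ExemplarTriad(cls, ordered, _ROLE_NAMES.get(cls, ("a", "b", "c")), volume)
        )
    out = {}
    for c in sorted(classes):
        ranked = sorted(
            found[c], key=lambda t: (-t.volume, tuple(repr(n) for n in sorted(t.nodes, key=repr)))
        )
        out[c] = ranked[:top_k]
    return out


def profile_table(profiles) -> pd.DataFrame:
    """Long-format table (period, triad_type, z) over a collection of profiles.

    One row per (profile, class); feeds box-plot style summaries (median,
    quartiles per class across periods).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    rows = [
        {"period": p.period, "triad_type": i + 1, "z": float(p.z[i])}
        for p in profiles
        for i in range(13)
    ]
    return pd.DataFrame(rows, columns=["period", "triad_type", "z"])
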