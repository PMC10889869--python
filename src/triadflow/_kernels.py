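"""Numba-jitted inner loops for the census and the edge-switching chain.

All randomness is pre-drawn with numpy Generators by the callers; the kernels
consume index arrays, so seeding semantics are pure numpy end to end.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["census_kernel", "rewire_kernel"]


@njit(cache=True)
def census_kernel(adj, edges, indptr, indices, table):
    """Count connected triples, classified through ``table``.

    adj      : (n, n) bool adjacency matrix of the digraph.
    edges    : (E, 2) int64 support (undirected) edges with u < v.
    indptr, indices : CSR adjacency of the support graph.
    table    : (64,) int8 mapping the 6-bit arc code of an ordered triple
               a < b < c to a class index 1..13 (0 = disconnected).

    Each connected triple is visited from every support edge it contains but
    counted only from its lexicographically smallest one.
    """
    counts = np.zeros(14, np.int64)
    for e in range(edges.shape[0]):
        u = edges[e, 0]
        v = edges[e, 1]
        for src in range(2):
            base = u if src == 0 else v
            for k in range(indptr[base], indptr[base + 1]):
                w = indices[k]
                if w == u or w == v:
                    continue
                uw = adj[u, w] or adj[w, u]
                if src == 1 and uw:
                    continue  # already visited from u's neighbour list
                ok = True
                if uw:
                    x = u if u < w else w
                    y = w if u < w else u
                    if x < u or (x == u and y < v):
                        ok = False
                if ok and (adj[v, w] or adj[w, v]):
                    x = v if v < w else w
                    y = w if v < w else v
                    if x < u or (x == u and y < v):
                        ok = False
                if not ok:
                    continue
                # sort the triple
                a = u
                b = v
                c = w
                if c < a:
                    a, c = c, a
                if b < a:
                    a, b = b, a
                if c < b:
                    b, c = c, b
                code = 0
                if adj[a, b]:
                    code += 1
                if adj[b, a]:
                    code += 2
                if adj[a, c]:
                    code += 4
                if adj[c, a]:
                    code += 8
                if adj[b, c]:
                    code += 16
                if adj[c, b]:
                    code += 32
                counts[table[code]] += 1
    return counts


@njit(cache=True)
def rewire_kernel(adj, asym, mut, kinds, ia, im, flips, max_consec):
    """Run the cut-and-swap chain in place.

    adj   : (n, n) bool adjacency, mutated.
    asym  : (A, 2) int64 asymmetric arcs (tail, head), mutated.
    mut   : (M, 2) int64 mutual dyads (either orientation), mutated.
    kinds : (T,) uint8, 0 = asymmetric proposal, 1 = mutual proposal.
    ia/im : (T, 2) pre-drawn candidate indices into asym / mut.
    flips : (T, 2) pre-drawn orientation bits for mutual proposals.

    A proposal is rejected (chain state untouched) whenever it would create a
    self-loop, duplicate an existing arc, or convert a dyad's type.  Returns
    (accepted_asym, attempted_asym, accepted_mut, attempted_mut, aborted).
    """
    acc_a = 0
    att_a = 0
    acc_m = 0
    att_m = 0
    consec = 0
    aborted = False
    for t in range(kinds.shape[0]):
        if consec >= max_consec:
            aborted = True
            break
        if kinds[t] == 0:
            att_a += 1
            i = ia[t, 0]
            j = ia[t, 1]
            if i == j:
                consec += 1
                continue
            u = asym[i, 0]
            v = asym[i, 1]
            x = asym[j, 0]
            y = asym[j, 1]
            # new arcs u->y, x->v; reject self-loops, duplicates, minted mutuals
            if u == y or x == v or adj[u, y] or adj[x, v] or adj[y, u] or adj[v, x]:
                consec += 1
                continue
            adj[u, v] = False
            adj[x, y] = False
            adj[u, y] = True
            adj[x, v] = True
            asym[i, 1] = y
            asym[j, 1] = v
            acc_a += 1
            consec = 0
        else:
            att_m += 1
            i = im[t, 0]
            j = im[t, 1]
            if i == j:
                consec += 1
                continue
            fi = flips[t, 0]
            fj = flips[t, 1]
            u = mut[i, fi]
            v = mut[i, 1 - fi]
            x = mut[j, fj]
            y = mut[j, 1 - fj]
            # new dyads {u,y}, {x,v}
            if u == y or x == v or adj[u, y] or adj[y, u] or adj[x, v] or adj[v, x]:
                consec += 1
                continue
            adj[u, v] = False
            adj[v, u] = False
            adj[x, y] = False
            adj[y, x] = False
            adj[u, y] = True
            adj[y, u] = True
            adj[x, v] = True
            adj[v, x] = True
            mut[i, 0] = u
            mut[i, 1] = y
            mut[j, 0] = x
            mut[j, 1] = v
            acc_m += 1
            consec = 0
    return acc_a, att_a, acc_m, att_m, aborted
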