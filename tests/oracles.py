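"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written the slow, obvious way — plain Python
loops and closed forms — and never calls into the code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

PURINES = {"A", "G"}
BASES = "ACGT"


# ---------------------------------------------------------------------------
# K2P closed form, per-pair loop
# ---------------------------------------------------------------------------

def k2p_brute(seq_a: str, seq_b: str):
    """(n, ts, tv, d or None) by direct column-by-column counting."""
    n = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in BASES or y not in BASES:
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        return n, ts, tv, None
    p, q = ts / n, tv / n
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return n, ts, tv, None
    return n, ts, tv, -0.5 * math.log(w1 * math.sqrt(w2))


# ---------------------------------------------------------------------------
# Site classification, column by column
# ---------------------------------------------------------------------------

def classify_column(column: str) -> tuple[bool, bool]:
    """(variable, parsimony_informative) for one alignment column."""
    counts: dict[str, int] = {}
    for c in column.upper():
        if c in BASES:
            counts[c] = counts.get(c, 0) + 1
    variable = len(counts) >= 2
    informative = sum(1 for v in counts.values() if v >= 2) >= 2
    return variable, informative


def site_counts_brute(seqs: list[str]) -> tuple[int, int]:
    var = pi = 0
    for col in zip(*seqs):
        v, i = classify_column("".join(col))
        var += v
        pi += i
    return var, pi


# ---------------------------------------------------------------------------
# Nearest-neighbour identification
# ---------------------------------------------------------------------------

def best_match_brute(query: str, ids: list[str], values, species_of: dict[str, str],
                     threshold: float | None = None, rel_tol: float = 1e-9):
    """Verdict category by scanning all non-self defined distances."""
    idx = {s: i for i, s in enumerate(ids)}
    dists = []
    for other in ids:
        if other == query:
            continue
        d = values[idx[query], idx[other]]
        if not math.isnan(d):
            dists.append((d, other))
    best = min(d for d, _ in dists)
    if threshold is not None and best > threshold:
        return "no_match", best
    tol = rel_tol * max(1.0, abs(best))
    tied_species = {species_of[o] for d, o in dists if d <= best + tol}
    q_sp = species_of[query]
    if tied_species == {q_sp}:
        return "correct", best
    if q_sp in tied_species:
        return "ambiguous", best
    return "incorrect", best


# ---------------------------------------------------------------------------
# Local barcoding gap, by explicit pair scans
# ---------------------------------------------------------------------------

def local_gap_brute(species: str, ids: list[str], values,
                    species_of: dict[str, str]) -> bool:
    idx = {s: i for i, s in enumerate(ids)}
    members = [s for s in ids if species_of.get(s) == species]
    intra = [
        values[idx[a], idx[b]]
        for a, b in itertools.combinations(members, 2)
        if not math.isnan(values[idx[a], idx[b]])
    ]
    inter = [
        values[idx[a], idx[o]]
        for a in members
        for o in ids
        if species_of.get(o) != species and not math.isnan(values[idx[a], idx[o]])
    ]
    return min(inter) > max(intra)


# ---------------------------------------------------------------------------
# Unrooted tree enumeration and additive matrices
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(leaves: list[str]):
    """All unrooted binary topologies by stepwise addition.

    Trees are edge dicts {frozenset({u, v}): None}; internal nodes are
    negative integers, leaves their labels. 15 trees for 5 leaves, 105 for 6.
    """
    assert len(leaves) >= 3
    base = [{frozenset({leaves[0], -1}), frozenset({leaves[1], -1}),
             frozenset({leaves[2], -1})}]
    trees = base
    next_internal = -2
    for leaf in leaves[3:]:
        new_trees = []
        for edges in trees:
            for edge in sorted(edges, key=sorted_key):
                u, v = sorted(edge, key=str)
                rest = edges - {edge}
                new = set(rest)
                new.add(frozenset({u, next_internal}))
                new.add(frozenset({v, next_internal}))
                new.add(frozenset({leaf, next_internal}))
                new_trees.append(new)
        trees = new_trees
        next_internal -= 1
    return trees


def sorted_key(edge):
    return tuple(sorted(str(x) for x in edge))


def additive_matrix(edges, lengths: dict, leaves: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix via BFS over the edge set."""
    adj: dict = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, lengths[e]))
        adj.setdefault(v, []).append((u, lengths[e]))
    n = len(leaves)
    out = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    stack.append(nb)
        for j, dst in enumerate(leaves):
            out[i, j] = dist[dst]
    return out


def topology_bipartitions(edges, leaves: list[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an edge-set tree, canonicalised like the
    package (side without the smallest leaf)."""
    leafset = frozenset(leaves)
    ref = min(leaves)
    adj: dict = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    out = set()
    for e in edges:
        u, v = tuple(e)
        # leaves on v's side when edge removed
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            node = stack.pop()
            if node in leafset:
                side.add(node)
            for nb in adj[node]:
                if nb not in seen or nb == u:
                    if (frozenset({node, nb}) != e) and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        key = frozenset(side) if ref not in side else leafset - frozenset(side)
        if 2 <= len(key) <= len(leaves) - 2:
            out.add(key)
    return out
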