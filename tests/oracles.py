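"""Independent brute-force oracles used to verify the main implementations.

Everything here is deliberately naive (exhaustive enumeration, triple
scans, closed forms) and shares no code with the package internals.
"""

from itertools import combinations
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive neighbour-joining oracle: enumerate unrooted topologies, fit
# branch lengths by least squares on the path-length system, keep the best
# ---------------------------------------------------------------------------
def _all_topologies(labels):
    """Yield unrooted binary topologies as edge lists over labelled nodes.

    Leaves are the given labels; internal nodes are ints. Built by inserting
    each successive leaf into every edge of every partial topology.
    """
    labels = list(labels)
    base = [(labels[0], 0), (labels[1], 0), (labels[2], 0)]
    tops = [(base, 1)]  # (edges, next internal node id)
    for leaf in labels[3:]:
        new_tops = []
        for edges, nxt in tops:
            for i, (u, v) in enumerate(edges):
                ne = edges[:i] + edges[i + 1 :]
                ne = ne + [(u, nxt), (v, nxt), (leaf, nxt)]
                new_tops.append((ne, nxt + 1))
        tops = new_tops
    return [e for e, _ in tops]


def _paths(edges, labels):
    """leaf-pair -> set of edge indices on the connecting path."""
    adj = {}
    for i, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, i))
        adj.setdefault(v, []).append((u, i))

    def path(a, b):
        stack = [(a, None, [])]
        seen = set()
        while stack:
            node, prev, acc = stack.pop()
            if node == b:
                return acc
            seen.add(node)
            for nb, ei in adj[node]:
                if nb not in seen:
                    stack.append((nb, node, acc + [ei]))
        raise AssertionError("disconnected topology")

    return {(a, b): path(a, b) for a, b in combinations(labels, 2)}


def nj_oracle(labels, d):
    """Best-fitting topology by exhaustive enumeration + least squares.

    Returns (bipartitions, lengths_by_bipartition, residual). Bipartitions
    are canonical frozensets of leaf labels (smaller side, ties by sorted
    tuple), one per edge including trivial leaf edges.
    """
    labels = list(labels)
    full = frozenset(labels)
    idx = {lbl: i for i, lbl in enumerate(labels)}
    best = None
    for edges in _all_topologies(labels):
        paths = _paths(edges, labels)
        a_mat = np.zeros((len(paths), len(edges)))
        rhs = np.zeros(len(paths))
        for r, ((x, y), eids) in enumerate(paths.items()):
            for ei in eids:
                a_mat[r, ei] = 1.0
            rhs[r] = d[idx[x], idx[y]]
        sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        resid = float(np.abs(a_mat @ sol - rhs).max())
        if best is None or resid < best[2]:
            best = (edges, sol, resid)
    edges, sol, resid = best

    # leaf set below each edge, from the side not containing labels[0]
    adj = {}
    for i, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, i))
        adj.setdefault(v, []).append((u, i))

    def leaves_beyond(node, banned_edge):
        out, stack, seen = set(), [node], set()
        while stack:
            cur = stack.pop()
            seen.add(cur)
            if isinstance(cur, str):
                out.add(cur)
            for nb, ei in adj[cur]:
                if ei != banned_edge and nb not in seen:
                    stack.append(nb)
        return out

    def canonical(side):
        comp = full - side
        if len(side) != len(comp):
            return frozenset(side if len(side) < len(comp) else comp)
        return frozenset(min(side, comp, key=lambda s: tuple(sorted(s))))

    bips, lengths = set(), {}
    for i, (u, v) in enumerate(edges):
        side = frozenset(leaves_beyond(u, i))
        key = canonical(side)
        bips.add(key)
        lengths[key] = float(sol[i])
    return bips, lengths, resid


def random_additive_matrix(labels, rng, lo=0.1, hi=1.0):
    """Random unrooted binary tree -> (distance matrix, true bipartitions)."""
    labels = list(labels)
    tops = _all_topologies(labels)
    edges = tops[rng.integers(len(tops))]
    lens = rng.uniform(lo, hi, size=len(edges))
    paths = _paths(edges, labels)
    n = len(labels)
    idx = {lbl: i for i, lbl in enumerate(labels)}
    d = np.zeros((n, n))
    for (x, y), eids in paths.items():
        dist = sum(lens[e] for e in eids)
        d[idx[x], idx[y]] = d[idx[y], idx[x]] = dist
    full = frozenset(labels)
    adj = {}
    for i, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, i))
        adj.setdefault(v, []).append((u, i))

    def leaves_beyond(node, banned_edge):
        out, stack, seen = set(), [node], set()
        while stack:
            cur = stack.pop()
            seen.add(cur)
            if isinstance(cur, str):
                out.add(cur)
            for nb, ei in adj[cur]:
                if ei != banned_edge and nb not in seen:
                    stack.append(nb)
        return out

    bips = set()
    for i, (u, v) in enumerate(edges):
        side = leaves_beyond(u, i)
        comp = full - side
        if len(side) >= 2 and len(comp) >= 2:
            if len(side) < len(comp):
                bips.add(frozenset(side))
            elif len(comp) < len(side):
                bips.add(frozenset(comp))
            else:
                bips.add(frozenset(min(side, comp, key=lambda s: tuple(sorted(s)))))
    return d, bips


# ---------------------------------------------------------------------------
# hypergeometric upper tail by exhaustive enumeration (N small)
# ---------------------------------------------------------------------------
def hypergeom_tail_enum(N, K, n, k):
    """P(X >= k) by summing the exact pmf over the upper tail."""
    total = comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return acc / total


# ---------------------------------------------------------------------------
# graph statistic oracles
# ---------------------------------------------------------------------------
def clustering_triple_scan(nodes, edges):
    """Per-node clustering coefficient by O(n^3) triple enumeration."""
    nodes = list(nodes)
    eset = {frozenset(e) for e in edges}
    out = {}
    for v in nodes:
        nbrs = [u for u in nodes if frozenset((u, v)) in eset]
        deg = len(nbrs)
        if deg < 2:
            out[v] = 0.0
            continue
        tri = 0
        for a, b in combinations(nbrs, 2):
            if frozenset((a, b)) in eset:
                tri += 1
        out[v] = 2.0 * tri / (deg * (deg - 1))
    return out


def pair_connectivity_filter(edges, cluster_a, cluster_b):
    """Inter-cluster connectivity by explicit edge filtering."""
    a, b = set(cluster_a), set(cluster_b)
    count = 0
    for u, v in edges:
        if (u in a and v in b) or (u in b and v in a):
            count += 1
    return count / (len(a) + len(b))


# ---------------------------------------------------------------------------
# reciprocal best hit by brute force
# ---------------------------------------------------------------------------
def rbh_brute_force(fwd, rev):
    """All (a, b) pairs that are mutual best hits, re-derived via sorting."""

    def best_of(hits, query):
        mine = [h for h in hits if h.query_id == query]
        if not mine:
            return None
        mine.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        return mine[0].subject_id

    queries = {h.query_id for h in fwd}
    subjects = {h.query_id for h in rev}
    out = set()
    for a in queries:
        b = best_of(fwd, a)
        if b is not None and b in subjects and best_of(rev, b) == a:
            out.add((a, b))
    return out
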