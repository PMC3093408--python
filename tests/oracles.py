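"""Independent brute-force oracles used by unit and acceptance tests.

Everything here re-derives expected results from first principles —
exhaustive dynamic programming, per-basepair loops, explicit staged
comparisons, exhaustive topology search — and deliberately shares no code
path with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# affine-gap global alignment score (Gotoh three-state DP)
# ---------------------------------------------------------------------------

def gotoh_score(a, b, match=2.0, mismatch=-1.0, gap_open=-10.0, gap_extend=-2.0):
    """Optimal global affine-gap alignment score; a gap of length k costs
    gap_open + (k-1)*gap_extend."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------
# locus-dedup cascade by explicit staged comparison
# ---------------------------------------------------------------------------

def _beats(c, d):
    """True if chain c beats chain d in the selection cascade."""
    cd, dd = len({p.gene for p in c.puteins}), len({p.gene for p in d.puteins})
    if cd != dd:
        return cd > dd
    if len(c.puteins) != len(d.puteins):
        return len(c.puteins) > len(d.puteins)
    if c.score != d.score:
        return c.score > d.score
    if c.start != d.start:
        return c.start < d.start
    return c.id < d.id


def brute_force_dedup_ids(chains):
    """Survivor ids via explicit connected components + staged comparison."""
    comps = []
    for c in chains:
        merged = [c]
        rest = []
        for comp in comps:
            if any(
                c.chromosome == o.chromosome
                and c.start < o.end
                and o.start < c.end
                for o in comp
            ):
                merged += comp
            else:
                rest.append(comp)
        comps = rest + [merged]
    survivors = set()
    for comp in comps:
        best = comp[0]
        for c in comp[1:]:
            if _beats(c, best):
                best = c
        survivors.add(best.id)
    return survivors


# ---------------------------------------------------------------------------
# per-basepair neighborhood profile
# ---------------------------------------------------------------------------

def brute_force_profile(ervs, models, window):
    """Quadratic per-basepair double loop re-deriving the offset mapping:
    a model base inside the provirus is at offset 0; the k-th base beyond
    the 3' end at +k; the k-th base beyond the 5' end at -k (in the
    provirus's own frame)."""
    n = 2 * window + 1
    sense = np.zeros(n, dtype=np.int64)
    anti = np.zeros(n, dtype=np.int64)
    for erv in ervs:
        for m in models:
            if m.chromosome != erv.chromosome:
                continue
            for x in range(m.start, m.end):
                if erv.start <= x < erv.end:
                    off = 0
                elif x >= erv.end:
                    off = x - erv.end + 1
                else:
                    off = x - erv.start  # negative
                if erv.strand == "-":
                    off = -off
                if abs(off) > window:
                    continue
                if m.strand == erv.strand:
                    sense[off + window] += 1
                else:
                    anti[off + window] += 1
    return sense, anti


def window_coverage_bp(ervs, models, window):
    """Total model basepairs inside any provirus window, by interval
    arithmetic (conservation oracle)."""
    total = 0
    for erv in ervs:
        lo, hi = erv.start - window, erv.end + window
        for m in models:
            if m.chromosome != erv.chromosome:
                continue
            total += max(0, min(m.end, hi) - max(m.start, lo))
    return total


# ---------------------------------------------------------------------------
# exhaustive small-tree search
# ---------------------------------------------------------------------------

def all_unrooted_topologies(labels):
    """All unrooted binary topologies on the labels, as frozensets of
    non-trivial splits (each split = the side without labels[0])."""
    labels = list(labels)
    # a tree is a list of edges between node ids (ints = leaves, strings =
    # internal); grow by inserting each new leaf into every existing edge,
    # starting from the unique 3-leaf star
    trees = [[(0, "I0"), (1, "I0"), (2, "I0")]]
    next_internal = 1
    for leaf in range(3, len(labels)):
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                node = f"I{next_internal}_{leaf}_{k}"
                new_edges = edges[:k] + edges[k + 1:]
                new_edges += [(u, node), (v, node), (leaf, node)]
                new_trees.append(new_edges)
        trees = new_trees
    return [frozenset(tree_splits(e, len(labels), labels)) for e in trees], trees


def tree_splits(edges, n_leaves, labels):
    """Non-trivial splits of an edge list, sides not containing labels[0]."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = []
    for u, v in edges:
        side = _component(adj, v, u)
        leaves = frozenset(labels[x] for x in side if isinstance(x, int))
        if labels[0] in leaves:
            leaves = frozenset(labels) - leaves
        if 1 < len(leaves) < n_leaves - 1:
            splits.append(leaves)
    return splits


def _component(adj, start, blocked):
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y != blocked and y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def least_squares_topology(dist, labels):
    """Exhaustive OLS tree search: fit branch lengths for every unrooted
    topology by least squares on the path matrix, return the split set of
    the minimum-SSE topology."""
    split_sets, edge_lists = all_unrooted_topologies(labels)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    d = np.array([dist[i][j] for i, j in pairs])
    best = None
    best_sse = np.inf
    for splits, edges in zip(split_sets, edge_lists):
        adj = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        A = np.zeros((len(pairs), len(edges)))
        for r, (i, j) in enumerate(pairs):
            path = _path(adj, i, j)
            for k, (u, v) in enumerate(edges):
                if (u, v) in path or (v, u) in path:
                    A[r, k] = 1.0
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        sse = float(((A @ x - d) ** 2).sum())
        if sse < best_sse - 1e-12:
            best_sse = sse
            best = splits
    return best


def _path(adj, a, b):
    prev = {a: None}
    stack = [a]
    while stack:
        x = stack.pop()
        if x == b:
            break
        for y in adj[x]:
            if y not in prev:
                prev[y] = x
                stack.append(y)
    edges = set()
    x = b
    while prev[x] is not None:
        edges.add((prev[x], x))
        x = prev[x]
    return edges


def random_additive_matrix(rng, labels, noise=0.0):
    """Distance matrix generated from a random unrooted binary tree with
    uniform branch lengths; returns (matrix, true split set)."""
    split_sets, edge_lists = all_unrooted_topologies(labels)
    pick = int(rng.integers(0, len(edge_lists)))
    edges = edge_lists[pick]
    lengths = {e: float(rng.uniform(0.05, 1.0)) for e in edges}
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            path = _path(adj, i, j)
            dist = sum(
                lengths[e if e in lengths else (e[1], e[0])] for e in path
            )
            if noise:
                dist *= 1.0 + float(rng.uniform(-noise, noise))
            m[i, j] = m[j, i] = dist
    return m, split_sets[pick]
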