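"""Independent brute-force oracles used by the test suite.

Everything here is written against the raw graph structure (adjacency
lists, explicit loops) and never calls the library code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def adjacency(nodes, edges):
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def sequences(nodes, edges):
    """node -> sorted tuple of neighbour degrees, by direct enumeration."""
    adj = adjacency(nodes, edges)
    deg = {u: len(adj[u]) for u in nodes}
    return {u: tuple(sorted(deg[v] for v in adj[u])) for u in nodes}


def similarity_pairwise(nodes, edges):
    """S by O(n^2) pairwise sequence comparison over non-isolated nodes."""
    seqs = {u: s for u, s in sequences(nodes, edges).items() if s}
    keys = list(seqs)
    if not keys:
        return 0.0
    matched = 0
    for i in keys:
        for j in keys:
            if i != j and seqs[i] == seqs[j]:
                matched += 1
                break
    return matched / len(keys)


def omega_literal(seq_list):
    """Literal per-class formula from the sequence multiset of one class."""
    q = len(seq_list)
    uniq = sorted(set(seq_list))
    total = 0
    for s in uniq:
        c = sum(1 for t in seq_list if t == s)
        total += q - c
    return len(uniq) * total / (q * q * (q - 1))


def complexity_naive(nodes, edges, weighted=False):
    """R (or R_Omega) by explicit triple-sum loops; None if D_2 empty."""
    seqs = {u: s for u, s in sequences(nodes, edges).items() if s}
    classes: dict[int, list] = {}
    for s in seqs.values():
        classes.setdefault(len(s), []).append(s)
    d2 = [p for p, ss in classes.items() if len(ss) >= 2]
    if not d2:
        return None
    total = 0.0
    for p in d2:
        ss = classes[p]
        q = len(ss)
        inner = 0.0
        for j in range(p):
            mu = sum(s[j] for s in ss) / q
            for s in ss:
                inner += (s[j] - mu) ** 2
        term = inner / (p * (q - 1))
        if weighted:
            term *= omega_literal(ss)
        total += term
    return total / len(d2)


def node_heterogeneity_loop(nodes, edges, ddof=0):
    """V_n by an explicit per-node loop (population variance by default)."""
    seqs = {u: s for u, s in sequences(nodes, edges).items() if s}
    if not seqs:
        return 0.0
    total = 0.0
    for s in seqs.values():
        if len(s) > 1:
            mu = sum(s) / len(s)
            total += sum((x - mu) ** 2 for x in s) / (len(s) - ddof)
    return total / len(seqs)


def transitivity_triples(nodes, edges):
    """3 * triangles / connected triples by brute-force enumeration."""
    adj = adjacency(nodes, edges)
    closed = opened = 0
    for j in nodes:
        for i, k in itertools.combinations(sorted(adj[j]), 2):
            opened += 1
            if k in adj[i]:
                closed += 1
    return 3 * (closed / 3) / opened if opened else 0.0


def path_length_floyd(nodes, edges):
    """Mean finite shortest-path length via Floyd-Warshall; None if no pairs."""
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    for u, v in edges:
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    iu = np.triu_indices(n, 1)
    finite = d[iu][np.isfinite(d[iu])]
    if finite.size == 0:
        return None
    return float(finite.mean())


def assortativity_pearson(nodes, edges):
    """Pearson correlation over both orientations of edge endpoint degrees."""
    adj = adjacency(nodes, edges)
    deg = {u: len(adj[u]) for u in nodes}
    xs, ys = [], []
    for u, v in edges:
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    x, y = np.array(xs, float), np.array(ys, float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def wilcoxon_exact_enumeration(diffs):
    """Two-sided exact signed-rank p by enumerating all sign assignments.

    Requires nonzero, tie-free |diffs| (the textbook null distribution).
    Returns (W_statistic = min(W+, W-), p).
    """
    d = [x for x in diffs if x != 0]
    n = len(d)
    order = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0.0] * n
    for r, i in enumerate(order, 1):
        ranks[i] = float(r)
    w_plus = sum(ranks[i] for i in range(n) if d[i] > 0)
    total = n * (n + 1) / 2
    dist = []
    for signs in itertools.product((0, 1), repeat=n):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    count_le = sum(1 for w in dist if w <= w_plus)
    count_ge = sum(1 for w in dist if w >= w_plus)
    p = min(1.0, 2 * min(count_le, count_ge) / len(dist))
    return min(w_plus, total - w_plus), p


def rank_biserial_brute(x, y):
    """Effect size by explicit rank sums (average ranks on ties)."""
    d = [a - b for a, b in zip(x, y) if a != b]
    if not d:
        return 0.0
    absd = sorted((abs(v), i) for i, v in enumerate(d))
    ranks = [0.0] * len(d)
    i = 0
    while i < len(absd):
        j = i
        while j < len(absd) and absd[j][0] == absd[i][0]:
            j += 1
        avg = (i + 1 + j) / 2
        for k in range(i, j):
            ranks[absd[k][1]] = avg
        i = j
    wp = sum(r for r, v in zip(ranks, d) if v > 0)
    wm = sum(r for r, v in zip(ranks, d) if v < 0)
    return (wp - wm) / (wp + wm)


def spearman_rank_pearson(a, b):
    """Spearman rho as Pearson correlation of average ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        out = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and v[order[j]] == v[order[i]]:
                j += 1
            avg = (i + 1 + j) / 2
            for k in range(i, j):
                out[order[k]] = avg
            i = j
        return np.array(out)

    ra, rb = ranks(list(a)), ranks(list(b))
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / math.sqrt((ra**2).sum() * (rb**2).sum()))


def random_simple_graph(rng, n_max=30, p=0.2):
    """Seeded Erdos-Renyi-style edge set for oracle-equivalence tests."""
    n = rng.integers(4, n_max + 1)
    nodes = [str(i) for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges
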