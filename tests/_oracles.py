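"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (path enumeration, exhaustive subset
scans, Fraction arithmetic, BFS) kept separate from the package code paths
they validate.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction
from math import comb


# --- path enumeration ------------------------------------------------------

def enumerate_path_effect(nodes, weights: dict, X: list, Y: list):
    """ef[i][j] = sum over directed paths X_i -> Y_j of weight products,
    on the graph with all edges into members of X removed."""
    surgered = {(u, v): w for (u, v), w in weights.items() if v not in set(X)}
    children = {}
    for (u, v), w in surgered.items():
        children.setdefault(u, []).append((v, w))

    def paths_sum(src, dst):
        total = 0.0
        stack = [(src, 1.0)]
        while stack:
            node, prod = stack.pop()
            if node == dst:
                total += prod
                continue
            for v, w in children.get(node, []):
                stack.append((v, prod * w))
        return total

    return [[paths_sum(x, y) for y in Y] for x in X]


# --- equivalence classes ---------------------------------------------------

def brute_force_extensions(nodes, directed, undirected):
    """All orientations of the undirected edges that keep the graph acyclic
    and preserve the v-structure set (computed on the full skeleton)."""
    und = sorted(map(sorted, undirected))
    skel = {frozenset(e) for e in directed} | {frozenset(e) for e in und}
    base_vs = _colliders(directed, skel)
    out = []
    for choice in itertools.product([0, 1], repeat=len(und)):
        edges = set(directed)
        for bit, (a, b) in zip(choice, und):
            edges.add((a, b) if bit == 0 else (b, a))
        if _acyclic(nodes, edges) and _colliders(edges, skel) == base_vs:
            out.append(frozenset(edges))
    return out


def _acyclic(nodes, edges):
    indeg = {n: 0 for n in nodes}
    succ = {n: [] for n in nodes}
    for u, v in edges:
        indeg[v] += 1
        succ[u].append(v)
    q = deque(n for n in nodes if indeg[n] == 0)
    seen = 0
    while q:
        n = q.popleft()
        seen += 1
        for m in succ[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                q.append(m)
    return seen == len(nodes)


def _colliders(edges, skel):
    into = {}
    for u, v in edges:
        into.setdefault(v, set()).add(u)
    out = set()
    for c, pars in into.items():
        for a, b in itertools.combinations(sorted(pars), 2):
            if frozenset((a, b)) not in skel:
                out.add((a, c, b))
    return out


# --- hypergeometric --------------------------------------------------------

def hypergeom_upper_tail_exact(N, M, K, x) -> Fraction:
    """1 - sum_{i<x} C(M,i) C(N-M,K-i) / C(N,K) in exact rationals."""
    total = Fraction(0)
    for i in range(x):
        total += Fraction(comb(M, i) * comb(N - M, K - i), comb(N, K))
    return 1 - total


# --- bicliques -------------------------------------------------------------

def brute_force_maximal_bicliques(edges, min_left=2, min_right=2):
    """All maximal (C, D) with C x D complete, by scanning every subset pair."""
    left = sorted({u for u, _ in edges})
    right = sorted({v for _, v in edges})
    eset = set(edges)

    def complete(C, D):
        return all((u, v) in eset for u in C for v in D)

    bicliques = []
    for rc in range(1, len(left) + 1):
        for C in itertools.combinations(left, rc):
            for rd in range(1, len(right) + 1):
                for D in itertools.combinations(right, rd):
                    if complete(C, D):
                        bicliques.append((frozenset(C), frozenset(D)))
    maximal = []
    for C, D in bicliques:
        if any((C < C2 and D <= D2) or (C <= C2 and D < D2)
               for C2, D2 in bicliques):
            continue
        if len(C) >= min_left and len(D) >= min_right:
            maximal.append((C, D))
    return set(maximal)


# --- graph statistics ------------------------------------------------------

def brute_clustering(nodes, edges) -> float:
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    total = 0.0
    for n in nodes:
        k = len(adj[n])
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(sorted(adj[n]), 2)
                    if b in adj[a])
        total += links / (k * (k - 1) / 2)
    return total / len(nodes)


def brute_path_length(nodes, edges):
    """(mean over connected ordered pairs, number of excluded ordered pairs)."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    total, count = 0, 0
    for s in nodes:
        dist = {s: 0}
        q = deque([s])
        while q:
            n = q.popleft()
            for m in adj[n]:
                if m not in dist:
                    dist[m] = dist[n] + 1
                    q.append(m)
        for t, d in dist.items():
            if t != s:
                total += d
                count += 1
    n = len(nodes)
    if count == 0:
        return None, n * (n - 1)
    return total / count, n * (n - 1) - count


def ols_loglog(xs, ys):
    """Normal-equations least squares of log10(y) on log10(x)."""
    import math
    lx = [math.log10(x) for x in xs]
    ly = [math.log10(y) for y in ys]
    n = len(lx)
    sx, sy = sum(lx), sum(ly)
    sxx = sum(v * v for v in lx)
    sxy = sum(a * b for a, b in zip(lx, ly))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, 10 ** intercept
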