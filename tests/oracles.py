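"""Independent brute-force oracles for graph metrics and chunking.

Everything here is deliberately naive — union-find, Floyd-Warshall,
subset enumeration, matrix-power geodesic counting, exhaustive substring
scanning — and shares no code with the package implementations it checks.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

INF = float("inf")


# --- components --------------------------------------------------------------

def union_find_components(nodes, edges):
    """Undirected connected components by union-find."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for v in nodes:
        groups.setdefault(find(v), set()).add(v)
    return sorted(groups.values(), key=lambda c: (-len(c), sorted(map(repr, c))))


# --- distances ---------------------------------------------------------------

def floyd_warshall(nodes, edges):
    """All-pairs shortest path lengths on the undirected simple graph."""
    nodes = list(nodes)
    dist = {(u, v): (0 if u == v else INF) for u in nodes for v in nodes}
    for a, b in edges:
        if a != b:
            dist[(a, b)] = dist[(b, a)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                alt = dist[(i, k)] + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return dist


def mean_distance_and_diameter(nodes, edges):
    """(mean over ordered reachable pairs, diameter) for a connected graph."""
    dist = floyd_warshall(nodes, edges)
    ds = [d for (u, v), d in dist.items() if u != v]
    assert all(d < INF for d in ds), "graph must be connected"
    return sum(ds) / len(ds), max(ds)


# --- geodesic counting: closeness and betweenness ----------------------------

def _geodesic_counts(nodes, edges):
    """sigma[u][v]: number of shortest u-v paths, via adjacency-matrix powers
    (walks of minimal length are exactly the geodesics)."""
    nodes = list(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=object)
    for a, b in edges:
        if a != b:
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1
    dist = floyd_warshall(nodes, edges)
    power = np.eye(n, dtype=object)
    sigma = {}
    maxd = max((d for d in dist.values() if d < INF), default=0)
    powers = [power]
    for _ in range(int(maxd)):
        power = power @ adj
        powers.append(power)
    for u in nodes:
        for v in nodes:
            d = dist[(u, v)]
            sigma[(u, v)] = int(powers[int(d)][idx[u], idx[v]]) if d < INF else 0
    return dist, sigma


def closeness_oracle(nodes, edges):
    """Freeman-normalized closeness (N-1)/sum(d) on a connected graph."""
    dist = floyd_warshall(nodes, edges)
    nodes = list(nodes)
    out = {}
    for v in nodes:
        total = sum(dist[(v, u)] for u in nodes if u != v)
        out[v] = (len(nodes) - 1) / total if total else 0.0
    return out

def betweenness_oracle(nodes, edges):
    """Unnormalized betweenness: sum over unordered pairs j<k (j,k != v) of
    sigma_jk(v)/sigma_jk, with pass-through counts from sigma products."""
    dist, sigma = _geodesic_counts(nodes, edges)
    nodes = list(nodes)
    bc = {v: 0.0 for v in nodes}
    for j, k in itertools.combinations(nodes, 2):
        if sigma[(j, k)] == 0:
            continue
        for v in nodes:
            if v in (j, k):
                continue
            if dist[(j, v)] + dist[(v, k)] == dist[(j, k)]:
                bc[v] += sigma[(j, v)] * sigma[(v, k)] / sigma[(j, k)]
    return bc


# --- clustering --------------------------------------------------------------

def transitivity_oracle(nodes, edges):
    """3 * triangles / connected triples by full triple enumeration."""
    eset = {frozenset(e) for e in edges if e[0] != e[1]}
    triangles = triples = 0
    for a, b, c in itertools.combinations(nodes, 3):
        present = [frozenset(p) in eset for p in ((a, b), (b, c), (a, c))]
        k = sum(present)
        if k == 3:
            triangles += 1
            triples += 3
        elif k == 2:
            triples += 1
    return 3 * triangles / triples if triples else 0.0


# --- subset enumeration: k-core and biconnected components -------------------

def core_numbers_oracle(nodes, edges):
    """core(v) = max over vertex subsets containing v of the subset's minimum
    induced degree.  Exponential; use on <= 10 nodes."""
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    core = {v: 0 for v in nodes}
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            s = set(subset)
            mindeg = min(len(adj[v] & s) for v in s)
            for v in s:
                core[v] = max(core[v], mindeg)
    return core


def _is_connected(sub, adj):
    start = next(iter(sub))
    seen = {start}
    stack = [start]
    while stack:
        for w in adj[stack.pop()] & sub:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen == sub


def bicomponents_oracle(nodes, edges):
    """Maximal vertex sets (>= 2) whose induced subgraph is connected and has
    no articulation point.  Exponential; use on <= 9 nodes."""
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    eset = set()
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
            eset.add(frozenset((a, b)))
    candidates = []
    for r in range(2, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            s = set(subset)
            if not _is_connected(s, adj):
                continue
            if r == 2:
                if frozenset(subset) in eset:
                    candidates.append(s)
                continue
            if all(_is_connected(s - {v}, adj) for v in s):
                candidates.append(s)
    maximal = [s for s in candidates if not any(s < t for t in candidates)]
    return sorted(maximal, key=lambda c: (-len(c), sorted(map(repr, c))))


# --- degrees -----------------------------------------------------------------

def degree_recount(arcs):
    """(in-degree, out-degree) per node from a set of directed arcs; a loop
    adds one to both."""
    indeg: Counter = Counter()
    outdeg: Counter = Counter()
    for a, b in arcs:
        outdeg[a] += 1
        indeg[b] += 1
    return indeg, outdeg


# --- chunking ----------------------------------------------------------------

def chunk_oracle(text, surfaces):
    """Longest-leftmost non-overlapping token-boundary matching by exhaustive
    enumeration: list every occurrence of every surface at token boundaries,
    then greedily select by (start, -length)."""

    def boundary(i, j):
        left_ok = i == 0 or not (text[i - 1].isalnum() and text[i].isalnum())
        right_ok = j == len(text) or not (text[j - 1].isalnum() and text[j].isalnum())
        return left_ok and right_ok

    occurrences = []
    for s in surfaces:
        start = 0
        while True:
            i = text.find(s, start)
            if i == -1:
                break
            if boundary(i, i + len(s)):
                occurrences.append((i, i + len(s), s))
            start = i + 1
    occurrences.sort(key=lambda o: (o[0], -(o[1] - o[0])))
    chosen = []
    cursor = 0
    for i, j, s in occurrences:
        if i >= cursor:
            chosen.append((i, j, s))
            cursor = j
    return chosen
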