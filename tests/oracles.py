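"""Independent brute-force oracles for the graph-metric implementations.

Everything here is deliberately naive — hand-rolled BFS, explicit shortest
path enumeration over the predecessor DAG, O(N^2) pairwise comparisons —
so it shares no code path with the implementations it validates.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def _adj(g) -> dict:
    return {v: set(g.neighbors(v)) for v in g.nodes}


def _bfs(adj: dict, source):
    """Hand-rolled BFS returning (distances, predecessor lists)."""
    dist = {source: 0}
    preds: dict = {source: []}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                preds[w] = [u]
                queue.append(w)
            elif dist[w] == dist[u] + 1:
                preds[w].append(u)
    return dist, preds


def _enumerate_paths(preds: dict, source, target) -> list[list]:
    """All shortest source->target paths via the predecessor DAG."""
    if target not in preds:
        return []
    if target == source:
        return [[source]]
    out = []
    for p in preds[target]:
        for path in _enumerate_paths(preds, source, p):
            out.append(path + [target])
    return out


def betweenness_oracle(g) -> dict:
    """Node betweenness by explicit enumeration of every shortest path
    (unordered pairs, endpoints excluded, unnormalized)."""
    adj = _adj(g)
    nodes = sorted(g.nodes, key=str)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        _dist, preds = _bfs(adj, s)
        for t in nodes[i + 1:]:
            paths = _enumerate_paths(preds, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def edge_betweenness_oracle(g) -> dict:
    """Edge betweenness by the same explicit path enumeration."""
    adj = _adj(g)
    nodes = sorted(g.nodes, key=str)
    eb = {frozenset(e): 0.0 for e in g.edges}
    for i, s in enumerate(nodes):
        _dist, preds = _bfs(adj, s)
        for t in nodes[i + 1:]:
            paths = _enumerate_paths(preds, s, t)
            if not paths:
                continue
            for path in paths:
                for a, b in zip(path, path[1:]):
                    eb[frozenset((a, b))] += 1.0 / len(paths)
    return eb


def clustering_oracle(g) -> dict:
    """Clustering by exhaustive neighbor-pair enumeration."""
    adj = _adj(g)
    cc = {}
    for v in g.nodes:
        nbrs = sorted(adj[v], key=str)
        k = len(nbrs)
        if k < 2:
            cc[v] = 0.0
            continue
        t = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
        cc[v] = 2.0 * t / (k * (k - 1))
    return cc


def assortativity_oracle(g) -> float:
    """Pearson correlation of endpoint degrees over the symmetrized
    (both orientations) edge list; NaN when degenerate."""
    deg = dict(g.degree())
    xs, ys = [], []
    for u, v in g.edges():
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    xs, ys = np.array(xs, float), np.array(ys, float)
    if len(xs) < 2 or xs.std() == 0.0 or ys.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def duplicate_classes_oracle(g) -> tuple[list[frozenset], list[frozenset]]:
    """Duplicate / adjacent-twin classes by O(N^2) pairwise row comparison."""
    adj = _adj(g)
    nodes = sorted(g.nodes, key=str)

    def classes(key) -> list[frozenset]:
        remaining = list(nodes)
        out = []
        while remaining:
            v = remaining.pop(0)
            cls = {v}
            for w in list(remaining):
                if key(v) == key(w):
                    cls.add(w)
                    remaining.remove(w)
            if len(cls) >= 2:
                out.append(frozenset(cls))
        return sorted(out, key=lambda c: sorted(map(str, c)))

    dup = classes(lambda v: adj[v])
    twin = classes(lambda v: adj[v] | {v})
    return dup, twin


def pairwise_distance_sum(g) -> float:
    """Sum of d(u, v) over connected unordered pairs (hand-rolled BFS)."""
    adj = _adj(g)
    nodes = sorted(g.nodes, key=str)
    total = 0.0
    for i, s in enumerate(nodes):
        dist, _ = _bfs(adj, s)
        for t in nodes[i + 1:]:
            if t in dist:
                total += dist[t]
    return total
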