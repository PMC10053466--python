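"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive enumeration, O(n^3)
all-pairs, literal counting) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def best_stump_importance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Importance vector of a single depth-1 regression stump.

    Enumerates every (feature, threshold) partition, scores it by the
    variance reduction var(y) - (nL/N varL + nR/N varR) with biased
    variances, and credits the winning feature with that reduction.
    Ties between splits with equal reduction must be avoided by the caller.
    """
    n, p = X.shape
    var0 = y.var()
    best = (0.0, None)
    for j in range(p):
        for thr in np.unique(X[:, j])[:-1]:
            left = X[:, j] <= thr
            right = ~left
            red = var0 - (left.sum() / n) * y[left].var() - (right.sum() / n) * y[right].var()
            if red > best[0] + 1e-12:
                best = (red, j)
    out = np.zeros(p)
    if best[1] is not None:
        out[best[1]] = best[0]
    return out


def per_feature_best_reduction(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Best variance reduction achievable by splitting on each feature alone."""
    n, p = X.shape
    var0 = y.var()
    out = np.zeros(p)
    for j in range(p):
        for thr in np.unique(X[:, j])[:-1]:
            left = X[:, j] <= thr
            right = ~left
            red = var0 - (left.sum() / n) * y[left].var() - (right.sum() / n) * y[right].var()
            out[j] = max(out[j], red)
    return out


def auroc_all_pairs(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC by literal comparison of every (positive, negative) pair."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def graph_metrics_bruteforce(edges: list[tuple], min_nodes: int = 5) -> dict:
    """Transitivity, average path length and module count by enumeration.

    Undirected simple graph; shortest paths via Floyd-Warshall; transitivity
    by counting closed and connected ordered triples; modules by union-find.
    """
    nodes = sorted({u for e in edges for u in e})
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        if u != v:
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = True

    # transitivity: 3 * triangles / connected triples, over unordered triples
    triangles = 0
    triples = 0
    for a, b, c in itertools.combinations(range(n), 3):
        pairs = int(adj[a, b]) + int(adj[a, c]) + int(adj[b, c])
        if pairs >= 2:
            # each pair of incident edges at a centre is one connected triple
            for centre, x, y in ((a, b, c), (b, a, c), (c, a, b)):
                if adj[centre, x] and adj[centre, y]:
                    triples += 1
        if pairs == 3:
            triangles += 1
    transitivity = 3 * triangles / triples if triples else 0.0

    # Floyd-Warshall shortest paths
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[adj] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    finite = dist[(dist > 0) & np.isfinite(dist)]
    apl = float(finite.mean()) if finite.size else float("nan")

    # connected components via union-find
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(idx[u]), find(idx[v])
        if ru != rv:
            parent[ru] = rv
    sizes: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    modules = sum(1 for s in sizes.values() if s >= min_nodes)

    return {
        "n_nodes": n,
        "n_edges": int(adj.sum() // 2),
        "transitivity": transitivity,
        "average_path_length": apl,
        "module_count": modules,
    }
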