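"""Independent brute-force implementations of every graph metric.

Deliberately naive: Floyd-Warshall triple loops, exhaustive triple
enumeration for clustering, DFS enumeration of all shortest paths for
betweenness. These never call the package's metric code or networkx.
"""

import itertools

import numpy as np

TOL = 1e-12


def fw_distances(adjacency):
    """All-pairs shortest path lengths by Floyd-Warshall on 1/weight."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j] > 0:
                d[i, j] = 1.0 / a[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency(adjacency):
    d = fw_distances(adjacency)
    n = d.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def nodal_efficiency(adjacency):
    d = fw_distances(adjacency)
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                out[i] += 1.0 / d[i, j]
        out[i] /= n - 1
    return out


def char_path_length(adjacency):
    d = fw_distances(adjacency)
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("inf")


def clustering(adjacency, mode):
    """Per-node clustering by exhaustive enumeration of ordered triples."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    if mode == "binary":
        w = (a > 0).astype(float)
    else:
        w = a / a.max() if a.max() > 0 else a.copy()
    c = np.zeros(n)
    for i in range(n):
        k = int((a[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (w[i, j] * w[j, h] * w[i, h]) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c


def local_efficiency(adjacency):
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(sub)
    return out


def degree(adjacency, mode):
    a = np.asarray(adjacency, dtype=float)
    if mode == "binary":
        return (a > 0).sum(axis=1).astype(float)
    return a.sum(axis=1)


def _all_shortest_paths(adjacency, d, s, t):
    """Enumerate every shortest s->t path by DFS on the distance condition."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    paths = []

    def extend(node, so_far, length):
        if node == t:
            paths.append(list(so_far))
            return
        for nxt in range(n):
            if a[node, nxt] > 0 and nxt not in so_far:
                step = 1.0 / a[node, nxt]
                if abs(length + step + d[nxt, t] - d[s, t]) < 1e-9:
                    so_far.append(nxt)
                    extend(nxt, so_far, length + step)
                    so_far.pop()

    if np.isfinite(d[s, t]) and s != t:
        extend(s, [s], 0.0)
    return paths


def betweenness(adjacency):
    """Betweenness by explicit enumeration of all shortest paths."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    d = fw_distances(a)
    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(a, d, s, t)
        if not paths:
            continue
        share = 1.0 / len(paths)
        for path in paths:
            for v in path[1:-1]:
                out[v] += share
    return out
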