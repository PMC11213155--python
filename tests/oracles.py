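"""Independent brute-force oracles for graph measures.

Everything here is deliberately naive — Floyd-Warshall distances,
explicit triangle enumeration, depth-first enumeration of all shortest
paths — and shares no code with the package implementation.  Intended
for exhaustive checks on small graphs (<= ~8 nodes).
"""

from itertools import combinations

import numpy as np

INF = float("inf")


def bf_distances(adj):
    n = len(adj)
    d = [[0 if i == j else (1 if adj[i][j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def bf_degree(adj):
    return [sum(row) for row in adj]


def bf_clustering(adj):
    n = len(adj)
    out = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        if k < 2:
            out.append(0.0)
            continue
        tri = sum(1 for a, b in combinations(nb, 2) if adj[a][b])
        out.append(2.0 * tri / (k * (k - 1)))
    return out


def _all_shortest_paths(adj, s, t, dist):
    """Enumerate every shortest s-t path by bounded DFS."""
    target_len = dist[s][t]
    if target_len == INF:
        return []
    paths = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        if len(path) - 1 >= target_len:
            continue
        for nxt in range(len(adj)):
            if adj[node][nxt] and nxt not in path:
                # prune: remaining distance must fit in the budget
                if len(path) + dist[nxt][t] <= target_len:
                    stack.append((nxt, path + [nxt]))
    return paths


def bf_betweenness(adj):
    n = len(adj)
    dist = bf_distances(adj)
    bc = [0.0] * n
    for s, t in combinations(range(n), 2):
        paths = _all_shortest_paths(adj, s, t, dist)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def bf_global_efficiency(adj):
    n = len(adj)
    if n < 2:
        return 0.0
    d = bf_distances(adj)
    total = sum(
        1.0 / d[i][j] if d[i][j] != INF else 0.0
        for i in range(n) for j in range(n) if i != j
    )
    return total / (n * (n - 1))


def bf_cpl(adj):
    n = len(adj)
    d = bf_distances(adj)
    finite = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] != INF]
    return sum(finite) / len(finite) if finite else float("nan")


def bf_local_efficiency(adj):
    n = len(adj)
    out = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        if len(nb) < 2:
            out.append(0.0)
            continue
        sub = [[adj[a][b] for b in nb] for a in nb]
        out.append(bf_global_efficiency(sub))
    return out


def bf_assortativity(adj):
    n = len(adj)
    deg = bf_degree(adj)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if i < j and adj[i][j]:
                xs += [deg[i], deg[j]]
                ys += [deg[j], deg[i]]
    if not xs or len(set(xs)) == 1:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])
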