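"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written against different primitives than
the package uses (dense Floyd-Warshall matrices and fixed-point iteration
instead of per-node BFS and stack expansion).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def pairwise_shortest_paths(nodes: list, edges: set) -> dict:
    """All-pairs shortest path lengths via scipy's Floyd-Warshall; absent pairs omitted."""
    index = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for a, b in edges:
        if a in index and b in index:
            adj[index[a], index[b]] = adj[index[b], index[a]] = 1
    dist = floyd_warshall(adj, directed=False, unweighted=True)
    out = {}
    for p in nodes:
        for q in nodes:
            d = dist[index[p], index[q]]
            if np.isfinite(d):
                out[(p, q)] = int(d)
    return out


def ccrs_bruteforce(members1, members2, nodes, edges, *, shared_parent_correction=True):
    """Literal four-block enumeration of the corrected cumulative rank score.

    Returns (score, n_pairs); score is None when no pair has a distance.
    """
    sp = pairwise_shortest_paths(list(nodes), edges)
    g = set(members1) & set(members2)
    only1 = set(members1) - g
    only2 = set(members2) - g

    total, n = 0.0, 0

    def add_corrected(p, q):
        nonlocal total, n
        if p == q or (p, q) in sp:
            total += 1.0
            n += 1

    def add_path(p, q):
        nonlocal total, n
        if (p, q) in sp:
            total += sp[(p, q)]
            n += 1

    for p in g:
        for q in g:
            add_corrected(p, q)
    for p in g:
        for q in only1:
            (add_corrected if shared_parent_correction else add_path)(p, q)
    for p in g:
        for q in only2:
            (add_corrected if shared_parent_correction else add_path)(p, q)
    for p in only1:
        for q in only2:
            add_path(p, q)
    if n == 0:
        return None, 0
    return total / n, n


def ball_bruteforce(seeds, nodes, edges, radius):
    """Radius-limited neighborhood via the Floyd-Warshall distance matrix."""
    sp = pairwise_shortest_paths(list(nodes), edges)
    node_set = set(nodes)
    out = set()
    for s in seeds:
        if s not in node_set:
            continue
        for v in node_set:
            if (s, v) in sp and sp[(s, v)] <= radius:
                out.add(v)
    return out


def density_cluster_bruteforce(dist: np.ndarray, ids: list, eps: float, min_pts: int):
    """Fixed-point density-reachability closure oracle.

    Core points have > min_pts neighbors within eps; clusters are computed by
    repeatedly merging the clusters of any two core points within eps until
    nothing changes. Border points join the cluster of their nearest core
    (ties toward the smallest canonical cluster id). Returns (labels, types)
    with labels canonicalized by smallest member id and -1 for noise.
    """
    n = len(ids)
    d = dist.copy().astype(float)
    d[np.isnan(d)] = np.inf
    np.fill_diagonal(d, 0.0)
    neighbor_counts = [int(((d[i] <= eps)).sum()) - 1 for i in range(n)]
    core = [neighbor_counts[i] > min_pts for i in range(n)]

    cluster = {i: i for i in range(n) if core[i]}  # core index -> provisional id
    changed = True
    while changed:
        changed = False
        for i in cluster:
            for j in cluster:
                if d[i, j] <= eps and cluster[i] != cluster[j]:
                    a, b = sorted((cluster[i], cluster[j]))
                    for k in cluster:
                        if cluster[k] == b:
                            cluster[k] = a
                    changed = True

    # canonicalize provisional ids by the smallest member gene id
    provisional = sorted(set(cluster.values()),
                         key=lambda c: min(ids[i] for i in cluster if cluster[i] == c))
    remap = {c: new for new, c in enumerate(provisional)}

    labels = [-1] * n
    types = ["noise"] * n
    for i, c in cluster.items():
        labels[i] = remap[c]
        types[i] = "core"
    for i in range(n):
        if core[i]:
            continue
        core_nb = [j for j in cluster if d[i, j] <= eps]
        if core_nb:
            best = min(core_nb, key=lambda j: (d[i, j], remap[cluster[j]]))
            labels[i] = remap[cluster[best]]
            types[i] = "border"
    return labels, types


def random_graph(rng: np.random.Generator, n: int, p: float):
    """Simple undirected G(n, p) as (nodes, edge set) with string node ids."""
    nodes = [f"v{i}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((nodes[i], nodes[j]))
    return nodes, edges
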