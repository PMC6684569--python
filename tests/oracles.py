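"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — explicit BFS, explicit enumeration
of all geodesics, explicit normal equations, exhaustive partition search —
and shares no code with the package implementation it checks.
"""

from itertools import combinations

import numpy as np


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted distances by per-source BFS (inf if unreachable)."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def brute_path_length(adj: np.ndarray) -> float:
    d = bfs_distances(adj)
    vals = [d[i, j] for i in range(len(adj)) for j in range(len(adj))
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals))


def brute_global_efficiency(adj: np.ndarray) -> float:
    d = bfs_distances(adj)
    n = len(adj)
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
            for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def brute_mean_degree(adj: np.ndarray) -> float:
    return float(adj.sum(axis=1).mean())


def _count_geodesics(adj, dist, s, t, via=None):
    """Number of shortest s-t paths (optionally passing through ``via``),
    by explicit DFS enumeration over distance-decreasing edges."""

    def walk(u, seen_via):
        if u == t:
            return 1 if (via is None or seen_via) else 0
        total = 0
        for v in range(len(adj)):
            if adj[u, v] and dist[v, t] == dist[u, t] - 1:
                total += walk(v, seen_via or v == via)
        return total

    return walk(s, s == via)


def brute_mean_betweenness(adj: np.ndarray, normalized: bool = True) -> float:
    """Mean betweenness by enumerating every geodesic of every pair."""
    n = len(adj)
    dist = bfs_distances(adj)
    bc = np.zeros(n)
    for v in range(n):
        for s, t in combinations(range(n), 2):
            if v in (s, t) or not np.isfinite(dist[s, t]):
                continue
            sigma = _count_geodesics(adj, dist, s, t)
            if sigma == 0:
                continue
            sigma_v = _count_geodesics(adj, dist, s, t, via=v)
            bc[v] += sigma_v / sigma
    if normalized:
        bc /= (n - 1) * (n - 2) / 2.0
    return float(bc.mean())


def brute_modularity_q(adj: np.ndarray, partition) -> float:
    """Q = sum_c (e_cc - a_c^2) from explicit edge counting."""
    m = adj.sum() / 2.0
    if m == 0:
        return 0.0
    q = 0.0
    for comm in partition:
        comm = set(comm)
        e_cc = sum(
            adj[i, j] for i in comm for j in comm if i < j
        ) / m
        a_c = sum(adj[i].sum() for i in comm) / (2.0 * m)
        q += e_cc - a_c**2
    return float(q)


def _set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_modularity(adj: np.ndarray) -> float:
    """Maximum Q over all partitions (feasible for <= ~8 nodes)."""
    best = -np.inf
    for part in _set_partitions(list(range(len(adj)))):
        best = max(best, brute_modularity_q(adj, part))
    return float(best)


def brute_lstsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Normal equations solved explicitly (independent of np.linalg.lstsq)."""
    return np.linalg.solve(A.T @ A, A.T @ b)


def brute_bh_flags(pvals, q):
    """BH step-up by checking every candidate rank explicitly."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k_star = i
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_star]] = True
    return flags


def random_graph(n: int, p: float, rng) -> np.ndarray:
    """Symmetric 0/1 adjacency with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a + a.T
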