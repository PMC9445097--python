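"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively (triple loops, exhaustive enumeration)
and on purpose shares no code with the package under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_clustering(adj: np.ndarray, rule: str = "exclude") -> float:
    """Mean local clustering by explicit triangle counting."""
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            if rule == "zero":
                vals.append(0.0)
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a], nbrs[b]]:
                    links += 1
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals))


def naive_mean_path_length(adj: np.ndarray) -> float:
    """Mean pairwise distance via Floyd–Warshall."""
    n = adj.shape[0]
    inf = float("inf")
    d = [[0 if i == j else (1 if adj[i, j] else inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    total, pairs = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            total += d[i][j]
            pairs += 1
    return total / pairs


def all_partitions(items: list):
    """Every set partition (Bell-number enumeration, recursive)."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1 :]
        yield [[head]] + part


def brute_force_max_modularity(adj: np.ndarray) -> float:
    """Global maximum of Newman–Girvan Q over ALL partitions (small n only)."""
    n = adj.shape[0]
    k_total = adj.sum() / 2.0
    deg = adj.sum(axis=1)
    best = -np.inf
    for part in all_partitions(list(range(n))):
        q = 0.0
        for block in part:
            e = adj[np.ix_(block, block)].sum() / 2.0
            d = deg[block].sum()
            q += e / k_total - (d / (2 * k_total)) ** 2
        best = max(best, q)
    return float(best)


def exact_rank_sum_two_sided_p(a: list, b: list) -> float:
    """Two-sided exact Mann–Whitney p by permuting group membership."""
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "tie-free only"
    n_a = len(a)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - n_a * (n_a + 1) / 2
    mn = n_a * len(b)
    lo, hi = min(u_obs, mn - u_obs), max(u_obs, mn - u_obs)
    count = total = 0
    for combo in itertools.combinations(pooled, n_a):
        u = sum(rank[v] for v in combo) - n_a * (n_a + 1) / 2
        total += 1
        if u <= lo or u >= hi:
            count += 1
    return count / total


def random_connected_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random connected 0/1 graph: a random spanning tree plus noise edges."""
    adj = np.zeros((n, n), dtype=int)
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[rng.integers(i)]
        adj[order[i], j] = adj[j, order[i]] = 1
    p = rng.uniform(0.05, 0.5)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = 1
    return adj
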