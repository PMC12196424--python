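"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the library code paths (and networkx algorithms)
they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_counts(highsets: dict[str, set[str]], regions: list[str],
                       gene_list: list[str]) -> dict[str, int]:
    """Per-region count of list genes flagging the region, by enumeration."""
    return {r: sum(1 for g in gene_list if r in highsets[g]) for r in regions}


def hypergeom_moments(G: int, m: int, X: int) -> tuple[float, float]:
    """Mean and SD of a Hypergeometric(G, m, X) count."""
    p = m / G
    mean = X * p
    var = X * p * (1 - p) * (G - X) / (G - 1) if G > 1 else 0.0
    return mean, var**0.5


def brute_force_strength(edges: list[tuple[str, str, float]],
                         nodes: list[str]) -> dict[str, float]:
    s = {v: 0.0 for v in nodes}
    for u, v, w in edges:
        s[u] += w
        s[v] += w
    return s


def brute_force_betweenness(
    nodes: list[str],
    edges: list[tuple[str, str, float]],
    distance_mode: str = "inverse_weight",
    normalized: bool = True,
) -> dict[str, float]:
    """Betweenness by exhaustive simple-path enumeration (graphs <= ~8 nodes).

    Distances accumulate left-to-right along each path, mirroring Dijkstra's
    incremental sums, so float ties behave identically to the checked
    implementation.
    """
    adj: dict[str, dict[str, float]] = {v: {} for v in nodes}
    for u, v, w in edges:
        if distance_mode == "inverse_weight":
            d = 1.0 / w
        elif distance_mode == "weight_as_cost":
            d = float(w)
        elif distance_mode == "unweighted":
            d = 1.0
        else:
            raise ValueError(distance_mode)
        adj[u][v] = d
        adj[v][u] = d

    def all_paths(s: str, t: str):
        """Yield (distance, interior-node tuple) for every simple s->t path."""
        stack = [(s, 0.0, (s,))]
        while stack:
            node, dist, path = stack.pop()
            if node == t:
                yield dist, path[1:-1]
                continue
            for nxt, d in adj[node].items():
                if nxt not in path:
                    stack.append((nxt, dist + d, path + (nxt,)))

    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(all_paths(s, t))
        if not paths:
            continue
        best = min(d for d, _ in paths)
        shortest = [interior for d, interior in paths if d == best]
        sigma = len(shortest)
        for interior in shortest:
            for v in interior:
                bc[v] += 1.0 / sigma
    n = len(nodes)
    if normalized and n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bc = {v: b * scale for v, b in bc.items()}
    return bc


def random_weighted_graph(rng: np.random.Generator, n_nodes: int,
                          p_edge: float, weights: tuple[int, ...] = (1, 2, 4, 8)):
    """(nodes, edges) with weights drawn from ``weights``.

    The default power-of-two weights make both the weights and their
    reciprocals exact dyadic floats, so shortest-path ties are exact and
    independent of summation order — a brute-force path enumeration and a
    Dijkstra-based implementation then agree bit-for-bit on tie counting.
    """
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            edges.append((nodes[i], nodes[j], int(rng.choice(weights))))
    return nodes, edges
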