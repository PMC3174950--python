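"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's optimized code paths: the MCL
oracle works on dense numpy arrays with plain python-loop cluster
extraction, and the hypergeometric oracle sums binomial coefficients in
exact integer arithmetic.
"""
from __future__ import annotations

import math

import numpy as np


def dense_mcl_clusters(
    graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iterations: int = 100,
):
    """Straightforward dense-matrix MCL; returns sorted frozenset clusters."""
    nodes = sorted(graph.nodes())
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        adj[index[u], index[v]] = adj[index[v], index[u]] = w
    for i in range(n):
        incident = adj[i][adj[i] > 0]
        adj[i, i] = incident.max() if incident.size else 1.0

    def column_normalize(matrix):
        sums = matrix.sum(axis=0)
        sums[sums == 0] = 1.0
        return matrix / sums

    flow = column_normalize(adj)
    for _ in range(max_iterations):
        previous = flow.copy()
        expanded = np.linalg.matrix_power(flow, expansion)
        flow = column_normalize(expanded ** inflation)
        flow[flow < prune] = 0.0
        flow = column_normalize(flow)
        if np.abs(flow - previous).max() < tol:
            break

    groups: list[set[int]] = []
    for attractor in range(n):
        if flow[attractor, attractor] <= 0:
            continue
        members = set(np.flatnonzero(flow[attractor] > 0)) | {attractor}
        merged, kept = set(members), []
        for group in groups:
            if group & merged:
                merged |= group
            else:
                kept.append(group)
        groups = kept + [merged]
    covered = set().union(*groups) if groups else set()
    groups.extend({i} for i in range(n) if i not in covered)
    return sorted((frozenset(nodes[i] for i in g) for g in groups), key=min)


def naive_hypergeom_tail(c: int, m: int, N: int, M: int) -> float:
    """Exact upper-tail hypergeometric by integer term-by-term summation."""
    total = 0
    for k in range(m, min(c, M) + 1):
        if c - k <= N - M:
            total += math.comb(M, k) * math.comb(N - M, c - k)
    return total / math.comb(N, c)
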