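"""Degree-preserving pseudorandom networks via double-edge swaps.

The null model keeps every node's connectivity while reallocating edges
at random: repeatedly pick two distinct edges (a,b), (c,d) and rewire
them to (a,d), (c,b), rejecting any swap that would create a self-loop
or a duplicate edge. The node set, edge count and the exact degree of
every node are invariant under this chain; a conventional mixing
heuristic of 10 accepted swaps per edge is the default intensity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np


@dataclass
class RewireConfig:
    swaps_per_edge: int = 10
    seed: int = 0
    max_tries_factor: int = 100

    def __post_init__(self) -> None:
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")
        if self.max_tries_factor < 1:
            raise ValueError("max_tries_factor must be >= 1")


def rewire(graph: nx.Graph, config: RewireConfig | None = None) -> nx.Graph:
    """Return a degree-preserving randomization of ``graph``.

    Performs swaps_per_edge * |E| accepted double-edge swaps, attempting
    at most max_tries_factor times that many candidates; if the target
    is not reached (rigid graphs such as a 2-edge path admit no valid
    swap) the partially rewired network is returned with a warning.
    Deterministic for a fixed seed; weights travel with the rewired
    edge's first endpoint pair.
    """
    config = config or RewireConfig()
    n_edges = graph.number_of_edges()
    if n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(config.seed)

    edges = [tuple(sorted(e)) for e in graph.edges()]
    edges.sort()
    weights = {e: graph[e[0]][e[1]].get("weight", 1.0) for e in edges}
    edge_set = set(edges)

    target = config.swaps_per_edge * n_edges
    max_tries = config.max_tries_factor * target
    accepted = tries = 0
    while accepted < target and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:  # random orientation of the second edge
            c, d = d, c
        # proposed replacement: (a,d) and (c,b)
        if a == d or c == b:
            continue
        e1, e2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        if e1 == e2 or e1 in edge_set or e2 in edge_set:
            continue
        old1, old2 = edges[i], edges[j]
        edge_set.remove(old1)
        edge_set.remove(old2)
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
        w1, w2 = weights.pop(old1), weights.pop(old2)
        weights[e1], weights[e2] = w1, w2
        accepted += 1
    if accepted < target:
        warnings.warn(
            f"rewire: accepted {accepted}/{target} swaps after {tries} attempts",
            stacklevel=2,
        )

    out = nx.Graph()
    out.add_nodes_from(graph.nodes())
    for u, v in edges:
        out.add_edge(u, v, weight=weights[(u, v)])
    return out
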