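"""Reconstruction of time-course protein interaction networks.

Two steps: (i) threshold the expression matrix at every time point to
obtain the active gene sets S_1..S_T (strictly greater than the cutoff;
probe-level rows are first collapsed to genes), then (ii) keep each
static interaction whose two endpoints are both active at a time point.
The result is one subnetwork of the static network per time point, with
nodes present only through retained interactions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix


@dataclass
class FilterConfig:
    """Expression filter: fixed per-time-point cutoff, probe aggregation rule."""

    threshold: float = 0.7
    aggregation: str = "max"  # probe -> gene collapse: "max" or "mean"

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.aggregation not in ("max", "mean"):
            raise ValueError("aggregation must be 'max' or 'mean'")


@dataclass
class ActiveGeneSets:
    """Per-time-point active gene sets S_1..S_T."""

    sets: list[set[str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, t: int) -> set[str]:
        return self.sets[t]

    def sizes(self) -> list[int]:
        return [len(s) for s in self.sets]

    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s
        return out


def aggregate_probes(matrix: ExpressionMatrix, aggregation: str = "max") -> pd.DataFrame:
    """Collapse probe rows to gene rows via the probe map (max or mean).

    Probes without a gene mapping are dropped. Without a probe map the
    matrix is returned unchanged (rows are already genes).
    """
    if matrix.probe_to_gene is None:
        return matrix.data
    mapped = matrix.data.loc[matrix.data.index.isin(matrix.probe_to_gene)]
    genes = mapped.index.map(matrix.probe_to_gene)
    grouped = mapped.groupby(genes, sort=True)
    return grouped.max() if aggregation == "max" else grouped.mean()


def filter_expression(matrix: ExpressionMatrix, config: FilterConfig | None = None) -> ActiveGeneSets:
    """Active gene sets: g in S_t iff aggregated expression(g, t) > threshold."""
    config = config or FilterConfig()
    data = aggregate_probes(matrix, config.aggregation)
    if data.shape[0] == 0 or data.shape[1] == 0:
        raise ValueError("cannot filter an empty expression matrix")
    values = data.to_numpy(dtype=float)
    genes = np.asarray(data.index)
    active = values > config.threshold  # strict: boundary values excluded
    return ActiveGeneSets([set(genes[active[:, t]]) for t in range(values.shape[1])])


def build_tcpins(static: nx.Graph, active: ActiveGeneSets) -> list[nx.Graph]:
    """One network per time point: edges whose endpoints are both active.

    Nodes enter a time-course network only as endpoints of retained
    interactions (no isolated nodes); edge weights are inherited from
    the static network.
    """
    tcpins = []
    for genes in active:
        sub = nx.Graph()
        for u, v, data in static.edges(data=True):
            if u in genes and v in genes:
                sub.add_edge(u, v, **data)
        tcpins.append(sub)
    return tcpins


def network_summary(graph: nx.Graph) -> dict[str, float]:
    """Topological summary: nodes, edges, average degree, density,
    global clustering coefficient (transitivity), components."""
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    if n == 0:
        return {
            "nodes": 0, "edges": 0, "avg_degree": 0.0, "density": 0.0,
            "clustering": 0.0, "components": 0,
        }
    return {
        "nodes": n,
        "edges": m,
        "avg_degree": 2.0 * m / n,
        "density": nx.density(graph),
        "clustering": nx.transitivity(graph),
        "components": nx.number_connected_components(graph),
    }
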