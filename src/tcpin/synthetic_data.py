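"""Synthetic planted-complex datasets for end-to-end testing.

The generator emulates the statistical structure the pipeline assumes:
a protein network containing dense planted complexes over a sparse
background, a periodic expression matrix in which the members of each
planted complex are simultaneously active in overlapping time windows,
a benchmark catalogue listing exactly the planted complexes, and a toy
GO-style annotation set with one private term per complex.

Expression follows a rectified sine over the metabolic-cycle grid: with
T = 36 time points and a 12-point period there are three consecutive
cycles, and complexes are assigned one of three canonical phases in
rotation, mimicking expression programs peaking in different phases of
the cycle. All generators are deterministic for a fixed seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import AnnotationSet, BenchmarkComplexSet, ExpressionMatrix

ROOT_TERM = "GO:0000001"


@dataclass
class SyntheticSpec:
    """Parameters of the planted-complex generator.

    Defaults are the study conditions used throughout the test suite:
    10 planted complexes of 4-10 proteins wired at p_within = 0.9 over a
    100-protein background at p_background = 0.01, expressed over 36
    time points with a 12-point cycle, and an activity threshold of 0.7
    on a baseline-0.3 / amplitude-1.6 signal (peak 1.9, comfortably
    above threshold; background stays below it).
    """

    n_complexes: int = 10
    complex_size_range: tuple[int, int] = (4, 10)
    p_within: float = 0.9
    n_background: int = 100
    p_background: float = 0.01
    T: int = 36
    period: int = 12
    amplitude: float = 1.6
    baseline: float = 0.3
    noise_sd: float = 0.1
    active_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ValueError("complex_size_range must satisfy 2 <= min <= max")
        if not (0 < self.p_background < self.p_within <= 1):
            raise ValueError("require 0 < p_background < p_within <= 1")
        if self.T < 1 or self.period < 1:
            raise ValueError("T and period must be positive")
        if self.T % self.period != 0:
            warnings.warn(
                f"period {self.period} does not divide T={self.T}; cycles will be truncated",
                stacklevel=2,
            )
        if self.noise_sd < 0 or self.amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitude, baseline and noise_sd must be nonnegative")


def make_network(spec: SyntheticSpec) -> tuple[nx.Graph, BenchmarkComplexSet]:
    """Plant dense Erdos-Renyi complex blocks over a sparse background.

    Every pair inside a planted complex is wired with probability
    ``p_within``; every other pair (background-background, background-
    complex and cross-complex) with probability ``p_background``. The
    returned benchmark lists exactly the planted complexes.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_complexes)

    complexes: dict[str, frozenset[str]] = {}
    membership: dict[str, str] = {}
    nodes: list[str] = []
    for k, size in enumerate(sizes):
        name = f"PLANTED{k:02d}"
        members = [f"C{k:02d}P{j:02d}" for j in range(size)]
        complexes[name] = frozenset(members)
        for m in members:
            membership[m] = name
        nodes.extend(members)
    nodes.extend(f"BG{j:03d}" for j in range(spec.n_background))

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    n = len(nodes)
    for a in range(n):
        for b in range(a + 1, n):
            u, v = nodes[a], nodes[b]
            same_complex = membership.get(u) is not None and membership.get(u) == membership.get(v)
            p = spec.p_within if same_complex else spec.p_background
            if rng.random() < p:
                graph.add_edge(u, v, weight=1.0)
    return graph, BenchmarkComplexSet(dict(complexes))


def _signal(spec: SyntheticSpec, phase: float) -> np.ndarray:
    t = np.arange(spec.T)
    return spec.baseline + spec.amplitude * np.maximum(
        0.0, np.sin(2 * np.pi * (t - phase) / spec.period)
    )


def complex_phases(spec: SyntheticSpec) -> dict[str, float]:
    """Canonical phase per complex: three phases a third of a cycle apart."""
    phases = [0.0, spec.period / 3.0, 2.0 * spec.period / 3.0]
    names = [f"PLANTED{k:02d}" for k in range(spec.n_complexes)]
    return {name: phases[k % 3] for k, name in enumerate(names)}


def make_expression(
    spec: SyntheticSpec,
    network: nx.Graph,
    complexes: BenchmarkComplexSet,
    max_retries: int = 100,
) -> ExpressionMatrix:
    """Periodic expression for complex members, flat noise for background.

    Member genes follow ``baseline + amplitude * max(0, sin(...))`` at
    their complex's phase plus truncated Gaussian noise; background
    genes get baseline plus noise. Whenever the noiseless peak exceeds
    ``active_threshold`` the generator guarantees (resampling noise up
    to ``max_retries`` times per complex, then raising) that every
    complex has at least one time point at which all members are
    strictly above threshold. Configurations whose noiseless signal
    never reaches threshold are returned as-is: no amount of resampling
    could make them co-active, and an all-inactive matrix is itself a
    meaningful degenerate condition.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = sorted(network.nodes())
    gene_to_complex: dict[str, str] = {}
    for name, members in complexes.complexes.items():
        for g in members:
            gene_to_complex[g] = name
    phases = complex_phases(spec)

    values = np.empty((len(genes), spec.T))
    for i, gene in enumerate(genes):
        name = gene_to_complex.get(gene)
        base = _signal(spec, phases[name]) if name is not None else np.full(spec.T, spec.baseline)
        values[i] = np.maximum(0.0, base + rng.normal(0.0, spec.noise_sd, size=spec.T))

    enforce = spec.baseline + spec.amplitude > spec.active_threshold
    if enforce:
        index = {g: i for i, g in enumerate(genes)}
        for name, members in sorted(complexes.complexes.items()):
            rows = [index[g] for g in sorted(members) if g in index]
            base = _signal(spec, phases[name])
            for attempt in range(max_retries + 1):
                block = values[rows]
                if (block > spec.active_threshold).all(axis=0).any():
                    break
                if attempt == max_retries:
                    raise RuntimeError(
                        f"could not make complex {name} co-active after {max_retries} retries"
                    )
                noise = rng.normal(0.0, spec.noise_sd, size=(len(rows), spec.T))
                values[rows] = np.maximum(0.0, base[None, :] + noise)

    labels = [f"t{j + 1:02d}" for j in range(spec.T)]
    frame = pd.DataFrame(values, index=genes, columns=labels)
    return ExpressionMatrix(frame)


def make_annotations(
    complexes: BenchmarkComplexSet,
    n_noise_terms: int = 5,
    seed: int = 0,
    all_genes: set[str] | None = None,
) -> AnnotationSet:
    """Toy annotation set: one private term per planted complex.

    Each complex gets a synthetic term annotating exactly its members;
    ``n_noise_terms`` extra terms annotate random genes. The DAG is flat
    (every term a child of one root) and the root annotates every gene,
    so the root's enrichment P-value is always 1.
    """
    rng = np.random.default_rng(seed)
    genes: set[str] = set(all_genes) if all_genes is not None else set()
    for members in complexes.complexes.values():
        genes |= members
    gene_list = sorted(genes)

    dag: dict[str, set[str]] = {ROOT_TERM: set()}
    direct: dict[str, set[str]] = {g: {ROOT_TERM} for g in gene_list}
    for k, name in enumerate(sorted(complexes.complexes)):
        term = f"GO:1{k:06d}"
        dag[term] = {ROOT_TERM}
        for g in complexes.complexes[name]:
            direct.setdefault(g, {ROOT_TERM}).add(term)
    for j in range(n_noise_terms):
        term = f"GO:2{j:06d}"
        dag[term] = {ROOT_TERM}
        size = int(rng.integers(3, max(4, min(10, len(gene_list)))))
        for g in rng.choice(gene_list, size=min(size, len(gene_list)), replace=False):
            direct[g].add(term)
    return AnnotationSet(ontology="BP", direct=direct, dag=dag)


def planted_term_map(complexes: BenchmarkComplexSet) -> dict[str, str]:
    """Map planted complex name -> its private synthetic term ID."""
    return {name: f"GO:1{k:06d}" for k, name in enumerate(sorted(complexes.complexes))}


def write_gaf(annotations: AnnotationSet, path) -> None:
    """Write direct annotations as a minimal GAF 2.1 file."""
    aspect = {"BP": "P", "MF": "F", "CC": "C"}[annotations.ontology]
    with open(path, "w") as handle:
        handle.write("!gaf-version: 2.1\n")
        for gene in sorted(annotations.direct):
            for term in sorted(annotations.direct[gene]):
                cols = [
                    "SYN", gene, gene, "", term, "PMID:0", "IEA", "", aspect,
                    gene, "", "protein", "taxon:4932", "20100101", "SYN", "", "",
                ]
                handle.write("\t".join(cols) + "\n")


def write_obo(annotations: AnnotationSet, path) -> None:
    """Write the term DAG as a minimal OBO 1.2 file."""
    namespace = {
        "BP": "biological_process",
        "MF": "molecular_function",
        "CC": "cellular_component",
    }[annotations.ontology]
    with open(path, "w") as handle:
        handle.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(annotations.dag):
            handle.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            handle.write(f"namespace: {namespace}\n")
            for parent in sorted(annotations.dag[term]):
                handle.write(f"is_a: {parent} ! parent\n")
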