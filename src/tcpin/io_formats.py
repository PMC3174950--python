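"""Readers, writers and shared domain containers.

Every external format the pipeline touches comes through this module:
plain edge-list TSV for protein interaction networks, a header-first
expression matrix TSV, a two-column probe-to-gene map, a CYC2008-style
complex catalogue, GAF 2.x annotation files together with an OBO 1.2
ontology, and the module TSV used to persist clustering output.

All readers accept ``#``-prefixed comment lines and blank lines.
Networks are held as :class:`networkx.Graph`; the readers guarantee the
invariants the rest of the pipeline relies on (no self-loops, no
duplicate edges, strictly positive weights).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

STATIC = "static"
RANDOM = "random"

#: GAF aspect column code -> ontology domain
_ASPECT_TO_ONTOLOGY = {"P": "BP", "F": "MF", "C": "CC"}
_ONTOLOGY_TO_NAMESPACE = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _data_lines(path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping comments/blanks."""
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# Interaction networks
# ---------------------------------------------------------------------------

def read_edge_list(path, has_weights: bool = False) -> nx.Graph:
    """Read an undirected protein interaction network from 2/3-column TSV.

    Self-interactions are dropped and duplicated interactions collapsed
    (the first weight seen wins); the counts of dropped records are
    logged. Returns a simple undirected :class:`networkx.Graph` whose
    edges carry a ``weight`` attribute (1.0 when ``has_weights`` is
    false).
    """
    graph = nx.Graph()
    n_self = n_dup = 0
    seen_any = False
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}")
        seen_any = True
        u, v = fields[0], fields[1]
        if u == v:
            n_self += 1
            continue
        if graph.has_edge(u, v):
            n_dup += 1
            continue
        if has_weights:
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: weight column missing")
            try:
                weight = float(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from exc
            if weight <= 0:
                raise FormatError(f"{path}:{lineno}: weight must be strictly positive")
        else:
            weight = 1.0
        graph.add_edge(u, v, weight=weight)
    if not seen_any:
        raise FormatError(f"{path}: empty edge list")
    if n_self or n_dup:
        logger.info("read_edge_list(%s): dropped %d self-loops, %d duplicates", path, n_self, n_dup)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    """Write a network as sorted 3-column TSV (u, v, weight)."""
    with open(path, "w") as handle:
        for u, v in sorted((tuple(sorted(e)) for e in graph.edges()), key=lambda e: (e[0], e[1])):
            weight = graph[u][v].get("weight", 1.0)
            handle.write(f"{u}\t{v}\t{weight:g}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes/probes x time points of nonnegative expression levels.

    ``data`` is indexed by row (probe or gene) identifier with one column
    per time-point label. ``probe_to_gene``, when present, maps probe IDs
    to gene symbols and triggers probe aggregation during filtering.
    """

    data: pd.DataFrame
    probe_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate row identifier {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise FormatError("expression values must be finite")
        if values.size and (values < 0).any():
            raise FormatError("expression values must be nonnegative")
        if self.data.shape[1] < 1:
            raise FormatError("expression matrix needs at least one time point")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def read_expression_matrix(path, probe_to_gene: dict[str, str] | None = None) -> ExpressionMatrix:
    """Read a TSV whose first row holds T time labels, then ID + T numbers."""
    lines = list(_data_lines(path))
    if not lines:
        raise FormatError(f"{path}: empty expression matrix")
    header = lines[0][1].split("\t")
    # header may or may not carry a leading cell for the ID column
    time_labels = header[1:] if len(header) > 1 and header[0].lower() in {"", "id", "gene", "probe"} else header
    n_t = len(time_labels)
    if n_t < 1:
        raise FormatError(f"{path}: header declares no time points")
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != n_t + 1:
            raise FormatError(
                f"{path}:{lineno}: row {fields[0]!r} has {len(fields) - 1} values, expected {n_t}"
            )
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell in row {fields[0]!r}") from exc
        row_ids.append(fields[0])
    if len(set(row_ids)) != len(row_ids):
        dup = next(r for r in row_ids if row_ids.count(r) > 1)
        raise FormatError(f"{path}: duplicate row identifier {dup!r}")
    frame = pd.DataFrame(rows, index=row_ids, columns=time_labels, dtype=float)
    return ExpressionMatrix(frame, probe_to_gene=probe_to_gene)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="id", float_format="%g")


def read_probe_map(path) -> dict[str, str]:
    """Read a two-column probe -> gene TSV.

    Probes with a blank gene symbol are omitted (count logged); a probe
    mapped to two different genes is an error.
    """
    mapping: dict[str, str] = {}
    n_omitted = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        probe = fields[0].strip()
        gene = fields[1].strip() if len(fields) > 1 else ""
        if not gene:
            n_omitted += 1
            continue
        if probe in mapping and mapping[probe] != gene:
            raise FormatError(
                f"{path}:{lineno}: probe {probe!r} maps to both {mapping[probe]!r} and {gene!r}"
            )
        mapping[probe] = gene
    if n_omitted:
        logger.info("read_probe_map(%s): omitted %d probes without gene symbol", path, n_omitted)
    return mapping


# ---------------------------------------------------------------------------
# Benchmark complexes
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkComplexSet:
    """Named reference protein complexes, each with >= 2 members."""

    complexes: dict[str, frozenset[str]]
    n_filtered: int = 0

    def __post_init__(self) -> None:
        for name, members in self.complexes.items():
            if len(members) < 2:
                raise FormatError(f"benchmark complex {name!r} has fewer than 2 members")

    def __len__(self) -> int:
        return len(self.complexes)


def read_complexes(path) -> BenchmarkComplexSet:
    """Read a CYC2008-like TSV (complex_id, protein per line).

    Complexes with fewer than 2 members are filtered out; the filtered
    count is reported on the returned object and logged.
    """
    raw: dict[str, set[str]] = {}
    seen_any = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected complex_id<TAB>protein")
        seen_any = True
        raw.setdefault(fields[0], set()).add(fields[1])
    if not seen_any:
        raise FormatError(f"{path}: empty complex catalogue")
    kept = {name: frozenset(members) for name, members in raw.items() if len(members) >= 2}
    n_filtered = len(raw) - len(kept)
    if n_filtered:
        logger.info("read_complexes(%s): filtered %d complexes with <2 members", path, n_filtered)
    return BenchmarkComplexSet(kept, n_filtered=n_filtered)


def write_complexes(benchmark: BenchmarkComplexSet, path) -> None:
    with open(path, "w") as handle:
        for name in sorted(benchmark.complexes):
            for protein in sorted(benchmark.complexes[name]):
                handle.write(f"{name}\t{protein}\n")


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Direct GO annotations plus the term DAG for one ontology domain.

    ``direct`` maps gene -> set of directly annotated term IDs; ``dag``
    maps term -> set of parent terms (is_a and part_of), restricted to
    the requested namespace. The DAG must be acyclic.
    """

    ontology: str
    direct: dict[str, set[str]]
    dag: dict[str, set[str]]

    def __post_init__(self) -> None:
        if self.ontology not in _ONTOLOGY_TO_NAMESPACE:
            raise ValueError(f"ontology must be one of BP/MF/CC, got {self.ontology!r}")
        for gene, terms in self.direct.items():
            missing = terms - self.dag.keys()
            if missing:
                raise FormatError(f"gene {gene!r} annotated to unknown term(s) {sorted(missing)}")

    @property
    def genes(self) -> set[str]:
        return set(self.direct)


def read_annotations(gaf_path, obo_path, ontology: str) -> AnnotationSet:
    """Read a GAF 2.x file and an OBO 1.2 ontology for one GO domain.

    Only rows whose aspect column matches the requested ontology are
    kept; NOT-qualified rows are excluded; obsolete terms and terms
    outside the requested namespace are skipped. Gene identifiers are
    taken from the DB Object Symbol column.
    """
    if ontology not in _ONTOLOGY_TO_NAMESPACE:
        raise ValueError(f"ontology must be one of BP/MF/CC, got {ontology!r}")
    namespace = _ONTOLOGY_TO_NAMESPACE[ontology]
    # obonet drops obsolete terms by default; edges run child -> parent.
    obo_graph = obonet.read_obo(obo_path)
    dag: dict[str, set[str]] = {}
    for term, data in obo_graph.nodes(data=True):
        if data.get("namespace", namespace) != namespace:
            continue
        parents: set[str] = set()
        for _, parent, key in obo_graph.out_edges(term, keys=True):
            if key in ("is_a", "part_of") and obo_graph.nodes[parent].get("namespace", namespace) == namespace:
                parents.add(parent)
        dag[term] = parents

    direct: dict[str, set[str]] = {}
    n_skipped = 0
    for lineno, line in _data_lines(gaf_path):
        if line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise FormatError(f"{gaf_path}:{lineno}: GAF row has {len(fields)} columns, expected >= 9")
        qualifier, term, aspect = fields[3], fields[4], fields[8]
        gene = fields[2]
        if "NOT" in qualifier.split("|"):
            continue
        if aspect not in _ASPECT_TO_ONTOLOGY:
            logger.warning("%s:%d: unknown aspect code %r, skipping", gaf_path, lineno, aspect)
            continue
        if _ASPECT_TO_ONTOLOGY[aspect] != ontology:
            continue
        if term not in dag:
            n_skipped += 1
            continue
        direct.setdefault(gene, set()).add(term)
    if n_skipped:
        logger.info("read_annotations(%s): skipped %d rows to obsolete/foreign terms", gaf_path, n_skipped)
    return AnnotationSet(ontology=ontology, direct=direct, dag=dag)


# ---------------------------------------------------------------------------
# Module sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Module:
    """One predicted module with its provenance."""

    proteins: frozenset[str]
    time_point: int | str  # 0-based time index, or "static"/"random"
    cluster_index: int

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("module must be nonempty")

    @property
    def size(self) -> int:
        return len(self.proteins)

    def sort_key(self) -> tuple:
        tp = self.time_point
        # integer time points sort before the sentinels, sentinels lexicographic
        return (isinstance(tp, str), tp, self.cluster_index)


@dataclass
class ModuleSet:
    """Ordered collection of predicted modules."""

    modules: list[Module] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(m.time_point, m.cluster_index) for m in self.modules]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (time_point, cluster_index) in ModuleSet")

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[Module]:
        return iter(self.modules)

    def protein_sets(self) -> list[frozenset[str]]:
        return [m.proteins for m in self.modules]

    def sizes(self) -> list[int]:
        return [m.size for m in self.modules]


def _parse_time_point(token: str) -> int | str:
    if token in (STATIC, RANDOM):
        return token
    try:
        return int(token)
    except ValueError as exc:
        raise FormatError(f"invalid time point {token!r}") from exc


def write_modules(module_set: ModuleSet, path) -> None:
    """One module per line: time_point TAB cluster_index TAB sorted,comma-joined IDs."""
    with open(path, "w") as handle:
        for module in module_set:
            proteins = ",".join(sorted(module.proteins))
            handle.write(f"{module.time_point}\t{module.cluster_index}\t{proteins}\n")


def read_modules(path) -> ModuleSet:
    modules = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
        try:
            cluster_index = int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: invalid cluster index {fields[1]!r}") from exc
        proteins = frozenset(p for p in fields[2].split(",") if p)
        if not proteins:
            raise FormatError(f"{path}:{lineno}: empty module")
        modules.append(Module(proteins, _parse_time_point(fields[0]), cluster_index))
    return ModuleSet(modules)
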