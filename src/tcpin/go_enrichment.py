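"""Hypergeometric GO-term enrichment of protein modules.

For a module of size c (annotated members) drawn from a population of N
annotated proteins, M of which carry term A, the enrichment P-value is
the upper hypergeometric tail

    P = sum_{k=m}^{min(c, M)} C(M, k) C(N-M, c-k) / C(N, c)

i.e. the chance of seeing m or more carriers of A in the module by
random draw. Annotations are first propagated up the ontology DAG
(a gene annotated to a term carries all its ancestors), every term with
at least one annotated module member is tested, and the per-module
Bonferroni correction multiplies the best raw P by the number of terms
tested. A module is significant when its corrected P is at or below the
0.01 cutoff. The summation is carried out in log space so it stays
stable for populations of thousands of proteins.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.special import gammaln, logsumexp

from .io_formats import AnnotationSet

#: P-value interval edges for the enrichment report bins
_BIN_EDGES = (1e-15, 1e-10, 1e-5, 0.01)
BIN_LABELS = ("<1e-15", "[1e-15,1e-10)", "[1e-10,1e-5)", "[1e-5,0.01)", ">=0.01")


def propagate_annotations(annotations: AnnotationSet) -> AnnotationSet:
    """Close every gene's term set under ancestor relations in the DAG."""
    ancestors: dict[str, set[str]] = {}
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(term: str, stack: list[str]) -> set[str]:
        if term in ancestors:
            return ancestors[term]
        if state.get(term) == 0:
            raise ValueError(f"cycle in ontology DAG through {term!r}")
        state[term] = 0
        closure: set[str] = set()
        for parent in annotations.dag.get(term, ()):
            closure.add(parent)
            closure |= visit(parent, stack)
        state[term] = 1
        ancestors[term] = closure
        return closure

    for term in annotations.dag:
        visit(term, [])
    direct = {
        gene: set().union(terms, *(ancestors[t] for t in terms))
        for gene, terms in annotations.direct.items()
    }
    return AnnotationSet(ontology=annotations.ontology, direct=direct, dag=dict(annotations.dag))


def hypergeom_pvalue(c: int, m: int, N: int, M: int) -> float:
    """Upper-tail hypergeometric P(X >= m) computed in log space."""
    if not (0 <= M <= N and 0 <= c <= N):
        raise ValueError(f"require 0 <= M <= N and 0 <= c <= N, got c={c} m={m} N={N} M={M}")
    if not 0 <= m <= min(c, M):
        raise ValueError(f"require 0 <= m <= min(c, M), got c={c} m={m} N={N} M={M}")
    if m == 0:
        return 1.0

    def log_comb(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    denom = log_comb(N, c)
    terms = [
        log_comb(M, k) + log_comb(N - M, c - k) - denom
        for k in range(m, min(c, M) + 1)
        if c - k <= N - M
    ]
    if not terms:
        return 0.0
    return float(min(1.0, math.exp(logsumexp(terms))))


@dataclass
class EnrichmentResult:
    """Best GO term of one module within one ontology."""

    module_id: str
    ontology: str
    best_term: str | None
    raw_p: float
    corrected_p: float
    significant: bool
    n_terms_tested: int
    module_size: int


def enrich_module(
    module: Iterable[str],
    annotations: AnnotationSet,
    population: set[str],
    alpha: float = 0.01,
    module_id: str = "",
    propagated: bool = False,
) -> EnrichmentResult:
    """Best-term enrichment of one module against a gene population.

    ``population`` is the background universe (N = its size); module
    members outside it or without annotation do not count towards c.
    Every term annotating at least one module member is tested; the
    Bonferroni-corrected P is min(1, raw_p * n_terms_tested) and the
    best term is the one with the smallest corrected P (ties broken by
    term ID). A module with no annotated member yields best_term=None.
    """
    if not propagated:
        annotations = propagate_annotations(annotations)
    members = set(module) & population & annotations.genes
    n_pop = len(population)
    result_base = dict(
        module_id=module_id,
        ontology=annotations.ontology,
        module_size=len(set(module)),
    )
    if not members or n_pop == 0:
        return EnrichmentResult(
            best_term=None, raw_p=1.0, corrected_p=1.0,
            significant=False, n_terms_tested=0, **result_base,
        )

    term_members: dict[str, int] = {}
    for gene in members:
        for term in annotations.direct[gene]:
            term_members[term] = term_members.get(term, 0) + 1
    term_population: dict[str, int] = {}
    for gene in population & annotations.genes:
        for term in annotations.direct[gene]:
            term_population[term] = term_population.get(term, 0) + 1

    c = len(members)
    best: tuple[float, float, str] | None = None
    for term in sorted(term_members):
        m = term_members[term]
        big_m = term_population[term]
        raw = hypergeom_pvalue(c=c, m=m, N=n_pop, M=big_m)
        corrected = min(1.0, raw * len(term_members))
        if best is None or (corrected, term) < (best[0], best[2]):
            best = (corrected, raw, term)
    corrected_p, raw_p, best_term = best
    return EnrichmentResult(
        best_term=best_term,
        raw_p=raw_p,
        corrected_p=corrected_p,
        significant=corrected_p <= alpha,
        n_terms_tested=len(term_members),
        **result_base,
    )


def enrich_modules(
    modules: Sequence[Iterable[str]],
    annotations: AnnotationSet,
    population: set[str],
    alpha: float = 0.01,
    min_size: int = 3,
) -> list[EnrichmentResult]:
    """Enrichment of every module of at least ``min_size`` proteins."""
    annotations = propagate_annotations(annotations)
    results = []
    for idx, module in enumerate(modules):
        module = set(module)
        if len(module) < min_size:
            continue
        results.append(
            enrich_module(
                module, annotations, population,
                alpha=alpha, module_id=str(idx), propagated=True,
            )
        )
    return results


def build_population(
    genes: Iterable[str],
    annotations: AnnotationSet,
    population_mode: str = "annotated",
) -> set[str]:
    """Background universe: annotated genes among ``genes`` (default) or all."""
    genes = set(genes)
    if population_mode == "annotated":
        return genes & annotations.genes
    if population_mode == "all":
        return genes
    raise ValueError("population_mode must be 'annotated' or 'all'")


@dataclass
class EnrichmentReport:
    """Summary of a batch of enrichment results (one ontology)."""

    ontology: str
    n_modules: int
    n_significant: int
    proportion_significant: float
    avg_neglog10_p: float
    bin_counts: dict[str, int] = field(default_factory=dict)
    bin_proportions: dict[str, float] = field(default_factory=dict)


def enrichment_report(results: Sequence[EnrichmentResult]) -> EnrichmentReport:
    """Significant-module proportion, average -log10(P) and interval bins.

    Bins on the corrected P-value: <1e-15, [1e-15,1e-10), [1e-10,1e-5),
    [1e-5,0.01) and >=0.01; proportions are over all modules summarised.
    """
    if not results:
        raise ValueError("no enrichment results to summarise")
    n = len(results)
    n_significant = sum(r.significant for r in results)
    # floor corrected P at tiny positive value so -log10 stays finite
    avg = sum(-math.log10(max(r.corrected_p, 1e-300)) for r in results) / n

    counts = dict.fromkeys(BIN_LABELS, 0)
    for r in results:
        p = r.corrected_p
        if p < _BIN_EDGES[0]:
            label = BIN_LABELS[0]
        elif p < _BIN_EDGES[1]:
            label = BIN_LABELS[1]
        elif p < _BIN_EDGES[2]:
            label = BIN_LABELS[2]
        elif p < _BIN_EDGES[3]:
            label = BIN_LABELS[3]
        else:
            label = BIN_LABELS[4]
        counts[label] += 1
    return EnrichmentReport(
        ontology=results[0].ontology,
        n_modules=n,
        n_significant=n_significant,
        proportion_significant=n_significant / n,
        avg_neglog10_p=avg,
        bin_counts=counts,
        bin_proportions={k: v / n for k, v in counts.items()},
    )
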