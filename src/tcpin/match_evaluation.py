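"""Matching predicted modules against a benchmark complex catalogue.

The Overlap Score between a predicted module of size g and a benchmark
complex of size h sharing i proteins is

    OS = i^2 / (g * h)

1 for identical sets, 0 for disjoint ones. A module matches a complex
at threshold tau when OS >= tau (tau > 0); at tau = 0 every module
matches every complex by convention, so a sweep always starts from
perfect sensitivity. True positives are counted over predicted modules
(TP = modules matching at least one complex, FP the rest), false
negatives over complexes (FN = complexes matched by no module), giving

    Sn = TP / (TP + FN)    Sp = TP / (TP + FP)

and the f-measure as their harmonic mean. Mp and Mk are the matched
module and matched complex counts at the threshold.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .io_formats import BenchmarkComplexSet, ModuleSet


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ndigits, as the reference tables print."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def overlap_score(i: int, g: int, h: int) -> float:
    """OS = i^2 / (g*h) for i shared proteins, module size g, complex size h."""
    if g <= 0 or h <= 0:
        raise ValueError("module and complex sizes must be positive")
    if not 0 <= i <= min(g, h):
        raise ValueError(f"shared count i={i} outside [0, min({g}, {h})]")
    return (i * i) / (g * h)


def f_measure(sn: float, sp: float) -> float:
    """Harmonic mean of sensitivity and specificity; 0 when both are 0."""
    if not (0 <= sn <= 1 and 0 <= sp <= 1):
        raise ValueError("Sn and Sp must lie in [0, 1]")
    if sn + sp == 0:
        return 0.0
    return 2.0 * sn * sp / (sn + sp)


@dataclass
class MatchStats:
    """Matching statistics at one Overlap-Score threshold."""

    os_threshold: float
    TP: int
    FP: int
    FN: int
    Mp: int
    Mk: int
    sensitivity: float
    specificity: float
    f_measure: float


def pair_scores(
    predicted: Sequence[frozenset[str]],
    benchmark: BenchmarkComplexSet,
) -> list[dict]:
    """All (module, complex) Overlap Scores with the underlying counts."""
    rows = []
    for idx, module in enumerate(predicted):
        for name in sorted(benchmark.complexes):
            members = benchmark.complexes[name]
            shared = len(module & members)
            rows.append(
                {
                    "module_index": idx,
                    "complex": name,
                    "i": shared,
                    "g": len(module),
                    "h": len(members),
                    "os": overlap_score(shared, len(module), len(members)),
                }
            )
    return rows


def match_all(
    predicted: ModuleSet | Sequence[frozenset[str]],
    benchmark: BenchmarkComplexSet,
    os_threshold: float = 0.2,
) -> tuple[MatchStats, list[dict]]:
    """Matching statistics plus the per-pair score table at one threshold."""
    if not 0 <= os_threshold <= 1:
        raise ValueError("os_threshold must lie in [0, 1]")
    if len(benchmark) == 0:
        raise ValueError("benchmark complex set is empty")
    sets = predicted.protein_sets() if isinstance(predicted, ModuleSet) else list(predicted)

    table = pair_scores(sets, benchmark)
    matched_modules: set[int] = set()
    matched_complexes: set[str] = set()
    for row in table:
        hit = os_threshold == 0 or row["os"] >= os_threshold
        if hit:
            matched_modules.add(row["module_index"])
            matched_complexes.add(row["complex"])
    tp = len(matched_modules)
    fp = len(sets) - tp
    fn = len(benchmark) - len(matched_complexes)
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tp / (tp + fp) if tp + fp else 0.0
    stats = MatchStats(
        os_threshold=os_threshold,
        TP=tp, FP=fp, FN=fn,
        Mp=tp, Mk=len(matched_complexes),
        sensitivity=sn, specificity=sp, f_measure=f_measure(sn, sp),
    )
    return stats, table


def threshold_sweep(
    predicted: ModuleSet | Sequence[frozenset[str]],
    benchmark: BenchmarkComplexSet,
    thresholds: Iterable[float] = tuple(t / 10 for t in range(11)),
) -> list[MatchStats]:
    """Matching statistics over a grid of Overlap-Score thresholds."""
    return [match_all(predicted, benchmark, tau)[0] for tau in thresholds]


def size_distribution(
    predicted: ModuleSet | Sequence[frozenset[str]],
    large_cutoff: int = 80,
) -> tuple[Counter[int], int]:
    """Histogram of module sizes plus the count of large modules (>= cutoff)."""
    sets = predicted.protein_sets() if isinstance(predicted, ModuleSet) else list(predicted)
    histogram = Counter(len(s) for s in sets)
    n_large = sum(1 for s in sets if len(s) >= large_cutoff)
    return histogram, n_large
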