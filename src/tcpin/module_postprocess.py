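"""Cleaning of candidate modules and occurrence statistics.

Clustering each time-point network independently yields many raw
candidate modules: singletons, exact repeats of the same protein set at
several time points, and modules wholly contained in bigger ones. The
cleaning pass removes those in a fixed order (singletons, duplicates,
strict subsets) and is idempotent. Occurrence frequencies count, for
each distinct protein set, in how many of the per-time-point module
sets it appears — the basis for studying the temporal specificity of
modules.
"""
from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .io_formats import Module, ModuleSet


def clean_modules(module_set: ModuleSet, scope: str = "all") -> ModuleSet:
    """Drop singletons, exact duplicates, then strictly contained modules.

    Rules are applied in order: (1) modules with a single protein are
    removed; (2) among modules with identical protein sets the one with
    the smallest (time_point, cluster_index) is kept; (3) modules whose
    protein set is a strict subset of another surviving module's set
    are removed. With scope="all" (default) duplicate and containment
    checks run across all time points; scope="per_time_point" restricts
    both to modules from the same time point. Output order is by
    (time_point, cluster_index).
    """
    if scope not in ("all", "per_time_point"):
        raise ValueError("scope must be 'all' or 'per_time_point'")
    ordered = sorted(module_set, key=Module.sort_key)
    sized = [m for m in ordered if m.size >= 2]

    def group_key(module: Module):
        return module.time_point if scope == "per_time_point" else None

    seen: set[tuple] = set()
    deduped: list[Module] = []
    for module in sized:
        key = (group_key(module), module.proteins)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(module)

    survivors: list[Module] = []
    for module in deduped:
        contained = any(
            other is not module
            and group_key(other) == group_key(module)
            and module.proteins < other.proteins
            for other in deduped
        )
        if not contained:
            survivors.append(module)
    return ModuleSet(survivors)


def occurrence_frequencies(
    per_time_point_sets: Sequence[Iterable[frozenset[str]]],
) -> Counter[frozenset[str]]:
    """Count, per distinct protein set, the time points containing it.

    Input is one iterable of protein sets per time point (after
    singleton removal, before cross-time deduplication); membership is
    exact set equality and repeats within one time point count once.
    """
    counts: Counter[frozenset[str]] = Counter()
    for modules in per_time_point_sets:
        for proteins in set(frozenset(p) for p in modules):
            counts[proteins] += 1
    return counts


def occurrence_histogram(counts: Counter[frozenset[str]]) -> Counter[int]:
    """How many distinct modules occur exactly k times, for each k."""
    return Counter(counts.values())
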