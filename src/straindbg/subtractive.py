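"""Subtractive walk: repeated max-coverage contig walks with per-node
variant-count estimation and interpolated coverage subtraction.

Where several strains share sequence, the shared k-mers carry the summed
coverage of all of them.  Instead of deleting traversed nodes, each walk
estimates how many variants cover every node of its path (from the
normalized step-to-step coverage change delta) and subtracts only one
variant's worth of coverage, so shared cores remain traversable and are
emitted once per variant.

The delta statistic for one step of the outward walk is

    delta = (c_current - c_previous) / max(c_current, c_previous)

which lies in [-1, 1].  Starting from the minimum-coverage node of the path
(assigned one variant), a sharp rise (delta > delta_sw) means the walk is
entering a region shared by one more variant, and a sharp drop
(delta < -delta_sw) means it is leaving one.  ``as_printed=True`` applies
the opposite sign pairing instead (see the methods note for why the default
is what it is; the two modes genuinely differ and both are exposed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dbg import ContigPath, DeBruijnGraph, component_scan, make_path
from .consensus import walk_consensus

logger = logging.getLogger(__name__)

DEFAULT_DELTA_SW = 0.8
DEFAULT_SEARCH_BUDGET = 1000


@dataclass
class DeltaParams:
    """Threshold on the normalized coverage change; in (0, 1], default 0.8."""

    delta_sw: float = DEFAULT_DELTA_SW

    def __post_init__(self):
        if not 0 < self.delta_sw <= 1:
            raise ValueError(f"delta_sw must be in (0, 1], got {self.delta_sw}")


def compute_delta(c_previous, c_current):
    """Normalized coverage change, ``(c_cur - c_prev)/max(c_cur, c_prev)``.

    Accepts scalars or numpy arrays; both coverages must be positive.
    Antisymmetric under argument swap, always in [-1, 1].
    """
    prev = np.asarray(c_previous, dtype=float)
    cur = np.asarray(c_current, dtype=float)
    if np.any(prev <= 0) or np.any(cur <= 0):
        raise ValueError("coverages must be positive")
    delta = (cur - prev) / np.maximum(cur, prev)
    if delta.ndim == 0:
        return float(delta)
    return delta


def select_min_node(coverages: Sequence[float]) -> int:
    """Index of the minimal coverage; ties pick the position closest to the
    end of the path (the largest index)."""
    if len(coverages) == 0:
        raise ValueError("empty coverage list")
    lowest = min(coverages)
    return max(i for i, c in enumerate(coverages) if c == lowest)


def estimate_variant_counts(
    coverages: Sequence[float],
    params: DeltaParams | float = DEFAULT_DELTA_SW,
    as_printed: bool = False,
) -> list[int]:
    """Per-position variant counts for a path's coverage profile.

    The minimum-coverage node gets one variant; walking outward from it in
    each direction, delta is computed between the previous and current node
    of that walk.  Default semantics: delta > delta_sw increments the count,
    delta < -delta_sw decrements it (floored at 1); otherwise it carries
    over.  ``as_printed=True`` swaps the sign pairing.  Comparisons are
    strict, so delta equal to the threshold does not trigger.
    """
    if isinstance(params, (int, float)):
        params = DeltaParams(delta_sw=float(params))
    threshold = params.delta_sw
    n = len(coverages)
    if n == 0:
        raise ValueError("empty coverage list")
    counts = [0] * n
    m = select_min_node(coverages)
    counts[m] = 1

    def update(prev_count: int, delta: float) -> int:
        rise, drop = delta > threshold, delta < -threshold
        if as_printed:
            rise, drop = drop, rise
        if rise:
            return prev_count + 1
        if drop:
            return max(prev_count - 1, 1)
        return prev_count

    for i in range(m + 1, n):  # rightward walk
        delta = compute_delta(coverages[i - 1], coverages[i])
        counts[i] = update(counts[i - 1], delta)
    for i in range(m - 1, -1, -1):  # leftward walk: previous step is i+1
        delta = compute_delta(coverages[i + 1], coverages[i])
        counts[i] = update(counts[i + 1], delta)
    return counts


def interpolated_subtraction(
    coverages: Sequence[float], counts: Sequence[int]
) -> list[float]:
    """Per-position subtraction amounts.

    Positions covered by a single variant lose their full coverage.  A
    position with more than one variant loses an amount linearly
    interpolated, by path index, between the coverages of the nearest
    single-variant positions before and after it (constant extrapolation
    when one side has none; the minimum node guarantees at least one
    single-variant position exists).
    """
    if len(coverages) != len(counts):
        raise ValueError("coverages and counts must have equal length")
    n = len(coverages)
    ones = [i for i in range(n) if counts[i] == 1]
    amounts = [0.0] * n
    for i in range(n):
        if counts[i] == 1:
            amounts[i] = float(coverages[i])
            continue
        before = max((j for j in ones if j < i), default=None)
        after = min((j for j in ones if j > i), default=None)
        if before is None and after is None:
            amounts[i] = 0.0
        elif before is None:
            amounts[i] = float(coverages[after])
        elif after is None:
            amounts[i] = float(coverages[before])
        else:
            frac = (i - before) / (after - before)
            amounts[i] = coverages[before] + (coverages[after] - coverages[before]) * frac
    return amounts


@dataclass
class VariantProfile:
    """A walked path with its estimated variant counts and subtraction amounts."""

    path: ContigPath
    min_index: int
    variant_counts: list[int]
    subtraction_amounts: list[float]


def variant_profile(
    path: ContigPath,
    params: DeltaParams | float = DEFAULT_DELTA_SW,
    as_printed: bool = False,
) -> VariantProfile:
    counts = estimate_variant_counts(path.coverages, params, as_printed=as_printed)
    amounts = interpolated_subtraction(path.coverages, counts)
    return VariantProfile(
        path=path,
        min_index=select_min_node(path.coverages),
        variant_counts=counts,
        subtraction_amounts=amounts,
    )


def subtract_path_coverage(graph: DeBruijnGraph, profile: VariantProfile) -> None:
    """Apply a profile's subtraction amounts to the graph (in place).

    Single-variant nodes end at exactly 0; multi-variant nodes keep their
    (possibly fractional) residual, clamped at 0.
    """
    for (kmer, _), count, amount in zip(
        profile.path.steps, profile.variant_counts, profile.subtraction_amounts
    ):
        node = graph.nodes[kmer]
        if count == 1:
            node.coverage = 0.0
        else:
            node.coverage = max(node.coverage - amount, 0.0)


def walk_max_coverage(
    graph: DeBruijnGraph,
    seed: str,
    min_coverage: float,
    blocked: frozenset = frozenset(),
) -> ContigPath:
    """Bidirectional walk that always takes the highest-coverage branch
    (bubbles are disregarded); same stop conditions as the consensus walk."""
    return walk_consensus(
        graph, seed, min_coverage, blocked=blocked, use_bubble_rule=False
    )


def assemble_subtractive(
    graph: DeBruijnGraph,
    min_coverage: float = 2,
    delta_sw: float = DEFAULT_DELTA_SW,
    as_printed: bool = False,
    search_budget: Optional[int] = DEFAULT_SEARCH_BUDGET,
    max_walks: Optional[int] = None,
) -> list[ContigPath]:
    """Repeated subtractive walks until no node meets *min_coverage*.

    Each round starts from the first (sorted) node still meeting the
    threshold, finds a locally maximal seed with a budget-bounded component
    scan, walks the max-coverage path, records it, and subtracts one
    variant's worth of coverage along it.  Shared nodes may therefore appear
    in several output contigs.  A contig whose sequence (or reverse
    complement) was already emitted in this run is dropped.

    Mutates node coverages; total coverage strictly decreases every round,
    which guarantees termination.
    """
    if min_coverage < 1:
        raise ValueError("subtractive walk requires min_coverage >= 1")
    params = DeltaParams(delta_sw=delta_sw)
    contigs: list[ContigPath] = []
    seen_seqs: set[str] = set()
    walks = 0
    while True:
        start = next(
            (n for n in graph.sorted_nodes() if graph.coverage(n) >= min_coverage),
            None,
        )
        if start is None:
            break
        comp = component_scan(
            graph, start, node_budget=search_budget, min_coverage=min_coverage
        )
        path = walk_max_coverage(graph, comp.seed, min_coverage)
        profile = variant_profile(path, params, as_printed=as_printed)
        before = graph.total_coverage()
        subtract_path_coverage(graph, profile)
        after = graph.total_coverage()
        if not after < before:  # defensive: cannot happen while min_coverage >= 1
            logger.error("subtractive walk made no progress at %s; stopping", start)
            break
        from .dbg import reverse_complement

        if path.sequence not in seen_seqs:
            contigs.append(path)
            seen_seqs.add(path.sequence)
            seen_seqs.add(reverse_complement(path.sequence))
        walks += 1
        if max_walks is not None and walks >= max_walks:
            break
    logger.info("subtractive assembly: %d contigs in %d walks", len(contigs), walks)
    return contigs
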