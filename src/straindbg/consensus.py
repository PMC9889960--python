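"""Consensus traversal: coverage-guided contig walks with a collective
bubble rule, plus local-variant exploration emitted as a sequence graph.

Each connected component is walked from its highest-coverage node.  At a
branch point the branch whose next node has the highest coverage is taken,
unless two branches rejoin within a bounded lookahead (a bubble) and their
combined mean coverage exceeds every other candidate — then the
higher-coverage member of that pair is taken.  A walk stops at a dead end,
when the chosen branch leads back into the current path, or when no branch
meets the minimum coverage threshold.

Local variation along the chosen path (SNP/indel bubbles between strains)
is recovered afterwards by depth-first exploration of off-path branches and
written as alternative segments of a :class:`~straindbg.io_formats.SequenceGraphDoc`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .dbg import (
    FORWARD,
    REVERSE,
    ContigPath,
    DeBruijnGraph,
    component_scan,
    make_path,
)
from .io_formats import Edge, GraphPath, Segment, SequenceGraphDoc

logger = logging.getLogger(__name__)

DEFAULT_LOOKAHEAD = 64
DEFAULT_MAX_ALT_LENGTH = 500
DEFAULT_MIN_COMPONENT_SIZE = 2


@dataclass
class BubbleDecision:
    """Record of one branch decision at a junction (for inspection/logging)."""

    branch_point: str
    straight_branches: list[tuple[str, float]] = field(default_factory=list)
    bubble_pairs: list[tuple[tuple[str, str], str, float]] = field(default_factory=list)
    chosen: Optional[str] = None


def _lookahead_walk(graph, pos, lookahead, min_coverage, blocked):
    """Greedy highest-coverage walk of at most *lookahead* nodes from *pos*.

    Returns (ordered node ids, mean coverage).  Cycle-safe: stops on revisit.
    """
    nodes = [pos[0]]
    seen = {pos[0]}
    current = pos
    while len(nodes) < lookahead:
        best = None
        for base, nxt in graph.successors(*current):
            if nxt[0] in blocked or graph.coverage(nxt[0]) < min_coverage:
                continue
            if best is None or graph.coverage(nxt[0]) > graph.coverage(best[0]):
                best = nxt
        if best is None or best[0] in seen:
            break
        nodes.append(best[0])
        seen.add(best[0])
        current = best
    mean = sum(graph.coverage(n) for n in nodes) / len(nodes)
    return nodes, mean


def choose_branch(
    graph: DeBruijnGraph,
    position: tuple[str, bool],
    min_coverage: float,
    lookahead: int = DEFAULT_LOOKAHEAD,
    blocked: frozenset = frozenset(),
    use_bubble_rule: bool = True,
    decision: Optional[BubbleDecision] = None,
) -> Optional[str]:
    """Pick the next nucleotide at *position*, or ``None`` at a dead end.

    Candidates are outgoing nucleotides whose target node meets
    *min_coverage* and is not *blocked*.  With the bubble rule enabled,
    every unordered candidate pair is tested for rejoining within
    *lookahead* nodes; a pair whose combined mean branch coverage exceeds
    the mean of every non-pair candidate wins, and its higher-coverage
    member is returned.  Otherwise the candidate with the highest next-node
    coverage is returned (ties break by nucleotide order A<C<G<T).
    """
    cands = []
    for base, nxt in graph.successors(*position):
        if nxt[0] in blocked:
            continue
        if graph.coverage(nxt[0]) < min_coverage:
            continue
        cands.append((base, nxt))
    if not cands:
        return None
    if len(cands) == 1 or not use_bubble_rule:
        chosen = max(cands, key=lambda c: (graph.coverage(c[1][0]), _base_rank(c[0])))[0]
        if decision is not None:
            decision.chosen = chosen
        return chosen

    walks = {
        base: _lookahead_walk(graph, nxt, lookahead, min_coverage, blocked)
        for base, nxt in cands
    }
    best_pair = None  # (combined, (b1, b2), (mean1, mean2))
    bases = [b for b, _ in cands]
    for i in range(len(bases)):
        for j in range(i + 1, len(bases)):
            b1, b2 = bases[i], bases[j]
            n1, _ = walks[b1]
            n2, _ = walks[b2]
            in2 = set(n2)
            rejoin = next((n for n in n1 if n in in2), None)
            if rejoin is None:
                continue
            # the branch proper is everything strictly before the rejoin node;
            # the shared continuation must not inflate the pair's coverage
            branch1 = n1[: n1.index(rejoin)]
            branch2 = n2[: n2.index(rejoin)]
            if not branch1 or not branch2:
                continue  # one candidate's walk starts inside the other
            m1 = sum(graph.coverage(n) for n in branch1) / len(branch1)
            m2 = sum(graph.coverage(n) for n in branch2) / len(branch2)
            combined = m1 + m2
            if decision is not None:
                decision.bubble_pairs.append(((b1, b2), rejoin, combined))
            others = [walks[b][1] for b in bases if b not in (b1, b2)]
            if all(combined > m for m in others):
                if best_pair is None or combined > best_pair[0]:
                    best_pair = (combined, (b1, b2), (m1, m2))
    if decision is not None:
        decision.straight_branches = [(b, walks[b][1]) for b in bases]
    if best_pair is not None:
        _, (b1, b2), (m1, m2) = best_pair
        chosen = max([(b1, m1), (b2, m2)], key=lambda bm: (bm[1], _base_rank(bm[0])))[0]
        logger.debug("bubble rule at %s: pair %s/%s -> %s", position[0], b1, b2, chosen)
    else:
        chosen = max(cands, key=lambda c: (graph.coverage(c[1][0]), _base_rank(c[0])))[0]
    if decision is not None:
        decision.chosen = chosen
    return chosen


def _base_rank(base: str):
    # ties prefer A < C < G < T, i.e. the *smaller* base wins under max()
    return -"ACGT".index(base)


def _extend(graph, start, min_coverage, lookahead, blocked, path_nodes, use_bubble_rule):
    """Extend from an oriented start, returning the steps after it."""
    steps = []
    current = start
    while True:
        base = choose_branch(
            graph, current, min_coverage, lookahead,
            blocked=blocked, use_bubble_rule=use_bubble_rule,
        )
        if base is None:
            logger.debug("walk stop at %s: dead end / below threshold", current[0])
            break
        nxt = graph.step(*current, base)
        if nxt[0] in path_nodes:
            logger.debug("walk stop at %s: chosen branch already in path", current[0])
            break
        steps.append(nxt)
        path_nodes.add(nxt[0])
        current = nxt
    return steps


def walk_consensus(
    graph: DeBruijnGraph,
    seed: str,
    min_coverage: float,
    lookahead: int = DEFAULT_LOOKAHEAD,
    blocked: frozenset = frozenset(),
    use_bubble_rule: bool = True,
) -> ContigPath:
    """Bidirectional coverage-guided walk from *seed*.

    The seed is extended forward first; the reverse-orientation extension is
    then prepended (flipped), and the result is reported 5'→3' of the final
    spelled strand.
    """
    path_nodes = {seed}
    fwd = _extend(graph, (seed, FORWARD), min_coverage, lookahead, blocked,
                  path_nodes, use_bubble_rule)
    rev = _extend(graph, (seed, REVERSE), min_coverage, lookahead, blocked,
                  path_nodes, use_bubble_rule)
    steps = [(k, not o) for k, o in reversed(rev)] + [(seed, FORWARD)] + fwd
    return make_path(graph, steps)


# -- local variant exploration --------------------------------------------


def explore_local_variants(
    graph: DeBruijnGraph,
    path: ContigPath,
    min_coverage: float,
    max_alt_length: int = DEFAULT_MAX_ALT_LENGTH,
    name: str = "contig_1",
) -> SequenceGraphDoc:
    """Find off-path bubbles along *path* and build a sequence-graph document.

    At every path node, each qualifying off-path branch is followed
    depth-first (greedy highest coverage, cycle-safe, at most
    *max_alt_length* nodes).  A walk that returns to the path at a strictly
    later position becomes an alternative segment spelling the off-path
    nodes, attached to the consensus segment by two k-1-base junction
    overlap edges; exploration then resumes from the rejoin position.
    """
    k = graph.k
    doc = SequenceGraphDoc()
    mean_cov = sum(path.coverages) / len(path.coverages)
    doc.segments.append(Segment(id=name, sequence=path.sequence, coverage=mean_cov))
    doc.paths.append(GraphPath(name=f"{name}_path", segment_ids=[name]))

    pos_index = {kmer: i for i, (kmer, _) in enumerate(path.steps)}
    alt_n = 0
    i = 0
    while i < len(path.steps):
        kmer, orient = path.steps[i]
        path_base = (
            graph.oriented_seq(*path.steps[i + 1])[-1] if i + 1 < len(path.steps) else None
        )
        jumped = False
        for base, nxt in graph.successors(kmer, orient):
            if base == path_base:
                continue
            if nxt[0] in pos_index:
                continue  # immediate re-entry, no variant sequence
            if graph.coverage(nxt[0]) < min_coverage:
                continue
            found = _follow_alt(graph, nxt, pos_index, i, min_coverage, max_alt_length)
            if found is None:
                continue
            walked, j = found
            alt_n += 1
            alt_id = f"{name}_alt_{alt_n}"
            alt_seq = _spell_alt(graph, walked)
            alt_cov = sum(graph.coverage(n) for n, _ in walked) / len(walked)
            doc.segments.append(Segment(id=alt_id, sequence=alt_seq, coverage=alt_cov))
            # departure: consensus (k-1)-suffix of the branch k-mer overlaps
            # the alternative's first k-1 bases
            doc.edges.append(
                Edge(f"{alt_id}_in", name, i + 1, i + k, alt_id, 0, k - 1)
            )
            # rejoin: the alternative's last k-1 bases overlap the consensus
            # (k-1)-prefix of the rejoin k-mer
            m = len(walked)
            doc.edges.append(
                Edge(f"{alt_id}_out", alt_id, m, m + k - 1, name, j, j + k - 1)
            )
            doc.paths.append(GraphPath(name=f"{name}_alt_path_{alt_n}", segment_ids=[alt_id]))
            i = j  # continue from where the alternative rejoins
            jumped = True
            break
        if not jumped:
            i += 1
    return doc


def _follow_alt(graph, start, pos_index, branch_pos, min_coverage, max_alt_length):
    """Greedy off-path walk; returns (walked steps, rejoin path index) or None."""
    walked = []
    seen = set()
    current = start
    while len(walked) < max_alt_length:
        if current[0] in pos_index:
            j = pos_index[current[0]]
            if j > branch_pos and walked:
                return walked, j
            return None  # re-entry at or before the branch point
        if current[0] in seen:
            return None  # cycle
        walked.append(current)
        seen.add(current[0])
        best = None
        for base, nxt in graph.successors(*current):
            if graph.coverage(nxt[0]) < min_coverage:
                continue
            if best is None or graph.coverage(nxt[0]) > graph.coverage(best[0]):
                best = nxt
        if best is None:
            return None  # dead end without rejoining
        current = best
    return None


def _spell_alt(graph, steps):
    """Full spelling of the off-path walk: its first k-1 bases equal the
    consensus suffix of the branch k-mer, its last k-1 bases the consensus
    prefix of the rejoin k-mer (the two k-1 junction overlaps)."""
    k0, o0 = steps[0]
    parts = [graph.oriented_seq(k0, o0)]
    for kmer, orient in steps[1:]:
        parts.append(graph.oriented_seq(kmer, orient)[-1])
    return "".join(parts)


# -- whole-graph assembly --------------------------------------------------


def assemble_consensus(
    graph: DeBruijnGraph,
    min_coverage: float = 2,
    lookahead: int = DEFAULT_LOOKAHEAD,
    multiple_contigs: bool = False,
    min_component_size: int = DEFAULT_MIN_COMPONENT_SIZE,
    explore_variants: bool = True,
    max_alt_length: int = DEFAULT_MAX_ALT_LENGTH,
    component_budget: Optional[int] = None,
) -> tuple[list[ContigPath], list[SequenceGraphDoc]]:
    """Assemble one consensus contig per component (or per path).

    Nodes are consumed after each walk: the whole component by default, or
    only the path's own nodes when *multiple_contigs* is set (then the rest
    of the component is reconsidered and may yield further contigs).
    Components smaller than *min_component_size* are consumed without
    emitting a contig.  Returns ``(contigs, sequence-graph docs)`` in
    emission order; length filtering happens at FASTA-writing time.
    """
    consumed: set[str] = set()
    contigs: list[ContigPath] = []
    docs: list[SequenceGraphDoc] = []
    order = graph.sorted_nodes()
    idx = 0
    n = 0
    while idx < len(order):
        start = order[idx]
        if start in consumed:
            idx += 1
            continue
        comp = _residual_component(graph, start, consumed, component_budget)
        seed = comp.seed
        if comp.size < min_component_size or graph.coverage(seed) < min_coverage:
            consumed |= comp.node_ids
            idx += 1
            continue
        path = walk_consensus(
            graph, seed, min_coverage, lookahead, blocked=frozenset(consumed)
        )
        n += 1
        contigs.append(path)
        if explore_variants:
            docs.append(
                explore_local_variants(
                    graph, path, min_coverage, max_alt_length, name=f"contig_{n}"
                )
            )
        if multiple_contigs:
            consumed.update(path.node_ids())
            # stay on the same index: the component may yield more contigs
        else:
            consumed |= comp.node_ids
            idx += 1
    logger.info("consensus assembly: %d contigs from %d nodes", len(contigs), len(order))
    return contigs, docs


def _residual_component(graph, start, consumed, budget):
    """Component scan restricted to not-yet-consumed nodes."""
    from collections import deque

    visited = {start}
    queue = deque([start])
    truncated = False
    while queue:
        current = queue.popleft()
        for neigh in sorted(graph.neighbours(current)):
            if neigh in visited or neigh in consumed:
                continue
            if budget is not None and len(visited) >= budget:
                truncated = True
                queue.clear()
                break
            visited.add(neigh)
            queue.append(neigh)
    seed = max(visited, key=lambda x: (graph.coverage(x), tuple(-ord(c) for c in x)))
    from .dbg import Component

    return Component(node_ids=visited, size=len(visited), seed=seed, truncated=truncated)
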