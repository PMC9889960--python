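"""Canonical-k-mer de Bruijn graph: construction, pruning, scanning, serialization.

Nodes are canonical k-mers (the lexicographic minimum of a k-mer and its
reverse complement), so both strands of the input are represented by a single
node set.  Each node stores a coverage value (the number of read windows
supporting it; fractional after coverage subtraction) and, for each
orientation of the node, the set of outgoing nucleotides.  An oriented node
``(kmer, forward)`` denotes the canonical text itself; ``(kmer, reverse)``
denotes its reverse complement.  Every directed edge recorded on one node has
a mirrored counterpart on its neighbour, which keeps the graph consistent
under strand flips.

Only odd k is accepted: for even k a k-mer can equal its own reverse
complement, which would make the orientation of a canonical node ambiguous.
"""

from __future__ import annotations

import logging
import struct
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

FORWARD = True
REVERSE = False

#: Largest k accepted by default (configurable per call).
DEFAULT_MAX_K = 31

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_BITS_BASE = {v: k for k, v in _BASE_BITS.items()}
_PACK = {"A": 0, "C": 1, "G": 2, "T": 3}
_UNPACK = {v: k for k, v in _PACK.items()}

_MAGIC = b"SFDBG"
_FORMAT_VERSION = 1


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(text: str) -> tuple[str, str]:
    """Canonicalize a k-mer.

    Returns ``(canonical, orientation)`` where *canonical* is the
    lexicographic minimum of *text* and its reverse complement and
    *orientation* is ``"forward"`` if the input already was canonical,
    ``"reverse"`` otherwise.

    Raises
    ------
    ValueError
        If the length is even or the text contains a non-ACGT character.
    """
    if len(text) % 2 == 0:
        raise ValueError(f"k must be odd, got k={len(text)}")
    if any(c not in _BASE_BITS for c in text):
        raise ValueError(f"k-mer contains non-ACGT character: {text!r}")
    rc = reverse_complement(text)
    if text <= rc:
        return text, "forward"
    return rc, "reverse"


def _canon(text: str) -> tuple[str, bool]:
    """Internal canonicalization without validation; bool orientation."""
    rc = reverse_complement(text)
    if text <= rc:
        return text, FORWARD
    return rc, REVERSE


@dataclass
class GraphNode:
    """A canonical-k-mer node: coverage plus per-orientation outgoing edges."""

    coverage: float = 0.0
    out_fwd: set[str] = field(default_factory=set)
    out_rev: set[str] = field(default_factory=set)

    def outs(self, orient: bool) -> set[str]:
        return self.out_fwd if orient else self.out_rev

    def stub_count(self) -> int:
        """Number of incident edge stubs (both orientations)."""
        return len(self.out_fwd) + len(self.out_rev)


class DeBruijnGraph:
    """Map from canonical k-mer text to :class:`GraphNode`.

    Node iteration is always in sorted k-mer order, so all downstream
    traversals are deterministic for identical inputs.
    """

    def __init__(self, k: int):
        if k % 2 == 0 or k < 3:
            raise ValueError(f"k must be odd and >= 3, got {k}")
        self.k = k
        self.nodes: dict[str, GraphNode] = {}

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.nodes

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def coverage(self, kmer: str) -> float:
        return self.nodes[kmer].coverage

    def total_coverage(self) -> float:
        return sum(n.coverage for n in self.nodes.values())

    def oriented_seq(self, kmer: str, orient: bool) -> str:
        return kmer if orient else reverse_complement(kmer)

    def get_or_add(self, kmer: str) -> GraphNode:
        node = self.nodes.get(kmer)
        if node is None:
            node = GraphNode()
            self.nodes[kmer] = node
        return node

    # -- edges -------------------------------------------------------------

    def step(self, kmer: str, orient: bool, base: str) -> tuple[str, bool]:
        """The oriented node reached by appending *base* to ``(kmer, orient)``."""
        seq = self.oriented_seq(kmer, orient)
        return _canon(seq[1:] + base)

    def add_edge(self, kmer: str, orient: bool, base: str) -> None:
        """Record the directed edge and its strand-mirrored counterpart."""
        seq = self.oriented_seq(kmer, orient)
        nkmer, norient = _canon(seq[1:] + base)
        if nkmer not in self.nodes:
            raise KeyError(f"edge target {nkmer} not in graph")
        self.nodes[kmer].outs(orient).add(base)
        # mirror: revcomp(next) is followed by complement of seq[0]
        mirror_base = reverse_complement(seq[0])
        self.nodes[nkmer].outs(not norient).add(mirror_base)

    def out_edges(self, kmer: str, orient: bool) -> list[str]:
        """Sorted outgoing nucleotides for an oriented node."""
        return sorted(self.nodes[kmer].outs(orient))

    def successors(self, kmer: str, orient: bool) -> list[tuple[str, tuple[str, bool]]]:
        """``(base, (neighbour kmer, neighbour orientation))`` pairs, sorted by base."""
        return [(b, self.step(kmer, orient, b)) for b in self.out_edges(kmer, orient)]

    def neighbours(self, kmer: str) -> set[str]:
        """Distinct neighbouring node ids over both orientations (undirected)."""
        out = set()
        for orient in (FORWARD, REVERSE):
            for _, (nk, _) in self.successors(kmer, orient):
                out.add(nk)
        out.discard(kmer)
        return out

    def remove_node(self, kmer: str) -> None:
        """Remove a node and every mirrored edge pointing at it."""
        node = self.nodes[kmer]
        for orient in (FORWARD, REVERSE):
            for base in list(node.outs(orient)):
                nkmer, norient = self.step(kmer, orient, base)
                if nkmer == kmer:
                    continue
                neigh = self.nodes.get(nkmer)
                if neigh is None:
                    continue
                seq = self.oriented_seq(kmer, orient)
                neigh.outs(not norient).discard(reverse_complement(seq[0]))
        del self.nodes[kmer]

    def check_edge_symmetry(self) -> None:
        """Raise ``AssertionError`` if any edge lacks its mirrored counterpart."""
        for kmer, node in self.nodes.items():
            for orient in (FORWARD, REVERSE):
                seq = self.oriented_seq(kmer, orient)
                for base in node.outs(orient):
                    nkmer, norient = _canon(seq[1:] + base)
                    assert nkmer in self.nodes, f"dangling edge {kmer}->{nkmer}"
                    mirror = reverse_complement(seq[0])
                    assert mirror in self.nodes[nkmer].outs(not norient), (
                        f"asymmetric edge {kmer}:{orient} -{base}-> {nkmer}"
                    )

    def equals(self, other: "DeBruijnGraph") -> bool:
        if self.k != other.k or set(self.nodes) != set(other.nodes):
            return False
        for kmer, node in self.nodes.items():
            o = other.nodes[kmer]
            if (
                abs(node.coverage - o.coverage) > 1e-9
                or node.out_fwd != o.out_fwd
                or node.out_rev != o.out_rev
            ):
                return False
        return True


# -- paths -----------------------------------------------------------------


@dataclass
class ContigPath:
    """An ordered oriented node walk with its spelled sequence.

    ``len(sequence) == len(steps) + k - 1``; consecutive steps are joined by
    an existing graph edge and no node appears twice.
    """

    steps: list[tuple[str, bool]]
    sequence: str
    coverages: list[float]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def kmer_count(self) -> int:
        return len(self.steps)

    def node_ids(self) -> list[str]:
        return [kmer for kmer, _ in self.steps]


def spell_path(graph: DeBruijnGraph, steps: list[tuple[str, bool]]) -> str:
    """Spell the DNA sequence of an oriented node walk."""
    if not steps:
        return ""
    k0, o0 = steps[0]
    parts = [graph.oriented_seq(k0, o0)]
    for kmer, orient in steps[1:]:
        parts.append(graph.oriented_seq(kmer, orient)[-1])
    return "".join(parts)


def make_path(graph: DeBruijnGraph, steps: list[tuple[str, bool]]) -> ContigPath:
    return ContigPath(
        steps=list(steps),
        sequence=spell_path(graph, steps),
        coverages=[graph.coverage(kmer) for kmer, _ in steps],
    )


# -- construction ----------------------------------------------------------


def build_graph(reads: Iterable, k: int, max_k: int = None) -> DeBruijnGraph:
    """Build the graph from a stream of sequence records.

    Every k-length window without an N adds one unit of coverage to its
    canonical node; consecutive valid windows of a read induce the
    corresponding oriented edge on both endpoints.  Reads shorter than k
    contribute nothing.
    """
    limit = max_k if max_k is not None else DEFAULT_MAX_K
    if k % 2 == 0:
        raise ValueError(
            f"k must be odd (even k admits palindromic canonical k-mers), got {k}"
        )
    if not 3 <= k <= limit:
        raise ValueError(f"k must satisfy 3 <= k <= {limit}, got {k}")
    graph = DeBruijnGraph(k)
    for record in reads:
        seq = getattr(record, "sequence", record)
        if len(seq) < k:
            continue
        prev_valid = False
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" in window:
                prev_valid = False
                continue
            kmer, orient = _canon(window)
            graph.get_or_add(kmer).coverage += 1
            if prev_valid:
                pk, po = _canon(seq[i - 1 : i - 1 + k])
                graph.add_edge(pk, po, window[-1])
            prev_valid = True
    if not graph.nodes:
        logger.warning("no valid k-mers in input; graph is empty")
    return graph


# -- pruning ---------------------------------------------------------------


def prune_graph(
    graph: DeBruijnGraph, max_tip_length: int = 100, min_coverage: float = 2
) -> tuple[int, int]:
    """Remove low-coverage nodes, then clip short dead-end tips.

    The coverage filter runs first: removing low-coverage nodes creates tips
    that the tip pass then cleans.  A tip is a maximal dead-end chain of at
    most *max_tip_length* nodes hanging off a branching node (the branching
    node itself is kept); clipping iterates to a fixed point.

    Returns ``(tip nodes removed, low-coverage nodes removed)``.
    """
    low = [kmer for kmer, n in graph.nodes.items() if n.coverage < min_coverage]
    for kmer in low:
        graph.remove_node(kmer)

    tips_removed = 0
    changed = True
    while changed:
        changed = False
        for kmer in graph.sorted_nodes():
            node = graph.nodes.get(kmer)
            if node is None:
                continue
            for orient in (FORWARD, REVERSE):
                clipped = _clip_side(graph, kmer, orient, max_tip_length)
                if clipped:
                    tips_removed += clipped
                    changed = True
    return tips_removed, len(low)


def _clip_side(graph: DeBruijnGraph, kmer: str, orient: bool, max_tip_length: int) -> int:
    """Clip short dead-end branches competing at one side of a fork.

    Considers the out-edges of ``(kmer, orient)``; branches that run into a
    dead end within *max_tip_length* nodes are tips.  If every branch on the
    side is such a dead end, the best one (longest, then highest total
    coverage, then smallest spelled sequence) is kept and the rest clipped;
    if at least one branch continues into the wider graph, all tips on the
    side are clipped.  Returns the number of nodes removed.
    """
    node = graph.nodes[kmer]
    bases = sorted(node.outs(orient))
    if len(bases) < 2:
        return 0
    chains: dict[str, Optional[list[str]]] = {}
    for base in bases:
        chains[base] = _dead_end_chain(graph, kmer, orient, base, max_tip_length)
    clippable = {b: c for b, c in chains.items() if c is not None}
    if not clippable:
        return 0
    if len(clippable) == len(bases):
        # every branch dead-ends: keep the best one
        def rank(item):
            base, chain = item
            total = sum(graph.coverage(c) for c in chain)
            return (len(chain), total, tuple(_neg_lex(c) for c in chain))

        keep = max(clippable.items(), key=rank)[0]
        del clippable[keep]
    removed = 0
    for chain in clippable.values():
        for c in chain:
            if c in graph.nodes:
                graph.remove_node(c)
                removed += 1
    return removed


def _dead_end_chain(
    graph: DeBruijnGraph, kmer: str, orient: bool, base: str, max_tip_length: int
) -> Optional[list[str]]:
    """Nodes of the dead-end chain entered via *base*, or None if the branch
    continues into the wider graph, exceeds the length bound, or cycles."""
    chain: list[str] = []
    seen = {kmer}
    current = graph.step(kmer, orient, base)
    while len(chain) < max_tip_length + 1:
        ckmer, corient = current
        if ckmer in seen:
            return None  # cycle
        cnode = graph.nodes[ckmer]
        if cnode.stub_count() >= 3:
            return None  # joins the wider graph
        chain.append(ckmer)
        seen.add(ckmer)
        outs = graph.out_edges(ckmer, corient)
        if not outs:
            return chain if len(chain) <= max_tip_length else None
        if len(outs) > 1:
            return None
        current = graph.step(ckmer, corient, outs[0])
    return None  # too long


# -- component scan --------------------------------------------------------


@dataclass
class Component:
    """A connected component discovered by breadth-first exploration."""

    node_ids: set[str]
    size: int
    seed: str
    truncated: bool = False  # True when the node budget stopped exploration early


def component_scan(
    graph: DeBruijnGraph, start: str, node_budget: Optional[int] = None,
    min_coverage: float = 0.0,
) -> Component:
    """BFS from *start* over undirected adjacency.

    Stops early once *node_budget* nodes have been discovered (the reported
    size is then a lower bound, flagged by ``truncated``).  The seed is the
    highest-coverage discovered node; ties break toward the lexicographically
    smallest k-mer.  Nodes below *min_coverage* are treated as absent.
    """
    if start not in graph.nodes:
        raise KeyError(f"start node {start} not in graph")
    visited = {start}
    queue = deque([start])
    truncated = False
    while queue:
        current = queue.popleft()
        for neigh in sorted(graph.neighbours(current)):
            if neigh in visited or graph.coverage(neigh) < min_coverage:
                continue
            if node_budget is not None and len(visited) >= node_budget:
                truncated = True
                queue.clear()
                break
            visited.add(neigh)
            queue.append(neigh)
    seed = max(visited, key=lambda n: (graph.coverage(n), _neg_lex(n)))
    return Component(node_ids=visited, size=len(visited), seed=seed, truncated=truncated)


def _neg_lex(kmer: str):
    # invert lexicographic order so max() prefers the smallest k-mer on ties
    return tuple(-ord(c) for c in kmer)


# -- unitigs ---------------------------------------------------------------


def extract_unitigs(graph: DeBruijnGraph, min_coverage: float = 0.0) -> list[ContigPath]:
    """Maximal non-branching paths over nodes meeting *min_coverage*.

    Every inner node of a unitig has exactly one incoming and one outgoing
    edge within the filtered node set; the returned unitigs are node-disjoint
    and jointly cover all qualifying nodes.
    """
    alive = {n for n in graph.nodes if graph.coverage(n) >= min_coverage}
    assigned: set[str] = set()
    unitigs: list[ContigPath] = []

    def unique_next(pos):
        kmer, orient = pos
        cands = [
            (b, nxt)
            for b, nxt in graph.successors(kmer, orient)
            if nxt[0] in alive
        ]
        if len(cands) != 1:
            return None
        nxt = cands[0][1]
        # the next node must have a unique incoming edge, i.e. a unique
        # predecessor seen from its reverse orientation
        back = [
            (b, p)
            for b, p in graph.successors(nxt[0], not nxt[1])
            if p[0] in alive
        ]
        if len(back) != 1:
            return None
        return nxt

    for start in sorted(alive):
        if start in assigned:
            continue
        steps = [(start, FORWARD)]
        used = {start}
        # forward extension
        while True:
            nxt = unique_next(steps[-1])
            if nxt is None or nxt[0] in assigned or nxt[0] in used:
                break
            steps.append(nxt)
            used.add(nxt[0])
        # backward extension from the start's reverse orientation
        back_steps = []
        pos = (start, REVERSE)
        while True:
            nxt = unique_next(pos)
            if nxt is None or nxt[0] in assigned or nxt[0] in used:
                break
            back_steps.append(nxt)
            used.add(nxt[0])
            pos = nxt
        steps = [(kmer, not orient) for kmer, orient in reversed(back_steps)] + steps
        assigned.update(used)
        unitigs.append(make_path(graph, steps))
    return unitigs


# -- serialization ---------------------------------------------------------


def _pack_kmer(kmer: str) -> bytes:
    out = bytearray((len(kmer) + 3) // 4)
    for i, base in enumerate(kmer):
        out[i // 4] |= _PACK[base] << (2 * (i % 4))
    return bytes(out)


def _unpack_kmer(data: bytes, k: int) -> str:
    return "".join(_UNPACK[(data[i // 4] >> (2 * (i % 4))) & 3] for i in range(k))


def save_graph(graph: DeBruijnGraph, destination) -> None:
    """Serialize the graph: magic ``SFDBG``, version, k, then per-node records
    (2-bit packed k-mer, float64 coverage, one edge-bitmask byte)."""
    with open(destination, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<BHQ", _FORMAT_VERSION, graph.k, len(graph.nodes)))
        for kmer in graph.sorted_nodes():
            node = graph.nodes[kmer]
            mask = 0
            for b in node.out_fwd:
                mask |= _BASE_BITS[b]
            for b in node.out_rev:
                mask |= _BASE_BITS[b] << 4
            fh.write(_pack_kmer(kmer))
            fh.write(struct.pack("<dB", node.coverage, mask))


def load_graph(path) -> DeBruijnGraph:
    """Inverse of :func:`save_graph`; raises ``ValueError`` on a foreign file."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(f"not a graph file (bad magic {magic!r})")
        version, k, count = struct.unpack("<BHQ", fh.read(11))
        if version != _FORMAT_VERSION:
            raise ValueError(f"unsupported graph format version {version}")
        graph = DeBruijnGraph(k)
        kbytes = (k + 3) // 4
        for _ in range(count):
            kmer = _unpack_kmer(fh.read(kbytes), k)
            coverage, mask = struct.unpack("<dB", fh.read(9))
            node = graph.get_or_add(kmer)
            node.coverage = coverage
            for b, bit in _BASE_BITS.items():
                if mask & bit:
                    node.out_fwd.add(b)
                if mask & (bit << 4):
                    node.out_rev.add(b)
    return graph


def merge_graphs(a: DeBruijnGraph, b: DeBruijnGraph) -> DeBruijnGraph:
    """Union of two graphs with the same k: coverages sum, edges union."""
    if a.k != b.k:
        raise ValueError(f"cannot merge graphs with k={a.k} and k={b.k}")
    merged = DeBruijnGraph(a.k)
    for src in (a, b):
        for kmer, node in src.nodes.items():
            m = merged.get_or_add(kmer)
            m.coverage += node.coverage
            m.out_fwd |= node.out_fwd
            m.out_rev |= node.out_rev
    return merged
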