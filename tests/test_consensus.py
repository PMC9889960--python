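"""Consensus traversal: branch choice, bubble rule, walks, variant docs."""

import pytest

import straindbg as sd
from straindbg.consensus import assemble_consensus, choose_branch, walk_consensus
from straindbg.dbg import _canon, reverse_complement
from straindbg.synthetic import random_genome, tiling_reads

from conftest import build_bubble_graph, snp_strain_pair


class TestChooseBranch:
    def test_single_candidate(self, chain_graph):
        g, seq = chain_graph
        canon, orient = _canon(seq[:7])
        # orient the position along seq so the expected next base is seq[7]
        base = choose_branch(g, (canon, orient), min_coverage=2)
        assert base == seq[7]

    def test_bubble_pair_beats_straight(self):
        # straight 10 vs rejoining pair 4+7: combined 11 > 10, take the 7 branch
        g, pos, bases = build_bubble_graph(10, 4, 7)
        assert choose_branch(g, pos, min_coverage=2) == bases["alt2"]

    def test_straight_beats_weak_pair(self):
        # straight 10 vs rejoining pair 4+5: combined 9 < 10, take the straight
        g, pos, bases = build_bubble_graph(10, 4, 5)
        assert choose_branch(g, pos, min_coverage=2) == bases["straight"]

    def test_no_candidate_above_threshold(self):
        g, pos, _ = build_bubble_graph(10, 4, 7)
        assert choose_branch(g, pos, min_coverage=50) is None

    def test_bubble_rule_disabled_takes_max_coverage(self):
        g, pos, bases = build_bubble_graph(10, 4, 7)
        assert choose_branch(g, pos, min_coverage=2, use_bubble_rule=False) == bases["straight"]


class TestWalkConsensus:
    def test_linear_chain_from_middle(self, chain_graph):
        g, seq = chain_graph
        mid = g.sorted_nodes()[len(g) // 2]
        path = walk_consensus(g, mid, min_coverage=1)
        assert path.kmer_count == len(g)
        assert len(path.sequence) == path.kmer_count + g.k - 1
        assert path.sequence in (seq, reverse_complement(seq))

    def test_cycle_visits_each_node_once(self):
        # a circular sequence: every node revisited exactly once then stop
        core = random_genome(30, seed=13, label="cyc")
        circular = core + core[:6]  # k-1 overlap wraps the cycle (k=7)
        g = sd.build_graph([sd.SequenceRecord("r", circular + core[6]), ], 7)
        seed = g.sorted_nodes()[0]
        path = walk_consensus(g, seed, min_coverage=0)
        ids = path.node_ids()
        assert len(ids) == len(set(ids))
        assert len(ids) >= len(g) - 1  # whole cycle traversed, no repeats

    def test_isolated_node(self):
        g = sd.build_graph([sd.SequenceRecord("r", "AACCGTC")], 7)
        path = walk_consensus(g, g.sorted_nodes()[0], min_coverage=0)
        assert path.kmer_count == 1 and len(path.sequence) == 7

    def test_path_geometry_invariant(self, two_strain_flank_fixture):
        g, _, _ = two_strain_flank_fixture
        comp = sd.component_scan(g, g.sorted_nodes()[0])
        path = walk_consensus(g, comp.seed, min_coverage=2)
        assert len(path.sequence) == path.kmer_count + g.k - 1
        for (a, ao), (b, bo) in zip(path.steps, path.steps[1:]):
            nxts = [n for _, n in g.successors(a, ao)]
            assert (b, bo) in nxts, "consecutive steps not joined by an edge"


class TestGreedyOracle:
    """Consensus walk equals an independent brute-force greedy walk on
    bubble-free graphs.

    The oracle recomputes neighbours from sequence arithmetic (no use of the
    stored edge sets) and maximizes next-node coverage step by step.
    """

    @staticmethod
    def _oracle_adjacency(reads, k):
        """Unordered canonical-pair adjacency rebuilt from the reads alone."""
        pairs = set()
        for seq in reads:
            for i in range(len(seq) - k):
                a, b = seq[i : i + k], seq[i + 1 : i + 1 + k]
                pairs.add(
                    frozenset(
                        (min(a, reverse_complement(a)), min(b, reverse_complement(b)))
                    )
                )
        return pairs

    @staticmethod
    def _oracle_neighbors(nodes, pairs, seq):
        here = min(seq, reverse_complement(seq))
        out = []
        for base in "ACGT":
            cand = seq[1:] + base
            canon = min(cand, reverse_complement(cand))
            if canon in nodes and frozenset((here, canon)) in pairs:
                out.append((canon, cand))
        return out

    def _oracle_walk(self, nodes, pairs, seed, min_coverage):
        def extend(start_seq, used):
            seq = start_seq
            order = []
            while True:
                best = None
                for canon, cand in self._oracle_neighbors(nodes, pairs, seq):
                    if nodes[canon] < min_coverage:
                        continue
                    if best is None or nodes[canon] > nodes[best[0]]:
                        best = (canon, cand)
                if best is None or best[0] in used:
                    break
                used.add(best[0])
                order.append(best)
                seq = best[1]
            return order

        used = {seed}
        fwd = extend(seed, used)
        rev = extend(reverse_complement(seed), used)
        sequence = seed + "".join(c[-1] for _, c in fwd)
        prefix = "".join(reverse_complement(c)[0] for _, c in rev[::-1])
        return prefix + sequence

    def _random_tree_graph(self, seed, k=11):
        """A random branching tree of k-mers: no cycles, hence no bubbles."""
        import networkx as nx

        rng_label = f"tree{seed}"
        trunk = random_genome(60, seed, rng_label)
        reads = [trunk]
        for b in range(3):
            at = 10 + 15 * b
            reads.append(trunk[:at] + random_genome(25, seed, f"{rng_label}b{b}"))
        self._last_reads = reads
        g = sd.build_graph([sd.SequenceRecord(f"r{i}", s) for i, s in enumerate(reads)], k)
        # verify acyclicity independently; reject colliding constructions
        ug = nx.Graph()
        for n in g.nodes:
            for m in g.neighbours(n):
                ug.add_edge(n, m)
        if ug.number_of_nodes() and not nx.is_forest(ug):
            return None
        cov_rng = __import__("numpy").random.default_rng(seed)
        for n in g.sorted_nodes():
            g.nodes[n].coverage = int(cov_rng.integers(1, 20))
        return g

    def test_matches_oracle_on_200_random_trees(self):
        checked = 0
        seed = 0
        while checked < 200:
            seed += 1
            g = self._random_tree_graph(seed)
            if g is None or len(g) < 3:
                continue
            nodes = {n: g.coverage(n) for n in g.nodes}
            pairs = self._oracle_adjacency(self._last_reads, 11)
            start = max(nodes, key=lambda n: (nodes[n], tuple(-ord(c) for c in n)))
            path = walk_consensus(g, start, min_coverage=1)
            expected = self._oracle_walk(nodes, pairs, start, min_coverage=1)
            assert path.sequence in (expected, reverse_complement(expected)), (
                f"walk differs from greedy oracle on tree seed={seed}"
            )
            checked += 1


class TestExploreLocalVariants:
    def _snp_doc(self):
        a, b = snp_strain_pair()
        reads = list(tiling_reads(a, 100, 20, "A")) + list(tiling_reads(b, 100, 20, "B"))
        g = sd.build_graph(reads, 15)
        contigs, docs = assemble_consensus(g, min_coverage=2)
        assert len(contigs) == 1
        return g, contigs[0], docs[0], (a, b)

    def test_snp_bubbles_found_with_junction_edges(self):
        g, contig, doc, _ = self._snp_doc()
        alts = [s for s in doc.segments if s.id != "contig_1"]
        assert len(alts) == 3  # one per planted SNP
        assert len(doc.edges) == 6  # two junction edges per alternative

    def test_alternatives_anchor_with_k_minus_1_overlaps(self):
        g, contig, doc, _ = self._snp_doc()
        k = g.k
        segmap = doc.segment_map()
        consensus = segmap["contig_1"].sequence
        for edge in doc.edges:
            assert edge.end1 - edge.beg1 == k - 1
            s1 = segmap[edge.sid1].sequence[edge.beg1 : edge.end1]
            s2 = segmap[edge.sid2].sequence[edge.beg2 : edge.end2]
            assert s1 == s2, "junction overlap sequences differ"
        # splicing each alternative into the consensus yields a valid strain walk
        for alt in [s for s in doc.segments if s.id != "contig_1"]:
            dep = next(e for e in doc.edges if e.sid2 == alt.id)
            rej = next(e for e in doc.edges if e.sid1 == alt.id)
            spliced = consensus[: dep.beg1] + alt.sequence + consensus[rej.end2 :]
            assert len(spliced) == len(consensus)  # SNP bubble: same length

    def test_no_offpath_branches_single_segment(self, chain_graph):
        g, _ = chain_graph
        path = walk_consensus(g, g.sorted_nodes()[0], min_coverage=1)
        doc = sd.explore_local_variants(g, path, min_coverage=1)
        assert len(doc.segments) == 1 and not doc.edges

    def test_dead_end_branch_not_emitted(self):
        # a side branch that never rejoins the path is a tip, not a variant
        trunk = random_genome(80, seed=21, label="trunk")
        side = trunk[:30] + random_genome(20, seed=21, label="side")
        g = sd.build_graph(
            [sd.SequenceRecord("a", trunk), sd.SequenceRecord("b", side)], 15
        )
        path = walk_consensus(g, _canon(trunk[:15])[0], min_coverage=0)
        doc = sd.explore_local_variants(g, path, min_coverage=0)
        assert len(doc.segments) == 1 and not doc.edges


class TestAssembleConsensus:
    def test_two_components_two_contigs(self):
        g1 = random_genome(100, seed=31, label="c1")
        g2 = random_genome(100, seed=31, label="c2")
        g = sd.build_graph(
            [sd.SequenceRecord("a", g1), sd.SequenceRecord("b", g2)], 15
        )
        contigs, docs = assemble_consensus(g, min_coverage=0)
        assert len(contigs) == 2
        recovered = {c.sequence for c in contigs} | {
            reverse_complement(c.sequence) for c in contigs
        }
        assert g1 in recovered and g2 in recovered

    def test_all_below_min_coverage(self, chain_graph):
        g, _ = chain_graph
        contigs, _ = assemble_consensus(g, min_coverage=50)
        assert contigs == []

    def test_multiple_contigs_mode_on_shared_core(self, two_strain_flank_fixture):
        g, a, b = two_strain_flank_fixture
        contigs, _ = assemble_consensus(g, min_coverage=2, multiple_contigs=True)
        assert len(contigs) >= 2
        # no two emitted paths share a node
        seen = set()
        for c in contigs:
            ids = set(c.node_ids())
            assert not (ids & seen)
            seen |= ids

    def test_default_mode_consumes_components_once(self, two_strain_flank_fixture):
        g, _, _ = two_strain_flank_fixture
        contigs, _ = assemble_consensus(g, min_coverage=2)
        assert len(contigs) == 1  # one contig per connected component

    def test_deterministic(self, two_strain_flank_fixture):
        g, a, b = two_strain_flank_fixture
        import copy

        r1 = assemble_consensus(copy.deepcopy(g), min_coverage=2)[0]
        r2 = assemble_consensus(copy.deepcopy(g), min_coverage=2)[0]
        assert [c.sequence for c in r1] == [c.sequence for c in r2]


def test_perfect_reconstruction_2kb():
    genome = random_genome(2000, seed=1)
    g = sd.build_graph(tiling_reads(genome, 150, 30), 31)
    contigs, _ = assemble_consensus(g, min_coverage=1)
    assert len(contigs) == 1
    assert contigs[0].sequence in (genome, reverse_complement(genome))
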