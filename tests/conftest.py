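"""Shared fixtures: small crafted graphs with prescribed topology/coverage."""

import pytest
from hypothesis import settings

import straindbg as sd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from straindbg.dbg import _canon
from straindbg.synthetic import random_genome, tiling_reads


def set_coverage(graph, sequence, value):
    """Assign *value* to every k-mer node spelled by *sequence*."""
    k = graph.k
    for i in range(len(sequence) - k + 1):
        graph.nodes[_canon(sequence[i : i + k])[0]].coverage = value


def build_bubble_graph(cov_straight, cov_alt1, cov_alt2, k=7, seed=5):
    """A junction with a straight branch and two branches that rejoin.

    Returns ``(graph, junction position, branch bases)`` where the branch
    bases dict maps 'straight'/'alt1'/'alt2' to the first nucleotide of each
    branch.  The stem and shared tail have coverage 10.
    """
    for trial in range(100):
        stem = random_genome(20, seed + trial, "stem")
        straight = random_genome(20, seed + trial, "straight")
        alt1 = random_genome(10, seed + trial, "bB")
        alt2 = random_genome(10, seed + trial, "bC")
        tail = random_genome(20, seed + trial, "tail")
        if len({straight[0], alt1[0], alt2[0]}) != 3:
            continue
        reads = [stem + straight, stem + alt1 + tail, stem + alt2 + tail]
        graph = sd.build_graph([sd.SequenceRecord(f"r{i}", r) for i, r in enumerate(reads)], k)
        junction = _canon(stem[-k:])[0]
        if graph.nodes[junction].stub_count() < 4:
            continue  # accidental k-mer sharing collapsed the junction
        set_coverage(graph, stem[-(k - 1) :] + straight, cov_straight)
        set_coverage(graph, stem[-(k - 1) :] + alt1 + tail[: k - 1], cov_alt1)
        set_coverage(graph, stem[-(k - 1) :] + alt2 + tail[: k - 1], cov_alt2)
        set_coverage(graph, stem, 10)
        set_coverage(graph, tail, 10)
        position = _canon(stem[-k:])
        bases = {"straight": straight[0], "alt1": alt1[0], "alt2": alt2[0]}
        return graph, position, bases
    raise RuntimeError("could not construct a collision-free bubble graph")


def snp_strain_pair(length=600, snp_positions=(150, 300, 450), seed=7):
    """Two strain sequences differing by isolated SNPs (spaced beyond k)."""
    base = random_genome(length, seed, "base")
    flipped = list(base)
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for p in snp_positions:
        flipped[p] = swap[base[p]]
    return base, "".join(flipped)


@pytest.fixture
def chain_graph():
    """A 40 bp linear sequence as a k=7 chain graph, uniform coverage 5."""
    seq = random_genome(40, seed=11, label="chain")
    graph = sd.build_graph([sd.SequenceRecord("r", seq)], 7)
    for node in graph.nodes.values():
        node.coverage = 5
    return graph, seq


@pytest.fixture
def two_strain_flank_fixture():
    """Two strains sharing a 1 kb core with distinct 500 bp flanks, 50x each."""
    core = random_genome(1000, seed=2, label="core")
    strain_a = random_genome(500, 2, "flankA1") + core + random_genome(500, 2, "flankA2")
    strain_b = random_genome(500, 2, "flankB1") + core + random_genome(500, 2, "flankB2")
    reads = list(tiling_reads(strain_a, 150, 50, "A")) + list(
        tiling_reads(strain_b, 150, 50, "B")
    )
    graph = sd.build_graph(reads, 31)
    return graph, strain_a, strain_b
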