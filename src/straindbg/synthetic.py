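"""Synthetic multi-strain communities and desk-scale assembly evaluation.

Emulates, at small scale, a shotgun read set from a community of reference
genomes plus mutated strains: per-genome SNP/indel strain variants,
abundance-weighted uniform read sampling from both strands, and independent
per-base substitution errors.  All randomness fans out derivably from a
single integer seed, so adding one genome never perturbs another's reads.

Evaluation is alignment-free: the genome fraction of a reference is the
percentage of its positions covered by at least one k-mer shared with the
assembly (strand-insensitive).  Exact on error-free fixtures; not
numerically comparable to alignment-based evaluation on errorful data.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .dbg import reverse_complement, _canon
from .io_formats import SequenceRecord

_BASES = np.array(list("ACGT"))


def _child_rng(seed: int, label: str) -> np.random.Generator:
    """Per-component generator derived from the master seed and a label."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def random_genome(length: int, seed: int, label: str = "genome") -> str:
    rng = _child_rng(seed, label)
    return "".join(_BASES[rng.integers(0, 4, length)])


@dataclass
class StrainSpec:
    """Per-strain mutation rates (events per base)."""

    snp_rate: float = 0.0
    indel_rate: float = 0.0


@dataclass
class SimulatedCommunity:
    """Ground truth for a simulated multi-strain community.

    ``genomes`` are the reference sequences; each genome may carry strain
    specs producing additional mutated sequences.  ``abundances`` weight the
    read counts of the final sequences (references and strains alike);
    sequences without an entry default to weight 1.
    """

    genomes: list[tuple[str, str]]
    strain_specs: dict[str, list[StrainSpec]] = field(default_factory=dict)
    abundances: dict[str, float] = field(default_factory=dict)
    read_length: int = 150
    depth: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError(f"error rate must be in [0, 1), got {self.error_rate}")
        for name, w in self.abundances.items():
            if w <= 0:
                raise ValueError(f"abundance for {name!r} must be positive, got {w}")

    def final_sequences(self) -> list[tuple[str, str]]:
        """References plus mutated strains, with derived names ``<id>_strain<j>``."""
        out = []
        for gid, seq in self.genomes:
            out.append((gid, seq))
            for j, spec in enumerate(self.strain_specs.get(gid, []), start=1):
                name = f"{gid}_strain{j}"
                mutated, _ = mutate_strain(
                    seq, spec.snp_rate, spec.indel_rate,
                    seed=[self.seed, zlib.crc32(name.encode())],
                )
                out.append((name, mutated))
        return out


def mutate_strain(
    genome: str, snp_rate: float, indel_rate: float, seed
) -> tuple[str, list[tuple[int, str, str]]]:
    """Mutate a genome with independent per-base SNP and indel events.

    SNPs substitute a uniform choice of the three alternative bases; indels
    insert or delete (equiprobably) 1-3 bases.  Returns the mutated sequence
    and the edit list ``(position, op, detail)`` with ``op`` one of
    ``snp``/``ins``/``del``, for ground-truth bookkeeping.  Deterministic
    under the seed.
    """
    for name, rate in (("snp_rate", snp_rate), ("indel_rate", indel_rate)):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must be in [0, 1), got {rate}")
    if not genome:
        raise ValueError("cannot mutate an empty genome")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    edits: list[tuple[int, str, str]] = []
    i = 0
    while i < len(genome):
        base = genome[i]
        if indel_rate and rng.random() < indel_rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion before this base
                ins = "".join(_BASES[rng.integers(0, 4, length)])
                out.append(ins)
                edits.append((i, "ins", ins))
                out.append(base)
            else:  # deletion of up to `length` bases
                deleted = genome[i : i + length]
                edits.append((i, "del", deleted))
                i += length
                continue
        elif snp_rate and rng.random() < snp_rate:
            alt = rng.choice([b for b in "ACGT" if b != base])
            out.append(str(alt))
            edits.append((i, "snp", f"{base}>{alt}"))
        else:
            out.append(base)
        i += 1
    return "".join(out), edits


def tiling_reads(
    sequence: str, read_length: int, depth: float, name: str = "tile"
) -> Iterator[SequenceRecord]:
    """Deterministic error-free reads tiling a sequence end to end.

    Start positions step by ``read_length/depth`` (at least 1), with a final
    read flush against the 3' end, so every k-mer of the sequence is present
    in the read set.  Interior positions reach approximately *depth*-fold
    coverage; coverage ramps down toward the ends.
    """
    if read_length > len(sequence):
        raise ValueError("read length exceeds sequence length")
    step = max(1, round(read_length / depth))
    starts = list(range(0, len(sequence) - read_length + 1, step))
    if starts[-1] != len(sequence) - read_length:
        starts.append(len(sequence) - read_length)
    for i, start in enumerate(starts):
        yield SequenceRecord(
            id=f"{name}_r{i}", sequence=sequence[start : start + read_length]
        )


def simulate_reads(community: SimulatedCommunity) -> Iterator[SequenceRecord]:
    """Stream error-bearing reads from every final sequence of the community.

    Per sequence the read count is ``ceil(depth * length / read_length)``
    scaled by its abundance weight; start positions and strands are uniform,
    substitution errors independent per base.  Byte-identical across calls
    with the same community.
    """
    rl = community.read_length
    for name, seq in community.final_sequences():
        if rl > len(seq):
            raise ValueError(
                f"read length {rl} exceeds sequence {name!r} length {len(seq)}"
            )
        weight = community.abundances.get(name, 1.0)
        n_reads = math.ceil(community.depth * len(seq) / rl * weight)
        rng = _child_rng(community.seed, f"reads:{name}")
        starts = rng.integers(0, len(seq) - rl + 1, n_reads)
        strands = rng.integers(0, 2, n_reads)
        for i in range(n_reads):
            read = seq[starts[i] : starts[i] + rl]
            if strands[i]:
                read = reverse_complement(read)
            if community.error_rate:
                arr = np.frombuffer(read.encode(), dtype="S1").copy()
                hits = np.nonzero(rng.random(rl) < community.error_rate)[0]
                for pos in hits:
                    current = arr[pos].decode()
                    arr[pos] = rng.choice([b for b in "ACGT" if b != current]).encode()
                read = arr.tobytes().decode()
            yield SequenceRecord(id=f"{name}_r{i}", sequence=read, source=name)


def evaluate_assembly(
    contigs: Sequence[str], references: Sequence[str], k: int
) -> dict:
    """Alignment-free assembly metrics.

    Returns ``genome_fraction`` (per reference, percent of positions covered
    by at least one k-mer shared with any contig, strand-insensitive),
    ``n50`` (largest L such that contigs of length >= L hold at least half
    the total assembly length) and ``contig_count``.
    """
    if not references:
        raise ValueError("no reference sequences given")
    kmers: set[str] = set()
    for contig in contigs:
        for i in range(len(contig) - k + 1):
            window = contig[i : i + k]
            if "N" not in window:
                kmers.add(_canon(window)[0])
    fractions = []
    for ref in references:
        covered = np.zeros(len(ref), dtype=bool)
        for i in range(len(ref) - k + 1):
            window = ref[i : i + k]
            if "N" not in window and _canon(window)[0] in kmers:
                covered[i : i + k] = True
        fractions.append(float(100.0 * covered.sum() / len(ref)))
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    n50 = 0
    acc = 0
    for length in lengths:
        acc += length
        if acc * 2 >= total:
            n50 = length
            break
    return {
        "genome_fraction": fractions,
        "n50": n50,
        "contig_count": len(contigs),
    }
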