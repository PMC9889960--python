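# straindbg

Strain-aware de Bruijn graph assembly for shotgun metagenomes.

Metagenomic samples — viral quasispecies especially — contain clouds of
closely related strains whose genomes share long stretches of sequence.
Conventional assemblers collapse the assembly graph into linear contigs and
discard exactly the within-species variation (SNP and indel bubbles,
coverage-stratified haplotypes) that distinguishes those strains.
`straindbg` is a small, deterministic assembler built for that problem: it
keeps local variation in sequence-graph output (GFA2/FASTG) and can
decompose coverage so that sequence shared between variants is emitted once
per variant.

## The method

Reads are decomposed into k-mers (odd k; each k-mer stored once as the
lexicographic minimum of itself and its reverse complement) and assembled
into a de Bruijn graph whose nodes carry coverage — the number of read
windows supporting them — and whose edges join k-mers overlapping by k−1
bases.  The graph is pruned of nodes below a minimum coverage (default 2)
and of short dead-end "tips" (up to 100 nodes by default), both signatures
of sequencing error.  Three traversals are available:

- **consensus** — each connected component is walked from its
  highest-coverage node, taking the highest-coverage branch at each
  junction.  If two branches rejoin within a bounded lookahead (a bubble)
  and their combined mean coverage c₁ + c₂ exceeds every other branch, the
  route through the bubble is taken (the higher of the pair).  Off-path
  branches that return to the path are then re-explored and written as
  alternative segments of a GFA2/FASTG sequence graph, so variation
  survives alongside the FASTA contig.  With `-M`, only path nodes are
  consumed per walk and one component can yield many contigs.
- **subtractive** — repeated maximum-coverage walks.  After each walk the
  number of variants covering every path node is estimated from the
  normalized coverage change per step,
  δ = (c_cur − c_prev) / max(c_cur, c_prev) ∈ [−1, 1],
  walking outward from the path's minimum-coverage node (one variant by
  assumption; |δ| > Δ_SW marks entering/leaving a shared region, default
  Δ_SW = 0.8, flag `-W`).  Single-variant nodes are zeroed; multi-variant
  nodes lose an amount linearly interpolated from the flanking
  single-variant coverages — so shared cores stay traversable and are
  emitted once per variant.
- **unitig** — maximal non-branching paths only.

A fourth operation consumes a sequence graph plus a per-segment mapping
score table (identity × query cover, e.g. from aligning segments to
reference genomes) and walks one contig per strain, picking at every bubble
the branch scoring highest for that strain (ties keep the consensus branch).

A synthetic-community module (reference genomes, SNP/indel-mutated strains,
abundance-weighted error-bearing reads, alignment-free evaluation) makes the
whole pipeline testable without external data.

## Worked example

`examples/02_subtractive_two_strains.py` builds two strains that share a
1 kb core (coverage 100×) and differ in their 500 bp flanks (50× each), and
runs the subtractive walk at Δ_SW = 0.4:

```
contigs: 2  lengths: [1995, 1995]
contigs containing the shared core: 2
genome fraction per strain (%): [99.75, 99.75]
```

The shared core appears in *both* contigs: the first walk estimated two
variants across it and subtracted only one variant's worth of coverage, so
the second walk could traverse it again.  Together the two contigs
reconstruct essentially all of both strains.  The other examples cover
consensus assembly of a two-genome community, sequence-graph output with a
per-strain graph walk that recovers planted haplotypes byte for byte, and
graph serialization/merging.

The same workflows are available from the shell:

```bash
straindbg simulate --genomes 2 --length 2000 -o community
straindbg assemble -i community_reads.fastq -k 31 --algorithm subtractive -W 0.4 -o asm
straindbg assemble -i community_reads.fastq -k 31 --gfa -o asm_mc
straindbg strains --gfa asm_mc_contig_1.gfa --scores scores.tsv --strain A --strain B
straindbg graph build reads.fastq -k 31 -o part1.sfdbg   # then: graph merge, graph info
```

## Layout

- `src/straindbg/dbg.py` — canonical-k-mer graph, pruning, unitigs, serialization
- `src/straindbg/consensus.py` — consensus walk, bubble rule, variant exploration
- `src/straindbg/subtractive.py` — δ statistic, variant counts, coverage subtraction
- `src/straindbg/strains.py` — score-guided per-strain graph walks
- `src/straindbg/io_formats.py` — FASTA/FASTQ reading, FASTA/GFA2/FASTG writing
- `src/straindbg/synthetic.py` — community simulation and evaluation
- `src/straindbg/pipeline.py`, `cli.py` — end-to-end runs and the `straindbg` command
- `docs/methods.md` — model, parameters, numerical choices, limitations
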