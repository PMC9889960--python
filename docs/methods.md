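# Methods

## Graph model

Nodes are canonical k-mers: a k-mer and its reverse complement map to the
same node, stored as the lexicographic minimum, with the orientation carried
alongside wherever a walk needs it.  k must be odd — an even-length k-mer
can equal its own reverse complement, which would make the orientation of a
canonical node ambiguous — and is bounded by a configurable maximum
(default 31).  Coverage counts every occurrence of a k-length window across
all reads (not per-read presence); windows containing an N are skipped.
Each directed edge is stored on both endpoints in mirrored form, and edge
symmetry is an invariant checked after every mutating operation in the test
suite.  Node iteration is always in sorted k-mer order; every traversal,
writer and the whole pipeline are deterministic for identical inputs, which
we consider a feature worth a small constant factor.

Storage grows dynamically with the k-mer set; there is no fixed-capacity
hash table and no silent dropping of k-mers.  Graphs serialize to a
versioned binary format (magic `SFDBG`, k, then per-node records: 2-bit
packed k-mer, float64 coverage, one edge-bitmask byte).  Merging graphs of
equal k sums coverages and unions edges.

## Pruning

The coverage filter (default minimum 2) runs before tip clipping: removing
low-coverage nodes creates new tips that the tip pass then cleans.  A tip is
a dead-end chain of at most `tip_length` nodes (default 100) measured in
nodes, hanging off a fork.  Clipping is fork-centric: at a node side with
two or more branches, every branch that dead-ends within the length bound is
a candidate; if *all* branches on that side dead-end, the best one — longest,
then highest total coverage, then lexicographically smallest spelling — is
kept and the rest clipped.  This keeps the free ends of genuine linear
chains (which are dead ends but not errors) while removing error branchlets,
and it iterates to a fixed point, so pruning is idempotent.

## Consensus traversal

Each component is explored (breadth-first, deterministic) to find its
highest-coverage node, with ties broken toward the smallest k-mer; the walk
extends from that seed forward, then backward, and is reported 5'→3' of the
final spelled strand.  At a junction, candidate branches must meet the
minimum coverage; the plain choice maximizes next-node coverage with ties
broken A<C<G<T.  The bubble rule modifies this: every unordered pair of
candidates is probed by a greedy lookahead walk (bounded, default 64 nodes —
unbounded search would be quadratic); if the two walks share a node, the
pair forms a bubble, and each branch's mean node coverage is computed over
the nodes strictly before the first shared node (including the shared
continuation would systematically inflate bubble pairs).  A pair whose
combined mean exceeds the lookahead mean of every non-pair candidate wins,
and its higher-coverage member is taken.  We compare the pair against each
other candidate singly, not against their sum; with at most four branches
per side this is the natural reading and is pinned by tests.

Walks stop at dead ends, when no branch meets the coverage threshold, or
when the chosen branch leads to a node already in the current path (repeat
protection).  In default mode the walk's whole component is then consumed;
with the multiple-contigs flag only path nodes are consumed and the residual
component is re-scanned, so one tangled component can yield many contigs.
Components below 2 nodes are consumed silently.  Contigs below the minimum
FASTA length (default 100 bp; 500 bp is the usual reporting convention for
metagenome evaluation) are dropped at write time but still consume nodes.

### Local variant exploration

For sequence-graph output, every node of the final path is examined for
off-path branches meeting the coverage threshold.  Each is followed
depth-first (greedy highest coverage, cycle-safe, at most 500 nodes by
default); a walk that returns to the path at a strictly later position —
strictness prevents inversions masquerading as bubbles — becomes an
alternative segment, and exploration resumes from the rejoin position.
Only forward-orientation branches are probed: an alternative that rejoins
the path is reachable from its departure junction in the forward
orientation, so reverse exploration would only rediscover the same bubbles
from their other end.

An alternative segment spells the complete off-path walk (m off-path nodes →
m+k−1 bases): its first k−1 bases equal the consensus suffix of the branch
k-mer and its last k−1 bases the consensus prefix of the rejoin k-mer.  Both
junctions are therefore exact k−1-base overlaps, written as GFA2 E lines
with internal coordinates on the consensus segment; each alternative is also
listed as an ordered group.  FASTG output lists the same segments with
edge-derived adjacency in the header (v1.0 draft colon syntax, no bracket
notation); variation is carried by distinct segments in both formats.

## Subtractive walk

Shared sequence carries the summed coverage of every variant through it.
The subtractive walk therefore reduces, rather than deletes, traversed
coverage.  Each round seeds at the locally maximal node found by a
budget-bounded component scan (default 1000 nodes — full component
exploration is unnecessary for seed choice and slow on large tangles),
walks the maximum-coverage path ignoring bubbles, and then estimates the
number of variants covering each path node:

- the minimum-coverage node of the path is assigned one variant; ties go to
  the node closest to the path's end;
- walking outward from it, each step computes
  δ = (c_cur − c_prev)/max(c_cur, c_prev); "previous" is the previous node
  of that outward walk (which, leftward, is the higher path index);
- δ > Δ_SW (a sharp rise) increments the variant count — the walk is
  entering sequence shared by one more variant; δ < −Δ_SW decrements it,
  floored at 1.  Comparisons are strict, so δ = ±Δ_SW exactly does not
  trigger.

The sign pairing deserves a note.  Starting from the minimum (one variant),
a region of *higher* coverage can only be covered by *more* variants, so a
sharp rise must increase the count — that is the default, and it is what
makes unique nodes end at zero and shared cores keep residual coverage in
the two-strain fixture.  The opposite pairing (drop→+1, rise→−1) is exposed
as `as_printed`/`--as-printed-delta-rule` for comparison; the two modes
genuinely differ and a test pins the divergence.

Subtraction: single-variant nodes are set to exactly 0; multi-variant nodes
lose an amount linearly interpolated, by path index, between the coverages
of the nearest single-variant nodes before and after (constant one-sided
extrapolation when a side has none — the minimum node guarantees at least
one single-variant position).  Coverages become fractional and are clamped
at 0; minimum-coverage comparisons use ≥ on the real value.  Each round
zeroes at least the path's minimum node (coverage ≥ the threshold ≥ 1), so
total coverage strictly decreases and termination is guaranteed even on
cycles; the threshold is required to be ≥ 1 for this reason.  Subtraction
is applied immediately after each walk, before the next seed search.  A
contig identical (or reverse-complement-identical) to one already emitted
in the run is dropped: re-walks of residual shared cores can reproduce a
path verbatim.

## Strain-specific walks

Given a consensus sequence graph and a table mapping (segment, strain) to
(identity, query cover) — supplied as a TSV rather than by invoking an
aligner, which keeps the module testable offline — a strain walk traverses
the backbone and, at every junction with alternatives, takes the branch with
the highest identity × query-cover product.  Missing entries are absent,
not zero.  An exact tie, or a junction where no candidate has a score,
keeps the backbone branch.  Alternatives overlapping an already-chosen
alternative are skipped (greedy resolution in walk order).  A helper builds
exact-substring score tables against reference sequences for fixtures.

## Synthetic communities

The generator emulates a multi-strain shotgun read set at desk scale:
reference genomes (i.i.d. uniform bases), per-genome strain variants with
independent per-base SNPs (uniform over the three alternatives) and indels
(insert/delete equiprobable, length 1–3), abundance-weighted read counts
(⌈depth × length / read length⌉ × weight), uniform start positions and
strands, and independent per-base substitution errors.  Read errors are
substitutions only: that suffices to exercise coverage pruning, and indel
read errors would not change what the tests demonstrate.  A single integer
seed fans out to per-sequence generators through a CRC of the sequence
name, so adding a genome never perturbs another genome's reads.  A separate
`tiling_reads` helper emits deterministic error-free reads stepping
read_length/depth positions with a flush final read, guaranteeing every
k-mer of the template is sampled — uniform sampling leaves terminal k-mers
uncovered with non-trivial probability, which matters only for
exact-reconstruction demonstrations.

Evaluation is alignment-free: a reference position counts as covered when
some k-mer containing it is shared (canonically) with any contig, and N50
is the usual length-weighted median.  On error-free fixtures this is exact;
on errorful data it is *not* numerically comparable to alignment-based
evaluators, and passing fixtures here says nothing about mismatch or
misassembly rates on real reads.  Defaults used by the test fixtures — 2 kb
genomes, 30–50× depth, 150 bp reads, SNP rate 0.02 between strains,
Δ_SW = 0.4 when strain sensitivity is wanted — are chosen as small but
representative of the strain-variation regime the method targets.

## Known limitations

- Pairing information in read names is carried as provenance only; there is
  no paired-end repeat resolution and no scaffolding.
- The bubble lookahead is greedy and bounded; branches that rejoin beyond
  the lookahead are treated as independent.
- Variant counts are integer estimates from a single statistic; abundance
  estimation and probabilistic haplotype phasing are out of scope.
- The k-mer-based genome fraction overstates agreement in repeat regions
  shorter than k and ignores base-level errors within unshared k-mers.
- Single-threaded by design: reproducibility is prioritized over speed.
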