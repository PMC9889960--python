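"""Reading sequencing input and writing FASTA / GFA2 / FASTG output.

Readers accept FASTA and FASTQ (optionally gzipped); characters outside
{A,C,G,T,N} are mapped to N on read (and thus excluded from k-mer counting),
which keeps real-world inputs usable without rejecting whole files.  All
writers are byte-deterministic for equal inputs.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = re.compile(r"[^ACGTN]")
_WRAP = 80


@dataclass
class SequenceRecord:
    """A named DNA sequence; qualities, if any, were parsed and discarded."""

    id: str
    sequence: str
    source: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record with empty id")
        if not self.sequence:
            raise ValueError(f"sequence record {self.id!r} with empty sequence")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map any character outside {A,C,G,T,N} to N."""
    return _VALID.sub("N", seq.upper())


def _open_text(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path, format: str = "auto") -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file (gzip transparent).

    With ``format="auto"`` the format is detected from the first character
    ('>' FASTA, '@' FASTQ).  FASTQ qualities are parsed but discarded.
    Malformed records raise ``ValueError`` naming the file.
    """
    handle = _open_text(path)
    try:
        if format == "auto":
            first = handle.read(1)
            handle.seek(0)
            if first == ">":
                format = "fasta"
            elif first == "@":
                format = "fastq"
            else:
                raise ValueError(
                    f"{path}: cannot detect format from first character {first!r}"
                )
        try:
            for i, rec in enumerate(SeqIO.parse(handle, format)):
                seq = normalize_sequence(str(rec.seq))
                if not seq:
                    raise ValueError(f"{path}: record {rec.id!r} has empty sequence")
                yield SequenceRecord(id=rec.id, sequence=seq, source=f"{path}#{i}")
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    finally:
        handle.close()


# -- FASTA contigs ---------------------------------------------------------


def _fmt_cov(value: float) -> str:
    if float(value).is_integer():
        return str(int(value))
    return f"{value:.2f}"


def _wrap(seq: str) -> str:
    return "\n".join(seq[i : i + _WRAP] for i in range(0, len(seq), _WRAP))


def write_contigs_fasta(contigs, destination, min_length: int = 0) -> int:
    """Write contig paths as FASTA with coverage statistics in the header.

    Contigs shorter than *min_length* are skipped.  Records are emitted by
    descending sequence length with a full-sequence tie-break, so output is
    reproducible.  Returns the number of records written.
    """
    kept = [c for c in contigs if len(c.sequence) >= min_length]
    kept.sort(key=lambda c: (-len(c.sequence), c.sequence))
    with open(destination, "w") as fh:
        for i, contig in enumerate(kept, start=1):
            covs = contig.coverages
            mean = sum(covs) / len(covs)
            fh.write(
                f">contig_{i} length={len(contig.sequence)}"
                f" kmer_count={len(covs)}"
                f" cov_mean={mean:.2f}"
                f" cov_min={_fmt_cov(min(covs))}"
                f" cov_max={_fmt_cov(max(covs))}\n"
            )
            fh.write(_wrap(contig.sequence) + "\n")
    return len(kept)


def write_fasta(records: dict[str, str], destination) -> int:
    """Plain multi-FASTA writer (id -> sequence), 80-column wrapped."""
    with open(destination, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{_wrap(seq)}\n")
    return len(records)


# -- sequence graph document ----------------------------------------------


@dataclass
class Segment:
    id: str
    sequence: str
    coverage: Optional[float] = None


@dataclass
class Edge:
    """An overlap edge: *sid1*[beg1:end1] aligns to *sid2*[beg2:end2].

    Junction edges between a consensus segment and an alternative segment
    always overlap exactly k-1 bases.
    """

    id: str
    sid1: str
    beg1: int
    end1: int
    sid2: str
    beg2: int
    end2: int


@dataclass
class GraphPath:
    name: str
    segment_ids: list[str]


@dataclass
class SequenceGraphDoc:
    """Segments + overlap edges + named paths: the GFA2/FASTG-serializable
    representation of a consensus contig with its local variation."""

    segments: list[Segment] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    paths: list[GraphPath] = field(default_factory=list)

    def segment_map(self) -> dict[str, Segment]:
        return {s.id: s for s in self.segments}

    def validate(self) -> None:
        seen = set()
        for seg in self.segments:
            if seg.id in seen:
                raise ValueError(f"duplicate segment id {seg.id!r}")
            seen.add(seg.id)
        lengths = {s.id: len(s.sequence) for s in self.segments}
        for edge in self.edges:
            for sid in (edge.sid1, edge.sid2):
                if sid not in lengths:
                    raise ValueError(f"edge {edge.id} references unknown segment {sid!r}")
            if edge.end1 - edge.beg1 != edge.end2 - edge.beg2:
                raise ValueError(f"edge {edge.id} has mismatched overlap lengths")
        for path in self.paths:
            for sid in path.segment_ids:
                if sid not in lengths:
                    raise ValueError(f"path {path.name} references unknown segment {sid!r}")


# -- GFA2 ------------------------------------------------------------------


def _gfa_pos(pos: int, seg_len: int) -> str:
    return f"{pos}$" if pos == seg_len else str(pos)


def write_gfa2(doc: SequenceGraphDoc, destination) -> None:
    """Emit the document as GFA2 (H/S/E/O lines), byte-deterministic.

    Segments carry mean coverage as an optional ``DP:f:`` tag; each named
    path becomes an ordered (O) group.  End-of-segment coordinates get the
    ``$`` sentinel required by the format.
    """
    doc.validate()
    lengths = {s.id: len(s.sequence) for s in doc.segments}
    lines = ["H\tVN:Z:2.0"]
    for seg in sorted(doc.segments, key=lambda s: s.id):
        line = f"S\t{seg.id}\t{len(seg.sequence)}\t{seg.sequence}"
        if seg.coverage is not None:
            line += f"\tDP:f:{seg.coverage:.2f}"
        lines.append(line)
    for edge in sorted(doc.edges, key=lambda e: (e.sid1, e.beg1, e.sid2, e.beg2, e.id)):
        lines.append(
            "E\t{id}\t{s1}+\t{s2}+\t{b1}\t{e1}\t{b2}\t{e2}\t*".format(
                id=edge.id,
                s1=edge.sid1,
                s2=edge.sid2,
                b1=_gfa_pos(edge.beg1, lengths[edge.sid1]),
                e1=_gfa_pos(edge.end1, lengths[edge.sid1]),
                b2=_gfa_pos(edge.beg2, lengths[edge.sid2]),
                e2=_gfa_pos(edge.end2, lengths[edge.sid2]),
            )
        )
    for path in doc.paths:
        refs = " ".join(f"{sid}+" for sid in path.segment_ids)
        lines.append(f"O\t{path.name}\t{refs}")
    with open(destination, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gfa2(path) -> SequenceGraphDoc:
    """Parse a GFA2 file produced by :func:`write_gfa2`.

    Unknown record types are skipped with a warning; an E line that names an
    absent segment raises ``ValueError``.  For files written by this package,
    ``write_gfa2(read_gfa2(f))`` reproduces *f* byte for byte.
    """
    doc = SequenceGraphDoc()
    known: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "H":
                continue
            if tag == "S":
                sid, _, seq = fields[1], fields[2], fields[3]
                coverage = None
                for extra in fields[4:]:
                    if extra.startswith("DP:f:"):
                        coverage = float(extra[5:])
                doc.segments.append(Segment(id=sid, sequence=seq, coverage=coverage))
                known.add(sid)
            elif tag == "E":
                eid = fields[1]
                sid1, sid2 = fields[2].rstrip("+-"), fields[3].rstrip("+-")
                for sid in (sid1, sid2):
                    if sid not in known:
                        raise ValueError(
                            f"{path}:{lineno}: E line references unknown segment {sid!r}"
                        )
                b1, e1, b2, e2 = (int(f.rstrip("$")) for f in fields[4:8])
                doc.edges.append(Edge(eid, sid1, b1, e1, sid2, b2, e2))
            elif tag == "O":
                name = fields[1]
                refs = [r.rstrip("+-") for r in fields[2].split(" ")]
                for sid in refs:
                    if sid not in known:
                        raise ValueError(
                            f"{path}:{lineno}: O line references unknown segment {sid!r}"
                        )
                doc.paths.append(GraphPath(name=name, segment_ids=refs))
            else:
                logger.warning("%s:%d: skipping unknown GFA2 record type %r", path, lineno, tag)
    return doc


# -- FASTG -----------------------------------------------------------------


def write_fastg(doc: SequenceGraphDoc, destination) -> None:
    """Emit the document as FASTG (v1.0 draft adjacency syntax).

    Each segment becomes one record; successors (segments entered by an
    overlap edge leaving this one) are listed colon/comma-separated in the
    header, which always ends with a semicolon.  Variation is carried by
    distinct segments, mirroring the GFA2 representation.
    """
    doc.validate()
    succ: dict[str, set[str]] = {s.id: set() for s in doc.segments}
    for edge in doc.edges:
        succ[edge.sid1].add(edge.sid2)
    with open(destination, "w") as fh:
        for seg in sorted(doc.segments, key=lambda s: s.id):
            header = seg.id
            if succ[seg.id]:
                header += ":" + ",".join(sorted(succ[seg.id]))
            fh.write(f">{header};\n{_wrap(seg.sequence)}\n")
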