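"""Strain-specific contig reconstruction from a sequence graph.

A consensus contig's sequence graph keeps the local variation (bubbles)
that the linear contig discarded.  Given a per-segment, per-strain mapping
score table — typically identity and query cover from aligning every
segment against reference genomes — a walk through the graph can pick, at
every junction, the branch that best matches one particular strain,
yielding one contig per strain.

The score of a branch for a strain is mapping identity multiplied by the
fraction of the alignment covering the query segment.  Ambiguous junctions
(an exact score tie, or no scored candidate at all) keep the consensus
contig's own branch.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Optional

from .io_formats import SequenceGraphDoc
from .dbg import reverse_complement

logger = logging.getLogger(__name__)


def branch_score(identity: float, query_cover: float) -> float:
    """Mapping identity times query cover; both must be fractions in [0, 1]."""
    for name, v in (("identity", identity), ("query_cover", query_cover)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return identity * query_cover


@dataclass
class SegmentScoreTable:
    """Map from (segment id, strain id) to (identity, query cover).

    Missing entries mean "no mapping", not a score of zero.
    """

    entries: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def add(self, segment_id: str, strain_id: str, identity: float, query_cover: float):
        branch_score(identity, query_cover)  # validates ranges
        self.entries[(segment_id, strain_id)] = (identity, query_cover)

    def score(self, segment_id: str, strain_id: str) -> Optional[float]:
        entry = self.entries.get((segment_id, strain_id))
        if entry is None:
            return None
        return branch_score(*entry)

    @classmethod
    def from_tsv(cls, path) -> "SegmentScoreTable":
        """Read a 4-column TSV: segment id, strain id, identity, query cover."""
        table = cls()
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                seg, strain, ident, qcov = row[0], row[1], float(row[2]), float(row[3])
                table.add(seg, strain, ident, qcov)
        return table

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            for (seg, strain), (ident, qcov) in sorted(self.entries.items()):
                writer.writerow([seg, strain, f"{ident:.6g}", f"{qcov:.6g}"])


def exact_match_scores(
    doc: SequenceGraphDoc, references: dict[str, str]
) -> SegmentScoreTable:
    """Score table for synthetic fixtures: a segment maps to a strain with
    identity 1 and query cover 1 when it is an exact substring of that
    strain's reference (either strand); otherwise no entry."""
    table = SegmentScoreTable()
    for seg in doc.segments:
        for strain, ref in references.items():
            if seg.sequence in ref or reverse_complement(seg.sequence) in ref:
                table.add(seg.id, strain, 1.0, 1.0)
    return table


@dataclass
class _Junction:
    position: int        # consensus index where the alternative departs
    resume: int          # consensus index where the walk resumes after the alt
    alt_id: str


def _junctions(doc: SequenceGraphDoc, backbone_id: str) -> list[_Junction]:
    """Pair up departure and rejoin edges of every alternative segment."""
    departures: dict[str, int] = {}
    resumes: dict[str, int] = {}
    for edge in doc.edges:
        if edge.sid1 == backbone_id and edge.beg2 == 0:
            departures[edge.sid2] = edge.beg1
        elif edge.sid2 == backbone_id:
            resumes[edge.sid1] = edge.end2
    out = []
    for alt_id, position in departures.items():
        if alt_id not in resumes:
            raise ValueError(
                f"alternative segment {alt_id!r} departs at {position} but never rejoins"
            )
        out.append(_Junction(position=position, resume=resumes[alt_id], alt_id=alt_id))
    out.sort(key=lambda j: (j.position, j.alt_id))
    return out


def walk_strain(
    doc: SequenceGraphDoc,
    scores: SegmentScoreTable,
    strain: str,
    backbone: str = "contig_1_path",
) -> str:
    """Walk the graph choosing, at each junction, the branch scoring highest
    for *strain*; returns the spelled sequence with k-1 overlaps collapsed.

    The backbone path's own branch is kept on ties and when no candidate has
    a score entry.  Junctions overlapped by an already-chosen alternative
    are skipped (greedy resolution in walk order).
    """
    path = next((p for p in doc.paths if p.name == backbone), None)
    if path is None:
        raise ValueError(f"backbone path {backbone!r} not found in document")
    backbone_id = path.segment_ids[0]
    segmap = doc.segment_map()
    consensus = segmap[backbone_id].sequence

    junctions = _junctions(doc, backbone_id)
    parts = []
    cursor = 0
    handled = set()
    for junction in junctions:
        if junction.position < cursor or junction.position in handled:
            continue  # inside a previously chosen alternative / already decided
        handled.add(junction.position)
        group = [j for j in junctions if j.position == junction.position]
        chosen = _choose(scores, strain, backbone_id, [j.alt_id for j in group])
        if chosen is None:
            continue  # keep the backbone branch
        rejoin = next(j for j in group if j.alt_id == chosen)
        parts.append(consensus[cursor : junction.position])
        parts.append(segmap[chosen].sequence)
        cursor = rejoin.resume
    parts.append(consensus[cursor:])
    return "".join(parts)


def _choose(scores, strain, backbone_id, alt_ids) -> Optional[str]:
    """The winning alternative segment id, or None to keep the backbone."""
    candidates = [(backbone_id, scores.score(backbone_id, strain))]
    candidates += [(a, scores.score(a, strain)) for a in alt_ids]
    scored = [(sid, s) for sid, s in candidates if s is not None]
    if not scored:
        return None
    best = max(s for _, s in scored)
    holders = [sid for sid, s in scored if s == best]
    if len(holders) > 1 or holders[0] == backbone_id:
        return None
    return holders[0]


def extract_strain_contigs(
    doc: SequenceGraphDoc,
    scores: SegmentScoreTable,
    strains: list[str],
    backbone: str = "contig_1_path",
) -> dict[str, str]:
    """One strain-specific walk per requested strain, in the given order."""
    return {
        strain: walk_strain(doc, scores, strain, backbone=backbone)
        for strain in strains
    }
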