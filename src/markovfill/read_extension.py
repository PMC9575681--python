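"""Project flank alignments across the gap onto the long read.

A hit anchored on the *right* flank is extended leftwards (the candidate
interval lies before it on the read); a hit on the *left* flank is extended
rightwards. For reverse-orientation hits the read runs antiparallel to the
query, so left/right swap on the read and the correspondence is
qstart<->send, qend<->sstart. Indices that fall off a read end are clamped
to the read boundary and the record is flagged; clamped intervals are
shorter than the gap and are the source of partial fills downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .alignment import AlignmentHit
from .gap_detection import GapRecord
from .sequence_io import BedRecord


class ContractViolation(ValueError):
    """A hit was routed to the wrong extension procedure."""


@dataclass(frozen=True)
class ExtensionRecord:
    """A BED-style candidate interval on a long read."""

    subject_id: str
    start: int
    end: int
    gap_id: str
    strand: str
    clamped: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_bed(self) -> BedRecord:
        return BedRecord(
            subject_id=self.subject_id,
            start=self.start,
            end=self.end,
            name=self.gap_id,
            strand=self.strand,
        )


def _interval_from_start(start: int, gap_length: int, subject_length: int):
    """Clamp the start index first, then take gap_length bases rightwards."""
    clamped = False
    if start < 0:
        start, clamped = 0, True
    end = start + gap_length
    if end > subject_length:
        end, clamped = subject_length, True
    if start >= end:
        return None  # interval entirely off the read
    return start, end, clamped


def _interval_from_end(end: int, gap_length: int, subject_length: int):
    """Clamp the end index first, then take gap_length bases leftwards."""
    clamped = False
    if end > subject_length:
        end, clamped = subject_length, True
    start = end - gap_length
    if start < 0:
        start, clamped = 0, True
    if start >= end:
        return None
    return start, end, clamped


def left_extend(
    hit: AlignmentHit,
    gap_offsets: tuple[int, int],
    gap_length: int,
    subject_length: int,
    gap_id: str = "",
) -> ExtensionRecord | None:
    """Extend a right-flank hit leftwards across the gap.

    Forward: new_start = sstart - (gap_length + (qstart - gap_end)), then
    new_end = new_start + gap_length. Reverse: the gap lies after the hit on
    the read, new_end = send + (gap_length + (qstart - gap_end)) and
    new_start = new_end - gap_length. Out-of-read indices clamp to the read
    boundary with ``clamped=True``; a fully off-read interval yields None.
    """
    if hit.flank_side != "right":
        raise ContractViolation(f"left_extend requires a right-flank hit, got {hit.flank_side!r}")
    gs, ge = gap_offsets
    offset = gap_length + (hit.qstart - ge)
    if hit.orientation == "forward":
        clamped = _interval_from_start(hit.sstart - offset, gap_length, subject_length)
    else:
        clamped = _interval_from_end(hit.send + offset, gap_length, subject_length)
    if clamped is None:
        return None
    start, end, was_clamped = clamped
    return ExtensionRecord(
        subject_id=hit.subject_id,
        start=start,
        end=end,
        gap_id=gap_id or hit.query_id,
        strand="+" if hit.orientation == "forward" else "-",
        clamped=was_clamped,
    )


def right_extend(
    hit: AlignmentHit,
    gap_offsets: tuple[int, int],
    gap_length: int,
    subject_length: int,
    gap_id: str = "",
) -> ExtensionRecord | None:
    """Extend a left-flank hit rightwards across the gap.

    Forward: new_start = send + (gap_start - qend), new_end = new_start +
    gap_length. Reverse: the gap lies before the hit on the read,
    new_end = sstart - (gap_start - qend), new_start = new_end - gap_length.
    """
    if hit.flank_side != "left":
        raise ContractViolation(f"right_extend requires a left-flank hit, got {hit.flank_side!r}")
    gs, ge = gap_offsets
    offset = gs - hit.qend
    if hit.orientation == "forward":
        clamped = _interval_from_start(hit.send + offset, gap_length, subject_length)
    else:
        clamped = _interval_from_end(hit.sstart - offset, gap_length, subject_length)
    if clamped is None:
        return None
    start, end, was_clamped = clamped
    return ExtensionRecord(
        subject_id=hit.subject_id,
        start=start,
        end=end,
        gap_id=gap_id or hit.query_id,
        strand="+" if hit.orientation == "forward" else "-",
        clamped=was_clamped,
    )


def _span_extend(
    hit: AlignmentHit,
    gap_offsets: tuple[int, int],
    gap_length: int,
    subject_length: int,
    gap_id: str,
) -> ExtensionRecord | None:
    """Map the gap interval of a spanning hit directly onto the read."""
    gs, ge = gap_offsets
    if hit.orientation == "forward":
        clamped = _interval_from_start(hit.sstart + (gs - hit.qstart), gap_length, subject_length)
    else:
        clamped = _interval_from_end(hit.send - (gs - hit.qstart), gap_length, subject_length)
    if clamped is None:
        return None
    start, end, was_clamped = clamped
    return ExtensionRecord(
        subject_id=hit.subject_id,
        start=start,
        end=end,
        gap_id=gap_id or hit.query_id,
        strand="+" if hit.orientation == "forward" else "-",
        clamped=was_clamped,
    )


def extend_all(
    hits: Sequence[AlignmentHit],
    gap: GapRecord,
    gap_offsets: tuple[int, int],
    subject_lengths: Mapping[str, int],
) -> list[ExtensionRecord]:
    """Apply the appropriate extension to every filtered hit of one gap.

    Returns records in deterministic order (subject_id, start, strand).
    """
    records: list[ExtensionRecord] = []
    for hit in hits:
        slen = subject_lengths[hit.subject_id]
        if hit.flank_side == "right":
            rec = left_extend(hit, gap_offsets, gap.gap_length, slen, gap.gap_id)
        elif hit.flank_side == "left":
            rec = right_extend(hit, gap_offsets, gap.gap_length, slen, gap.gap_id)
        elif hit.flank_side == "spanning":
            rec = _span_extend(hit, gap_offsets, gap.gap_length, slen, gap.gap_id)
        else:
            continue  # unassigned hits carry no gap-relative anchor
        if rec is not None:
            records.append(rec)
    records.sort(key=lambda r: (r.subject_id, r.start, r.strand))
    return records
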