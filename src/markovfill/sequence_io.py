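"""Sequence and interval I/O plus core nucleotide primitives.

All coordinates inside the package are 0-based, half-open. The one place
1-based inclusive coordinates appear — tabular alignment files in the
12-column BLAST-style layout — converts them at parse time and never again.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA/FASTQ input."""


class TableFormatError(ValueError):
    """Raised for malformed tabular alignment or BED input."""


@dataclass(frozen=True)
class ScaffoldRecord:
    """One named sequence from a draft assembly.

    ``id`` is the first whitespace-delimited token of the header line;
    ``sequence`` keeps the original character case (assemblies often
    soft-mask repeats as lowercase and that information must round-trip).
    """

    id: str
    sequence: str


@dataclass(frozen=True)
class LongRead:
    """A single long read; qualities, if present on input, are discarded."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BedRecord:
    """A BED6 interval on a long read (0-based, half-open)."""

    subject_id: str
    start: int
    end: int
    name: str
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid BED interval [{self.start}, {self.end}) for {self.subject_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANTGCAN")
_VALID_NUC = set("ACGTNacgtn")


def reverse_complement(seq: str) -> str:
    """Reverse-complement ``seq`` (A<->T, C<->G, N->N), returning uppercase.

    Raises ``ValueError`` naming the first character outside {A,C,G,T,N}.
    """
    for ch in seq:
        if ch not in _VALID_NUC:
            raise ValueError(f"invalid nucleotide {ch!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1].upper()


def read_fasta(path: str | os.PathLike) -> list[ScaffoldRecord]:
    """Read a FASTA file into :class:`ScaffoldRecord` objects, case preserved.

    Record ids are the first whitespace-delimited header token and must be
    unique within the file. An empty file is a format error.
    """
    try:
        records = [
            ScaffoldRecord(id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    except ValueError as exc:  # Biopython reports the offending content
        raise FastaFormatError(f"{path}: {exc}") from exc
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found (line 1)")
    seen: set[str] = set()
    for rec in records:
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.sequence) == 0:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
    return records


def read_long_reads(path: str | os.PathLike) -> list[LongRead]:
    """Read long reads from FASTA or FASTQ (auto-detected by first character)."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        fmt = "fastq"
    elif first == ">":
        fmt = "fasta"
    else:
        raise FastaFormatError(f"{path}: not FASTA or FASTQ (line 1)")
    reads = [LongRead(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]
    if not reads:
        raise FastaFormatError(f"{path}: no read records found (line 1)")
    return reads


def write_fasta(
    records: Iterable[ScaffoldRecord], path: str | os.PathLike, line_width: int = 60
) -> None:
    """Write records as FASTA wrapped at ``line_width`` columns (case-exact)."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_bed(records: Sequence[BedRecord], path: str | os.PathLike) -> None:
    """Write BED6 lines (score column fixed to 0)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.subject_id}\t{rec.start}\t{rec.end}\t{rec.name}\t0\t{rec.strand}\n")


def read_bed(path: str | os.PathLike) -> list[BedRecord]:
    out: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise TableFormatError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            out.append(
                BedRecord(
                    subject_id=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    strand=fields[5],
                )
            )
    return out


def parse_alignment_table(path: str | os.PathLike) -> list["AlignmentHit"]:
    """Parse a 12-column tabular alignment file (BLAST outfmt-6 column order).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore, with 1-based inclusive coordinates. Reversed
    coordinate pairs (start > end on either axis) are normalized to the
    internal 0-based half-open convention and flagged as reverse orientation.
    """
    from .alignment import AlignmentHit

    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise TableFormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            qid, sid = fields[0], fields[1]
            pident = float(fields[2])
            aln_length = int(fields[3])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            reverse = qstart > qend or sstart > send
            if qstart > qend:
                qstart, qend = qend, qstart
            if sstart > send:
                sstart, send = send, sstart
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    pident=pident,
                    aln_length=aln_length,
                    qstart=qstart - 1,
                    qend=qend,
                    sstart=sstart - 1,
                    send=send,
                    orientation="reverse" if reverse else "forward",
                )
            )
    return hits
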