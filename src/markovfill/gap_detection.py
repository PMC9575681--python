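"""Gap detection: find N-runs in scaffolds and extract their flanking anchors.

A gap is a maximal run of N (case-insensitive). Each gap gets up to
``flank_len`` bases of clean sequence on either side; flanks stop at the
scaffold boundary, at a neighboring N, or at any IUPAC ambiguity code, so a
flank never spans another gap and is always plain A/C/G/T (mixed case).

Flank scenarios mirror how much anchor sequence is available:

* ``both_full``    — both flanks reach ``flank_len``
* ``left_short`` / ``right_short`` — one side truncated but non-empty
* ``single_left`` / ``single_right`` — only that one flank is non-empty
* ``no_flanks``    — no anchor at all; the gap is unfillable
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable

from .sequence_io import ScaffoldRecord

_GAP_RE = re.compile(r"[Nn]+")
_PLAIN_BASE = set("ACGTacgt")


@dataclass(frozen=True)
class GapRecord:
    gap_id: str
    scaffold_id: str
    gap_start: int
    gap_end: int
    left_flank: str = ""
    right_flank: str = ""
    scenario: str = ""

    @property
    def gap_length(self) -> int:
        return self.gap_end - self.gap_start


def find_gaps(scaffold: ScaffoldRecord, min_gap_len: int = 1) -> list[GapRecord]:
    """Locate maximal N-runs of length >= ``min_gap_len``, left to right.

    Gap ids are ``<scaffold_id>_gap<k>`` with k counting reported gaps from 1.
    """
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    gaps: list[GapRecord] = []
    k = 0
    for m in _GAP_RE.finditer(scaffold.sequence):
        if m.end() - m.start() < min_gap_len:
            continue
        k += 1
        gaps.append(
            GapRecord(
                gap_id=f"{scaffold.id}_gap{k}",
                scaffold_id=scaffold.id,
                gap_start=m.start(),
                gap_end=m.end(),
            )
        )
    return gaps


def _take_flank_left(seq: str, pos: int, flank_len: int) -> str:
    """Up to ``flank_len`` clean bases ending just before ``pos``."""
    lo = pos
    while lo > 0 and pos - lo < flank_len and seq[lo - 1] in _PLAIN_BASE:
        lo -= 1
    return seq[lo:pos]


def _take_flank_right(seq: str, pos: int, flank_len: int) -> str:
    hi = pos
    while hi < len(seq) and hi - pos < flank_len and seq[hi] in _PLAIN_BASE:
        hi += 1
    return seq[pos:hi]


def extract_flanks(scaffold: ScaffoldRecord, gap: GapRecord, flank_len: int = 500) -> GapRecord:
    """Populate ``left_flank``, ``right_flank`` and ``scenario`` for a gap."""
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    seq = scaffold.sequence
    left = _take_flank_left(seq, gap.gap_start, flank_len)
    right = _take_flank_right(seq, gap.gap_end, flank_len)
    if left and right:
        if len(left) == flank_len and len(right) == flank_len:
            scenario = "both_full"
        elif len(left) < flank_len and len(right) == flank_len:
            scenario = "left_short"
        elif len(right) < flank_len and len(left) == flank_len:
            scenario = "right_short"
        else:
            # both truncated: record the more limiting side
            scenario = "left_short" if len(left) <= len(right) else "right_short"
    elif left:
        scenario = "single_left"
    elif right:
        scenario = "single_right"
    else:
        scenario = "no_flanks"
    return replace(gap, left_flank=left, right_flank=right, scenario=scenario)


def build_gap_query(gap: GapRecord) -> tuple[str, tuple[int, int]]:
    """Assemble the alignment query ``left_flank + N*gap_length + right_flank``.

    Returns the query and the query-local coordinates of the N-run; those
    offsets are the "gap start"/"gap end" the extension formulas consume.
    """
    if not gap.left_flank and not gap.right_flank:
        raise ValueError(f"{gap.gap_id}: both flanks empty, no query to build")
    gs = len(gap.left_flank)
    ge = gs + gap.gap_length
    query = gap.left_flank + "N" * gap.gap_length + gap.right_flank
    return query, (gs, ge)


def detect_gaps(
    scaffold: ScaffoldRecord, flank_len: int = 500, min_gap_len: int = 1
) -> list[GapRecord]:
    """find_gaps + extract_flanks in one pass."""
    return [extract_flanks(scaffold, g, flank_len) for g in find_gaps(scaffold, min_gap_len)]


def write_gap_manifest(gaps: Iterable[GapRecord], path) -> None:
    """Tab-separated gap manifest: gap_id, scaffold_id, coords, length, scenario."""
    with open(path, "w") as fh:
        fh.write("gap_id\tscaffold_id\tgap_start\tgap_end\tgap_length\tscenario\n")
        for g in gaps:
            fh.write(
                f"{g.gap_id}\t{g.scaffold_id}\t{g.gap_start}\t{g.gap_end}\t"
                f"{g.gap_length}\t{g.scenario}\n"
            )
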