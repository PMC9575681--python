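"""Local alignment of gap-region queries against long reads, plus hit filtering.

The internal aligner is deliberately simple seed-and-extend: exact k-mer
seeds from the query's non-N positions are looked up in a k-mer index of the
reads, chained by diagonal, and each chain is refined with an edit-distance
infix alignment (edlib) to obtain exact subject coordinates and percent
identity over aligned columns (indel columns included). Both the query and
its reverse complement are seeded, so minus-strand matches are reported with
``orientation == "reverse"`` and subject coordinates on the original read.

Because seeds never contain N, chains stop at the N-run of the query, so the
internal aligner emits per-flank hits; alignments that bridge a gap appear
as one left-flank and one right-flank hit on the same read. Spanning hits
(query interval covering the whole N-run) are still accepted from external
tabular alignment files and classified by :func:`filter_hits`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import edlib

from .sequence_io import LongRead, reverse_complement

#: maximum diagonal drift tolerated inside one seed chain (allows indels)
_DIAG_BAND = 30
#: padding added around a chain's subject extent before refinement
_REFINE_PAD = 24


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a gap query and a long read.

    Coordinates are 0-based half-open on both axes; for reverse-orientation
    hits the subject interval is on the original (plus-strand) read and the
    geometric correspondence is qstart<->send, qend<->sstart.
    """

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    qstart: int
    qend: int
    sstart: int
    send: int
    orientation: str  # "forward" | "reverse"
    flank_side: str = "unassigned"  # "left" | "right" | "spanning" | "unassigned"

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend):
            raise ValueError(f"invalid query interval [{self.qstart}, {self.qend})")
        if not (0 <= self.sstart < self.send):
            raise ValueError(f"invalid subject interval [{self.sstart}, {self.send})")
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident out of range: {self.pident}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for keeping a hit.

    ``min_identity`` (97) is the removal cutoff; ``hq_identity`` (98) marks
    high-quality matches for reporting. ``max_gap_distance`` bounds how far
    a hit's gap-facing end may sit from the N-run: a good match far away on
    a flank says nothing about the missing sequence.
    """

    min_identity: float = 97.0
    hq_identity: float = 98.0
    min_aln_length: int = 40
    max_gap_distance: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= self.hq_identity <= 100):
            raise ValueError("need 0 < min_identity <= hq_identity <= 100")


def is_high_quality(hit: AlignmentHit, params: FilterParams) -> bool:
    return hit.pident >= params.hq_identity


class ReadIndex:
    """Exact k-mer index over a read collection (forward strand only)."""

    def __init__(self, reads: Iterable[LongRead], k: int = 15):
        self.k = k
        self.reads: dict[str, LongRead] = {}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for read in reads:
            if read.id in self.reads:
                raise ValueError(f"duplicate read id {read.id!r}")
            self.reads[read.id] = read
            seq = read.sequence.upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self._index[kmer].append((read.id, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    def lengths(self) -> dict[str, int]:
        return {rid: r.length for rid, r in self.reads.items()}


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matching columns, total aligned columns) from an extended cigar."""
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches, columns


def _chain_seeds(seeds: list[tuple[int, int]]) -> list[tuple[int, int, int, int]]:
    """Group (qpos, spos) seeds into diagonal chains -> (qlo, qhi, slo, shi).

    Seeds are sorted by diagonal and split where the diagonal jumps by more
    than the band; each chain's extent is the min/max of its seeds.
    """
    seeds = sorted(seeds, key=lambda t: (t[1] - t[0], t[0]))
    chains: list[tuple[int, int, int, int]] = []
    cur: list[tuple[int, int]] = []
    prev_diag: int | None = None
    for qpos, spos in seeds:
        diag = spos - qpos
        if prev_diag is not None and abs(diag - prev_diag) > _DIAG_BAND:
            chains.append(_extent(cur))
            cur = []
        cur.append((qpos, spos))
        prev_diag = diag
    if cur:
        chains.append(_extent(cur))
    return chains


def _extent(seeds: list[tuple[int, int]]) -> tuple[int, int, int, int]:
    qs = [q for q, _ in seeds]
    ss = [s for _, s in seeds]
    return min(qs), max(qs), min(ss), max(ss)


def _refine_chain(
    oriented_query: str,
    read_seq: str,
    qlo: int,
    qhi: int,
    slo: int,
    shi: int,
    k: int,
) -> tuple[int, int, int, int, float, int] | None:
    """Align query[qlo:qhi+k] to a padded read window; exact coords + identity.

    A chain may legitimately span the query's N-run (a read that bridges the
    gap: flank seeds on either side share one diagonal). N columns are
    excluded from both matches and aligned columns — an unknown base is
    neither evidence for nor against the read — so identity reflects only
    the flank sequence. aln_length is likewise the non-N column count.
    """
    qseg = oriented_query[qlo : qhi + k].upper()
    wlo = max(0, slo - _REFINE_PAD)
    whi = min(len(read_seq), shi + k + _REFINE_PAD)
    window = read_seq[wlo:whi].upper()
    n_count = qseg.count("N")
    extra = [("N", b) for b in "ACGT"] if n_count else []
    res = edlib.align(qseg, window, mode="HW", task="path", additionalEqualities=extra)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc_start, loc_end = res["locations"][0]
    matches, columns = _cigar_stats(res["cigar"])
    matches = max(0, matches - n_count)
    columns -= n_count
    if columns <= 0:
        return None
    pident = matches / columns * 100.0
    return qlo, qhi + k, wlo + loc_start, wlo + loc_end + 1, pident, columns


def align_gap_region(
    query: str,
    reads: Sequence[LongRead] | ReadIndex,
    params: FilterParams | None = None,
    query_id: str = "query",
    k: int = 15,
) -> list[AlignmentHit]:
    """Locally align a gap query against every read and its reverse complement.

    Returns hits in deterministic order (subject_id, sstart, qstart,
    orientation). N positions in the query never seed or count as matches;
    a query of all N yields no hits.
    """
    index = reads if isinstance(reads, ReadIndex) else ReadIndex(reads, k=k)
    k = index.k
    hits: list[AlignmentHit] = []
    qlen = len(query)
    for orientation in ("forward", "reverse"):
        oq = query if orientation == "forward" else reverse_complement(query)
        oq_upper = oq.upper()
        per_read: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for i in range(qlen - k + 1):
            kmer = oq_upper[i : i + k]
            if "N" in kmer:
                continue
            for rid, spos in index.lookup(kmer):
                per_read[rid].append((i, spos))
        for rid, seeds in per_read.items():
            read = index.reads[rid]
            for qlo, qhi, slo, shi in _chain_seeds(seeds):
                refined = _refine_chain(oq, read.sequence, qlo, qhi, slo, shi, k)
                if refined is None:
                    continue
                oq_start, oq_end, sstart, send, pident, columns = refined
                if orientation == "forward":
                    qstart, qend = oq_start, oq_end
                else:
                    qstart, qend = qlen - oq_end, qlen - oq_start
                hits.append(
                    AlignmentHit(
                        query_id=query_id,
                        subject_id=rid,
                        pident=pident,
                        aln_length=columns,
                        qstart=qstart,
                        qend=qend,
                        sstart=sstart,
                        send=send,
                        orientation=orientation,
                    )
                )
    hits.sort(key=lambda h: (h.subject_id, h.sstart, h.qstart, h.orientation))
    return hits


def filter_hits(
    hits: Iterable[AlignmentHit],
    gap_offsets: tuple[int, int],
    params: FilterParams | None = None,
) -> list[AlignmentHit]:
    """Keep hits by identity, length and proximity to the gap; assign sides.

    A surviving hit is ``spanning`` when its query interval covers the whole
    N-run, ``left`` when it ends within ``max_gap_distance`` of the gap
    start, ``right`` when it begins within ``max_gap_distance`` of the gap
    end. Anything that fails identity, length or location is removed.
    """
    params = params or FilterParams()
    gs, ge = gap_offsets
    d = params.max_gap_distance
    kept: list[AlignmentHit] = []
    for h in hits:
        if h.pident < params.min_identity or h.aln_length < params.min_aln_length:
            continue
        if h.qstart <= gs and h.qend >= ge:
            kept.append(replace(h, flank_side="spanning"))
        elif h.qstart < gs and abs(gs - h.qend) <= d:
            kept.append(replace(h, flank_side="left"))
        elif h.qend > ge and abs(h.qstart - ge) <= d:
            kept.append(replace(h, flank_side="right"))
        # otherwise: located too far from the gap to inform the fill
    return kept
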