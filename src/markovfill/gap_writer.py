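"""Splice selected fills back into the scaffolds and report what happened.

Only N characters are ever replaced: a filled gap's N-run is substituted by
an equal-length generated sequence, a partial fill replaces the leading
portion and leaves the remaining Ns untouched, and everything outside the
reported gap intervals is copied byte-for-byte, case included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .gap_detection import GapRecord
from .markov_fill import FillResult
from .sequence_io import ScaffoldRecord


class FillContractError(ValueError):
    """A fill is longer than the gap it targets; never truncated silently."""


@dataclass(frozen=True)
class FillReportRow:
    gap_id: str
    scaffold_id: str
    gap_start: int
    gap_end: int
    gap_length: int
    status: str
    reason: str
    filled_length: int
    avg_cost: float
    n_candidates: int


@dataclass
class FillReport:
    rows: list[FillReportRow] = field(default_factory=list)

    def summary(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for row in self.rows:
            key = row.status if not row.reason else f"{row.status}:{row.reason}"
            totals[key] = totals.get(key, 0) + 1
        totals["total"] = len(self.rows)
        return totals

    def write_tsv(self, path) -> None:
        cols = (
            "gap_id scaffold_id gap_start gap_end gap_length status reason "
            "filled_length avg_cost n_candidates"
        ).split()
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.rows:
                fh.write(
                    f"{r.gap_id}\t{r.scaffold_id}\t{r.gap_start}\t{r.gap_end}\t"
                    f"{r.gap_length}\t{r.status}\t{r.reason}\t{r.filled_length}\t"
                    f"{r.avg_cost:.6f}\t{r.n_candidates}\n"
                )

    def write_summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def apply_fills(
    scaffolds: Sequence[ScaffoldRecord],
    gaps: Sequence[GapRecord],
    results: Mapping[str, FillResult],
    lowercase_fills: bool = False,
) -> tuple[list[ScaffoldRecord], FillReport]:
    """Substitute fills for N-runs; everything else is untouched.

    ``results`` maps gap_id to the fill outcome; gaps without a result are
    reported unfillable (not attempted). A fill longer than its gap raises
    :class:`FillContractError`.
    """
    by_scaffold: dict[str, list[GapRecord]] = {}
    for gap in gaps:
        by_scaffold.setdefault(gap.scaffold_id, []).append(gap)
    report = FillReport()
    out: list[ScaffoldRecord] = []
    for scaf in scaffolds:
        seq = scaf.sequence
        for gap in sorted(by_scaffold.get(scaf.id, []), key=lambda g: g.gap_start):
            res = results.get(gap.gap_id)
            if res is None:
                report.rows.append(
                    FillReportRow(
                        gap.gap_id, gap.scaffold_id, gap.gap_start, gap.gap_end,
                        gap.gap_length, "unfillable", "not_attempted", 0, 0.0, 0,
                    )
                )
                continue
            fill_seq = res.fill.sequence if res.fill else ""
            if len(fill_seq) > gap.gap_length:
                raise FillContractError(
                    f"{gap.gap_id}: fill length {len(fill_seq)} exceeds gap length "
                    f"{gap.gap_length}"
                )
            if fill_seq:
                if lowercase_fills:
                    fill_seq = fill_seq.lower()
                seq = (
                    seq[: gap.gap_start]
                    + fill_seq
                    + seq[gap.gap_start + len(fill_seq) : ]
                )
            report.rows.append(
                FillReportRow(
                    gap.gap_id, gap.scaffold_id, gap.gap_start, gap.gap_end,
                    gap.gap_length, res.status, res.reason, len(fill_seq),
                    res.fill.avg_cost if res.fill else 0.0, res.n_candidates,
                )
            )
        out.append(ScaffoldRecord(id=scaf.id, sequence=seq))
    return out, report
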