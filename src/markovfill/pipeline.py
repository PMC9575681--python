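"""End-to-end orchestration: detect -> align -> filter -> extend -> fill -> write.

The pipeline is deterministic for a fixed configuration: each gap draws its
randomness from a stream derived from the master seed and a stable hash of
the gap id, so results do not depend on processing order. A failing gap is
recorded as unfillable with a reason and never aborts the run.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import gap_detection, gap_writer, markov_fill, read_extension
from .alignment import AlignmentHit, FilterParams, ReadIndex, align_gap_region, filter_hits, is_high_quality
from .sequence_io import (
    ScaffoldRecord,
    parse_alignment_table,
    read_fasta,
    read_long_reads,
    write_bed,
    write_fasta,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    scaffolds: str
    reads: str
    out_dir: str
    flank_len: int = 500
    min_gap_len: int = 1
    min_identity: float = 97.0
    hq_identity: float = 98.0
    min_aln_length: int = 40
    max_gap_distance: int = 10
    n_samples: int = 8
    seed: int = 42
    aligner: str = "internal"  # "internal" | "external-tabular"
    alignment_table: str | None = None
    keep_intermediates: bool = False
    lowercase_fills: bool = False

    def __post_init__(self) -> None:
        for name in ("flank_len", "min_gap_len", "min_aln_length", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.min_identity > self.hq_identity:
            raise ValueError("min_identity must be <= hq_identity")
        if self.aligner not in ("internal", "external-tabular"):
            raise ValueError(f"unknown aligner {self.aligner!r}")
        if self.aligner == "external-tabular" and not self.alignment_table:
            raise ValueError("external-tabular aligner needs alignment_table")

    def filter_params(self) -> FilterParams:
        return FilterParams(
            min_identity=self.min_identity,
            hq_identity=self.hq_identity,
            min_aln_length=self.min_aln_length,
            max_gap_distance=self.max_gap_distance,
        )


def gap_rng(master_seed: int, gap_id: str) -> np.random.Generator:
    """Per-gap random stream, independent of gap processing order."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(gap_id.encode())])
    )


def anchor_base(scaffold: ScaffoldRecord, gap: gap_detection.GapRecord) -> str | None:
    """Last scaffold base before the gap, or None when absent/ambiguous."""
    if gap.gap_start == 0:
        return None
    ch = scaffold.sequence[gap.gap_start - 1].upper()
    return ch if ch in "ACGT" else None


def run_pipeline(config: RunConfig) -> gap_writer.FillReport:
    """Run all stages and write the filled FASTA, reports and per-gap logs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scaffolds = read_fasta(config.scaffolds)
    reads = read_long_reads(config.reads)
    read_map = {r.id: r for r in reads}
    read_lengths = {r.id: r.length for r in reads}
    params = config.filter_params()

    index: ReadIndex | None = None
    external_hits: dict[str, list[AlignmentHit]] = {}
    if config.aligner == "internal":
        index = ReadIndex(reads)
    else:
        for hit in parse_alignment_table(config.alignment_table):
            external_hits.setdefault(hit.query_id, []).append(hit)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    ext_dir = out / "extensions"
    if config.keep_intermediates:
        ext_dir.mkdir(exist_ok=True)

    all_gaps: list[gap_detection.GapRecord] = []
    results: dict[str, markov_fill.FillResult] = {}
    log_rows: list[dict] = []
    for scaffold in scaffolds:
        gaps = gap_detection.detect_gaps(scaffold, config.flank_len, config.min_gap_len)
        all_gaps.extend(gaps)
        if config.keep_intermediates and gaps:
            queries = [
                ScaffoldRecord(id=g.gap_id, sequence=gap_detection.build_gap_query(g)[0])
                for g in gaps
                if g.scenario != "no_flanks"
            ]
            if queries:
                write_fasta(queries, out / f"{scaffold.id}.gaps.fasta")
        for gap in gaps:
            results[gap.gap_id], row = _process_gap(
                scaffold, gap, config, params, index, external_hits,
                read_map, read_lengths, ext_dir if config.keep_intermediates else None,
            )
            log_rows.append(row)

    filled, report = gap_writer.apply_fills(
        scaffolds, all_gaps, results, lowercase_fills=config.lowercase_fills
    )
    write_fasta(filled, out / "filled.fasta")
    gap_detection.write_gap_manifest(all_gaps, out / "gaps.tsv")
    report.write_tsv(out / "report.tsv")
    report.write_summary_json(out / "summary.json")
    with open(out / "gaps.jsonl", "w") as fh:
        for row in log_rows:
            fh.write(json.dumps(row, sort_keys=True) + "\n")
    return report


def _process_gap(
    scaffold, gap, config, params, index, external_hits, read_map, read_lengths, ext_dir
) -> tuple[markov_fill.FillResult, dict]:
    """Run one gap through alignment, extension and Markov filling."""
    row = {
        "gap_id": gap.gap_id,
        "scenario": gap.scenario,
        "gap_length": gap.gap_length,
        "n_hits": 0,
        "n_hq_hits": 0,
        "n_candidates": 0,
        "best_avg_cost": None,
    }
    try:
        if gap.scenario == "no_flanks":
            res = markov_fill.FillResult(gap.gap_id, "unfillable", "no_flanks", None, 0)
            row["status"] = "unfillable:no_flanks"
            return res, row
        query, offsets = gap_detection.build_gap_query(gap)
        if config.aligner == "internal":
            hits = align_gap_region(query, index, params, query_id=gap.gap_id)
        else:
            hits = external_hits.get(gap.gap_id, [])
        kept = filter_hits(hits, offsets, params)
        if ext_dir is not None and kept:
            with open(ext_dir / f"{gap.gap_id}.hits.tsv", "w") as fh:
                fh.write(
                    "query_id\tsubject_id\tpident\taln_length\tqstart\tqend\t"
                    "sstart\tsend\torientation\tflank_side\n"
                )
                for h in kept:
                    fh.write(
                        f"{h.query_id}\t{h.subject_id}\t{h.pident:.2f}\t{h.aln_length}\t"
                        f"{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}\t{h.orientation}\t"
                        f"{h.flank_side}\n"
                    )
        row["n_hits"] = len(kept)
        row["n_hq_hits"] = sum(1 for h in kept if is_high_quality(h, params))
        records = read_extension.extend_all(kept, gap, offsets, read_lengths)
        if ext_dir is not None and records:
            write_bed([r.to_bed() for r in records], ext_dir / f"{gap.gap_id}.bed")
        candidates = markov_fill.extract_candidates(records, read_map, gap.gap_length)
        row["n_candidates"] = len(candidates)
        res = markov_fill.fill_gap(
            candidates,
            gap.gap_id,
            gap.gap_length,
            anchor_base(scaffold, gap),
            gap_rng(config.seed, gap.gap_id),
            n_samples=config.n_samples,
        )
    except Exception as exc:  # a failing gap never aborts the run
        logger.warning("gap %s failed: %s", gap.gap_id, exc)
        res = markov_fill.FillResult(gap.gap_id, "unfillable", "error", None, 0)
    if res.fill is not None:
        row["best_avg_cost"] = res.fill.avg_cost
    row["status"] = res.status if not res.reason else f"{res.status}:{res.reason}"
    return res, row
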