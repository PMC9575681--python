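"""Synthetic fixtures with known ground truth, and evaluation against it.

The generator emulates the situation the pipeline is built for: a reference
genome (optionally carrying diverged repeat copies, the classic cause of
assembly gaps), a scaffold derived from it by replacing chosen intervals
with N, and error-containing long reads sampled from the reference. The
entire chain is a pure function of :class:`SimulationConfig`, seed included.

Defaults describe the reference study conditions used throughout the test
suite: a 50 kb genome at 50% GC with one 100-base repeat planted five times
at 2% divergence, twenty gaps of 50-300 bases, and 2 kb reads at 15-fold
coverage with no sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .gap_writer import FillReport
from .sequence_io import LongRead, ScaffoldRecord

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """The simulation request cannot be satisfied (e.g. repeats do not fit)."""


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 50_000
    gc_content: float = 0.5
    #: list of (unit_length, copy_number, divergence_fraction)
    repeat_spec: Sequence[tuple[int, int, float]] = ((100, 5, 0.02),)
    #: list of (count, min_length, max_length)
    gap_spec: Sequence[tuple[int, int, int]] = ((20, 50, 300),)
    read_length_mean: int = 2_000
    coverage: float = 15.0
    error_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ConfigError("coverage must be > 0")
        if not (0 <= self.error_rate < 0.5):
            raise ConfigError("error_rate must be in [0, 0.5)")
        if not (0 < self.gc_content < 1):
            raise ConfigError("gc_content must be in (0, 1)")
        for count, lo, hi in self.gap_spec:
            if lo < 1 or hi < lo or hi >= self.genome_length:
                raise ConfigError(f"bad gap spec ({count}, {lo}, {hi})")


@dataclass(frozen=True)
class Genome:
    """A simulated reference plus the intervals where repeats were planted."""

    sequence: str
    repeat_intervals: tuple[tuple[int, int], ...] = ()

    def __len__(self) -> int:
        return len(self.sequence)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i, ch in enumerate(chars):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != ch]
            chars[i] = choices[int(rng.integers(3))]
    return "".join(chars)


def _place_disjoint(
    rng: np.random.Generator,
    lengths: Sequence[int],
    genome_length: int,
    margin: int = 1,
    max_tries: int = 10_000,
) -> list[int]:
    """Random non-overlapping, non-touching start positions for the lengths."""
    taken: list[tuple[int, int]] = []
    starts: list[int] = []
    for ln in lengths:
        if ln + 2 * margin > genome_length:
            raise ConfigError(f"interval of length {ln} does not fit in {genome_length}")
        for _ in range(max_tries):
            s = int(rng.integers(margin, genome_length - ln - margin + 1))
            if all(s + ln + margin <= a or b + margin <= s for a, b in taken):
                taken.append((s, s + ln))
                starts.append(s)
                break
        else:
            raise ConfigError("could not place requested intervals disjointly")
    return starts


def simulate_genome(config: SimulationConfig) -> Genome:
    """Random reference at the requested GC with planted diverged repeats."""
    rng = np.random.default_rng(config.seed)
    seq = list(_random_seq(rng, config.genome_length, config.gc_content))
    intervals: list[tuple[int, int]] = []
    for unit_len, copies, divergence in config.repeat_spec:
        if unit_len * copies > config.genome_length:
            raise ConfigError("repeat_spec exceeds genome length")
        unit = _random_seq(rng, unit_len, config.gc_content)
        starts = _place_disjoint(rng, [unit_len] * copies, config.genome_length)
        for s in starts:
            copy = _mutate(rng, unit, divergence)
            seq[s : s + unit_len] = list(copy)
            intervals.append((s, s + unit_len))
    return Genome(sequence="".join(seq), repeat_intervals=tuple(sorted(intervals)))


def make_gapped_scaffold(
    reference: Genome | str,
    gap_spec: Sequence[tuple[int, int, int]],
    seed: int,
    scaffold_id: str = "scaffold_1",
) -> tuple[ScaffoldRecord, dict[str, str]]:
    """Replace disjoint intervals of the reference with N and record the truth.

    When the reference carries repeat annotations, roughly half the gaps are
    centered inside repeat copies (repeats are where real gaps arise). The
    truth table maps each gap id — matching the ids gap detection will
    assign — to the replaced substring.
    """
    ref_seq = reference.sequence if isinstance(reference, Genome) else reference
    repeats = reference.repeat_intervals if isinstance(reference, Genome) else ()
    rng = np.random.default_rng(seed)
    lengths: list[int] = []
    for count, lo, hi in gap_spec:
        lengths.extend(int(rng.integers(lo, hi + 1)) for _ in range(count))
    taken: list[tuple[int, int]] = []
    intervals: list[tuple[int, int]] = []
    for ln in lengths:
        placed = False
        for _ in range(10_000):
            if repeats and rng.random() < 0.5:
                a, b = repeats[int(rng.integers(len(repeats)))]
                center = (a + b) // 2
                s = max(1, center - ln // 2)
            else:
                s = int(rng.integers(1, len(ref_seq) - ln))
            if s + ln + 1 > len(ref_seq):
                continue
            if all(s + ln + 1 <= a or b + 1 <= s for a, b in taken):
                taken.append((s, s + ln))
                intervals.append((s, s + ln))
                placed = True
                break
        if not placed:
            raise ConfigError("could not place requested gaps disjointly")
    intervals.sort()
    seq = list(ref_seq)
    truth: dict[str, str] = {}
    for k, (a, b) in enumerate(intervals, start=1):
        truth[f"{scaffold_id}_gap{k}"] = ref_seq[a:b]
        seq[a:b] = ["N"] * (b - a)
    return ScaffoldRecord(id=scaffold_id, sequence="".join(seq)), truth


def simulate_long_reads(
    reference: Genome | str, config: SimulationConfig
) -> list[LongRead]:
    """Sample error-containing long reads uniformly over position and strand.

    Lengths are normal around the mean (sd = mean/4, floored at 200 bases);
    errors mix substitutions, insertions and deletions 60:20:20.
    """
    ref_seq = reference.sequence if isinstance(reference, Genome) else reference
    L = len(ref_seq)
    if config.read_length_mean >= L:
        raise ConfigError("read_length_mean must be smaller than the genome")
    rng = np.random.default_rng(config.seed + 1)
    target = config.coverage * L
    reads: list[LongRead] = []
    total = 0
    i = 0
    comp = str.maketrans("ACGT", "TGCA")
    while total < target:
        i += 1
        ln = int(rng.normal(config.read_length_mean, config.read_length_mean / 4))
        ln = max(200, min(ln, L))
        start = int(rng.integers(0, L - ln + 1))
        seq = ref_seq[start : start + ln]
        if rng.random() < 0.5:
            seq = seq.translate(comp)[::-1]
        seq = _inject_errors(rng, seq, config.error_rate)
        reads.append(LongRead(id=f"read_{i:06d}", sequence=seq))
        total += len(seq)
    return reads


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out: list[str] = []
    for ch in seq:
        if rng.random() >= rate:
            out.append(ch)
            continue
        kind = rng.random()
        if kind < 0.6:  # substitution
            out.append([b for b in "ACGT" if b != ch][int(rng.integers(3))])
        elif kind < 0.8:  # insertion before the base
            out.append("ACGT"[int(rng.integers(4))])
            out.append(ch)
        # else deletion: emit nothing
    return "".join(out)


@dataclass(frozen=True)
class GapEvaluation:
    gap_id: str
    status: str
    identity: float
    length_match: bool


@dataclass(frozen=True)
class EvaluationSummary:
    per_gap: tuple[GapEvaluation, ...]
    fraction_filled: float
    fraction_perfect: float
    mean_identity: float


def evaluate_fills(
    filled: Sequence[ScaffoldRecord],
    truth: dict[str, str],
    report: FillReport,
) -> EvaluationSummary:
    """Score each filled region against the truth by edit-distance identity.

    identity = 1 - edit_distance(fill, truth) / max(len(fill), len(truth));
    unfilled gaps (all-N regions) score 0. Trailing Ns of partial fills are
    stripped before comparison so a partial fill is scored on what it wrote.
    """
    by_id = {s.id: s.sequence for s in filled}
    per_gap: list[GapEvaluation] = []
    for row in report.rows:
        if row.gap_id not in truth:
            raise ValueError(f"report row {row.gap_id!r} not present in truth table")
        true_seq = truth[row.gap_id]
        scaf = by_id.get(row.scaffold_id)
        if scaf is None or row.gap_end > len(scaf):
            raise ValueError(f"report coordinates for {row.gap_id!r} exceed scaffold")
        region = scaf[row.gap_start : row.gap_end].upper().rstrip("N")
        if not region:
            per_gap.append(GapEvaluation(row.gap_id, "unfilled", 0.0, False))
            continue
        dist = edlib.align(region, true_seq.upper(), mode="NW", task="distance")["editDistance"]
        identity = 1.0 - dist / max(len(region), len(true_seq))
        per_gap.append(
            GapEvaluation(row.gap_id, row.status, identity, len(region) == len(true_seq))
        )
    n = len(per_gap)
    filled_n = sum(1 for g in per_gap if g.status == "filled")
    perfect = sum(1 for g in per_gap if g.identity == 1.0)
    mean_id = float(np.mean([g.identity for g in per_gap])) if n else 0.0
    return EvaluationSummary(
        per_gap=tuple(per_gap),
        fraction_filled=filled_n / n if n else 0.0,
        fraction_perfect=perfect / n if n else 0.0,
        mean_identity=mean_id,
    )
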