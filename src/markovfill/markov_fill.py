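"""First-order Markov gap filling.

Candidate intervals from read extension become uppercase A/C/G/T sequences
(minus-strand intervals are reverse-complemented at extraction). Adjacent
nucleotide pairs of every candidate are counted into one aggregated 4x4
frequency table — raw counts are summed across candidates before a single
row normalization, so a 500-pair candidate outweighs a 1-pair one, matching
the frequency interpretation. Each row of the resulting transition matrix
is either a probability distribution over the next nucleotide or all zero
(a state never observed as a predecessor).

Generation anchors on the last scaffold base before the gap (uppercased) so
the chain continues the local pattern rather than starting cold, draws one
state per missing base, and stops early if it walks into a zero row (a
partial fill). Because sampling is stochastic, generation is repeated a few
times (5-10, default 8) and the sample with the highest average transition
cost — the mean of the n-1 step probabilities of an n-base fill — wins.
Ties break to the lexicographically smallest sequence, then the earliest
sample, so output is reproducible for a fixed seed.

Gaps of a single base are unfillable by construction: a 1-base candidate
contains no nucleotide pair, so no pattern exists to learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .read_extension import ExtensionRecord
from .sequence_io import LongRead, reverse_complement

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_ENCODE = {c: i for i, c in enumerate(ALPHABET)}


class NoCandidatesError(ValueError):
    """No candidate sequences survived extraction for this gap."""


class AnchorMissingError(ValueError):
    """The base immediately before the gap is absent or not A/C/G/T."""


class UnfillableError(ValueError):
    """The transition table admits no generation from the anchor."""


def encode_nucleotide(ch: str) -> int:
    """Map A->0, C->1, G->2, T->3 (case-insensitive)."""
    idx = _ENCODE.get(ch.upper())
    if idx is None:
        raise ValueError(f"cannot encode nucleotide {ch!r}: not one of A/C/G/T")
    return idx


@dataclass(frozen=True)
class CandidateSequence:
    gap_id: str
    sequence: str  # uppercase, A/C/G/T only
    source: str  # "<subject_id>:<start>-<end>(<strand>)"
    full_length: bool


@dataclass(frozen=True)
class TransitionTable:
    counts: np.ndarray  # (4, 4) nonnegative ints
    probs: np.ndarray  # (4, 4) row-stochastic or all-zero rows

    def is_all_zero(self) -> bool:
        return not self.counts.any()


@dataclass(frozen=True)
class GeneratedFill:
    gap_id: str
    sequence: str
    avg_cost: float
    sample_index: int
    partial: bool = False


@dataclass(frozen=True)
class FillResult:
    """Outcome of attempting to fill one gap."""

    gap_id: str
    status: str  # "filled" | "partial" | "unfillable"
    reason: str  # empty when filled/partial, else the unfillable cause
    fill: GeneratedFill | None
    n_candidates: int

    @property
    def filled_length(self) -> int:
        return len(self.fill.sequence) if self.fill else 0


def extract_candidates(
    bed: Sequence[ExtensionRecord],
    reads: Mapping[str, LongRead],
    gap_length: int,
) -> list[CandidateSequence]:
    """Turn extension intervals into candidate sequences.

    Minus-strand intervals are reverse-complemented so every candidate reads
    in the scaffold's orientation. Candidates containing N are dropped (the
    read itself is uncertain there) with a logged count.
    """
    out: list[CandidateSequence] = []
    dropped = 0
    for rec in bed:
        read = reads.get(rec.subject_id)
        if read is None:
            raise KeyError(f"extension record refers to unknown read {rec.subject_id!r}")
        if rec.end > read.length:
            raise ValueError(
                f"interval [{rec.start}, {rec.end}) exceeds read {rec.subject_id!r} "
                f"length {read.length}"
            )
        seq = read.sequence[rec.start : rec.end]
        seq = reverse_complement(seq) if rec.strand == "-" else seq.upper()
        if "N" in seq:
            dropped += 1
            continue
        out.append(
            CandidateSequence(
                gap_id=rec.gap_id,
                sequence=seq,
                source=f"{rec.subject_id}:{rec.start}-{rec.end}({rec.strand})",
                full_length=len(seq) == gap_length,
            )
        )
    if dropped:
        logger.info("dropped %d candidate(s) containing N", dropped)
    return out


def count_transitions(seq: str) -> np.ndarray:
    """4x4 counts of adjacent nucleotide pairs; a 1-base sequence counts nothing."""
    counts = np.zeros((4, 4), dtype=np.int64)
    if len(seq) >= 2:
        codes = np.fromiter((encode_nucleotide(c) for c in seq), dtype=np.int64, count=len(seq))
        np.add.at(counts, (codes[:-1], codes[1:]), 1)
    return counts


def build_transition_table(candidates: Sequence[CandidateSequence]) -> TransitionTable:
    """Aggregate pair counts over all candidates, then row-normalize once."""
    if not candidates:
        raise NoCandidatesError("cannot build a transition table from zero candidates")
    counts = np.zeros((4, 4), dtype=np.int64)
    for cand in candidates:
        counts += count_transitions(cand.sequence)
    rowsums = counts.sum(axis=1, keepdims=True)
    probs = np.divide(
        counts, rowsums, out=np.zeros((4, 4), dtype=float), where=rowsums > 0
    )
    return TransitionTable(counts=counts, probs=probs)


def generate_fill(
    table: TransitionTable,
    gap_length: int,
    last_char: str,
    rng: np.random.Generator,
    gap_id: str = "",
    sample_index: int = 0,
) -> GeneratedFill:
    """Sample one fill of up to ``gap_length`` bases anchored on ``last_char``.

    The chain starts in the state of the (uppercased) anchor base and emits
    one sampled state per missing base. Hitting an all-zero row before the
    gap is complete ends generation early and flags the fill as partial.
    """
    if gap_length < 1:
        raise ValueError("gap_length must be >= 1")
    try:
        state = encode_nucleotide(last_char)
    except ValueError as exc:
        raise AnchorMissingError(str(exc)) from exc
    if table.is_all_zero():
        raise UnfillableError("transition table is all zero; no pattern to extend")
    chars: list[str] = []
    for _ in range(gap_length):
        row = table.probs[state]
        if not row.any():
            break
        state = int(rng.choice(4, p=row))
        chars.append(ALPHABET[state])
    seq = "".join(chars)
    return GeneratedFill(
        gap_id=gap_id,
        sequence=seq,
        avg_cost=score_fill(seq, table),
        sample_index=sample_index,
        partial=len(seq) < gap_length,
    )


def score_fill(sequence: str, table: TransitionTable) -> float:
    """Mean transition probability over the n-1 internal steps of the fill.

    Sequences shorter than two bases have no transitions and score 0 by
    convention. The anchor step is deliberately excluded: an n-base
    sequence has exactly n-1 transition costs.
    """
    if len(sequence) < 2:
        return 0.0
    codes = [encode_nucleotide(c) for c in sequence]
    steps = [table.probs[a, b] for a, b in zip(codes[:-1], codes[1:])]
    return float(np.mean(steps))


def fill_gap(
    candidates: Sequence[CandidateSequence],
    gap_id: str,
    gap_length: int,
    last_char: str | None,
    rng: np.random.Generator,
    n_samples: int = 8,
    enforce_sample_range: bool = True,
) -> FillResult:
    """Generate repeated Markov samples for one gap and keep the best.

    Full-length fills always beat partial ones; among fills of equal
    completeness the highest average transition cost wins, ties broken by
    lexicographically smallest sequence then lowest sample index. 1-base
    gaps are unfillable: no pattern can be detected in 1-base candidates.
    """
    if enforce_sample_range and not (5 <= n_samples <= 10):
        raise ValueError("n_samples must be between 5 and 10")
    if gap_length == 1:
        return FillResult(gap_id, "unfillable", "gap_too_short", None, len(candidates))
    if last_char is None:
        return FillResult(gap_id, "unfillable", "anchor_missing", None, len(candidates))
    try:
        table = build_transition_table(candidates)
        samples = [
            generate_fill(table, gap_length, last_char, rng, gap_id, i)
            for i in range(n_samples)
        ]
    except NoCandidatesError:
        return FillResult(gap_id, "unfillable", "no_candidates", None, 0)
    except AnchorMissingError:
        return FillResult(gap_id, "unfillable", "anchor_missing", None, len(candidates))
    except UnfillableError:
        return FillResult(gap_id, "unfillable", "all_zero_table", None, len(candidates))
    full = [s for s in samples if not s.partial]
    pool = full or [s for s in samples if s.sequence]
    if not pool:
        return FillResult(gap_id, "unfillable", "dead_anchor_state", None, len(candidates))
    best = min(pool, key=lambda s: (-s.avg_cost, s.sequence, s.sample_index))
    status = "filled" if not best.partial else "partial"
    return FillResult(gap_id, status, "", best, len(candidates))
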