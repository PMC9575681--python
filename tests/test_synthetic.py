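import numpy as np
import pytest

from markovfill.gap_detection import GapRecord
from markovfill.gap_writer import FillReport, FillReportRow
from markovfill.sequence_io import ScaffoldRecord, reverse_complement
from markovfill.synthetic import (
    ConfigError,
    SimulationConfig,
    evaluate_fills,
    make_gapped_scaffold,
    simulate_genome,
    simulate_long_reads,
)

BASE = SimulationConfig(
    genome_length=10_000, repeat_spec=(), gap_spec=((4, 30, 80),),
    read_length_mean=600, coverage=8.0, error_rate=0.0, seed=3,
)


class TestSimulateGenome:
    def test_deterministic_for_fixed_seed(self):
        assert simulate_genome(BASE).sequence == simulate_genome(BASE).sequence

    def test_gc_content_within_binomial_bounds(self):
        seq = simulate_genome(BASE).sequence
        gc = sum(c in "GC" for c in seq) / len(seq)
        assert abs(gc - 0.5) < 0.02  # ~4 sigma for n=10000

    def test_repeats_planted_with_zero_divergence(self):
        config = SimulationConfig(
            genome_length=5_000, repeat_spec=((100, 3, 0.0),), gap_spec=(),
            read_length_mean=600, coverage=1.0, error_rate=0.0, seed=5,
        )
        genome = simulate_genome(config)
        assert len(genome.repeat_intervals) == 3
        a, b = genome.repeat_intervals[0]
        unit = genome.sequence[a:b]
        assert sum(genome.sequence[s:e] == unit for s, e in genome.repeat_intervals) == 3

    def test_infeasible_repeats_rejected(self):
        config = SimulationConfig(
            genome_length=500, repeat_spec=((300, 5, 0.0),), gap_spec=(),
            read_length_mean=200, coverage=1.0, seed=1,
        )
        with pytest.raises(ConfigError):
            simulate_genome(config)


class TestMakeGappedScaffold:
    def test_n_count_matches_requested_gaps(self):
        genome = simulate_genome(BASE)
        scaffold, truth = make_gapped_scaffold(genome, BASE.gap_spec, seed=9)
        assert scaffold.sequence.count("N") == sum(len(s) for s in truth.values())
        assert len(truth) == 4

    def test_truth_splices_back_to_reference(self):
        genome = simulate_genome(BASE)
        scaffold, truth = make_gapped_scaffold(genome, BASE.gap_spec, seed=9)
        seq = scaffold.sequence
        # recover intervals by scanning for N-runs in order of position
        import re
        runs = [(m.start(), m.end()) for m in re.finditer("N+", seq)]
        assert len(runs) == len(truth)
        rebuilt = list(seq)
        for k, (a, b) in enumerate(runs, start=1):
            rebuilt[a:b] = truth[f"{scaffold.id}_gap{k}"]
        assert "".join(rebuilt) == genome.sequence

    def test_zero_gaps_identity(self):
        genome = simulate_genome(BASE)
        scaffold, truth = make_gapped_scaffold(genome, (), seed=9)
        assert scaffold.sequence == genome.sequence and truth == {}


class TestSimulateLongReads:
    def test_error_free_reads_are_exact_substrings(self):
        genome = simulate_genome(BASE)
        reads = simulate_long_reads(genome, BASE)
        ref = genome.sequence
        for read in reads[:40]:
            assert read.sequence in ref or reverse_complement(read.sequence) in ref

    def test_total_bases_near_target_coverage(self):
        genome = simulate_genome(BASE)
        reads = simulate_long_reads(genome, BASE)
        total = sum(r.length for r in reads)
        target = BASE.coverage * BASE.genome_length
        assert target <= total <= 1.1 * target

    def test_strand_balance(self):
        config = SimulationConfig(
            genome_length=20_000, repeat_spec=(), gap_spec=(),
            read_length_mean=300, coverage=15.0, error_rate=0.0, seed=13,
        )
        genome = simulate_genome(config)
        reads = simulate_long_reads(genome, config)
        ref = genome.sequence
        fwd = sum(r.sequence in ref for r in reads)
        assert 0.45 <= fwd / len(reads) <= 0.55

    def test_error_rate_perturbs_reads(self):
        noisy = SimulationConfig(
            genome_length=10_000, repeat_spec=(), gap_spec=(),
            read_length_mean=600, coverage=2.0, error_rate=0.1, seed=3,
        )
        genome = simulate_genome(noisy)
        reads = simulate_long_reads(genome, noisy)
        ref = genome.sequence
        assert not any(
            r.sequence in ref or reverse_complement(r.sequence) in ref for r in reads[:20]
        )

    def test_determinism(self):
        genome = simulate_genome(BASE)
        a = simulate_long_reads(genome, BASE)
        b = simulate_long_reads(genome, BASE)
        assert [r.sequence for r in a] == [r.sequence for r in b]


def _report_row(gap_id, start, end, status="filled", filled_length=None):
    length = end - start
    return FillReportRow(
        gap_id, "s", start, end, length, status, "",
        length if filled_length is None else filled_length, 0.5, 3,
    )


class TestEvaluateFills:
    def test_exact_fill_scores_one(self):
        truth = {"s_gap1": "TTAA"}
        scaf = ScaffoldRecord("s", "ACGTTTAAACGT")
        report = FillReport(rows=[_report_row("s_gap1", 4, 8)])
        summary = evaluate_fills([scaf], truth, report)
        assert summary.per_gap[0].identity == 1.0
        assert summary.fraction_filled == 1.0 and summary.fraction_perfect == 1.0

    def test_unfilled_gap_scores_zero(self):
        truth = {"s_gap1": "TTAA"}
        scaf = ScaffoldRecord("s", "ACGTNNNNACGT")
        report = FillReport(
            rows=[_report_row("s_gap1", 4, 8, status="unfillable", filled_length=0)]
        )
        summary = evaluate_fills([scaf], truth, report)
        assert summary.per_gap[0].identity == 0.0
        assert summary.per_gap[0].status == "unfilled"

    def test_single_mismatch_identity(self):
        truth_seq = "A" * 100
        fill = "A" * 50 + "C" + "A" * 49
        truth = {"s_gap1": truth_seq}
        scaf = ScaffoldRecord("s", "GG" + fill + "GG")
        report = FillReport(rows=[_report_row("s_gap1", 2, 102)])
        summary = evaluate_fills([scaf], truth, report)
        assert summary.per_gap[0].identity == pytest.approx(0.99)

    def test_unknown_gap_id_rejected(self):
        report = FillReport(rows=[_report_row("s_gapX", 2, 6)])
        with pytest.raises(ValueError):
            evaluate_fills([ScaffoldRecord("s", "AAAAAAAA")], {}, report)
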