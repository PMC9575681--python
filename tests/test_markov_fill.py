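import numpy as np
import pytest

from markovfill.markov_fill import (
    ALPHABET,
    AnchorMissingError,
    CandidateSequence,
    NoCandidatesError,
    TransitionTable,
    UnfillableError,
    build_transition_table,
    count_transitions,
    encode_nucleotide,
    extract_candidates,
    fill_gap,
    generate_fill,
    score_fill,
)
from markovfill.read_extension import ExtensionRecord
from markovfill.sequence_io import LongRead


def cands(*seqs, gap_id="g"):
    return [
        CandidateSequence(gap_id, s, f"src{i}", True) for i, s in enumerate(seqs)
    ]


def brute_force_table(seqs):
    """Independent oracle: count every adjacent pair with plain dict loops,
    then normalize each row by its sum."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = [[0] * 4 for _ in range(4)]
    for s in seqs:
        for a, b in zip(s, s[1:]):
            counts[idx[a]][idx[b]] += 1
    probs = [[0.0] * 4 for _ in range(4)]
    for i in range(4):
        total = sum(counts[i])
        if total:
            probs[i] = [c / total for c in counts[i]]
    return np.array(counts), np.array(probs)


DETERMINISTIC = build_transition_table(cands("ACGTACGTACGT"))


class TestEncode:
    @pytest.mark.parametrize("ch, code", [("A", 0), ("C", 1), ("G", 2), ("T", 3), ("a", 0), ("t", 3)])
    def test_encoding(self, ch, code):
        assert encode_nucleotide(ch) == code

    def test_outside_alphabet(self):
        with pytest.raises(ValueError, match="N"):
            encode_nucleotide("N")


class TestExtractCandidates:
    READS = {"r1": LongRead("r1", "AAGGTTCC")}

    def rec(self, strand, start=2, end=6):
        return ExtensionRecord("r1", start, end, "g", strand, clamped=False)

    def test_plus_strand_substring(self):
        (c,) = extract_candidates([self.rec("+")], self.READS, gap_length=4)
        assert c.sequence == "GGTT" and c.full_length

    def test_minus_strand_reverse_complement(self):
        (c,) = extract_candidates([self.rec("-")], self.READS, gap_length=4)
        assert c.sequence == "AACC"

    def test_candidate_with_n_dropped(self):
        reads = {"r1": LongRead("r1", "AAGNTTCC")}
        assert extract_candidates([self.rec("+")], reads, gap_length=4) == []

    def test_unknown_read_id(self):
        with pytest.raises(KeyError, match="r9"):
            extract_candidates(
                [ExtensionRecord("r9", 0, 4, "g", "+", False)], self.READS, 4
            )

    def test_short_interval_not_full_length(self):
        (c,) = extract_candidates([self.rec("+", 2, 5)], self.READS, gap_length=4)
        assert not c.full_length


class TestCountTransitions:
    def test_simple_chain(self):
        counts = count_transitions("ACGT")
        expected = np.zeros((4, 4), dtype=int)
        expected[0, 1] = expected[1, 2] = expected[2, 3] = 1
        assert (counts == expected).all()

    def test_single_base_counts_nothing(self):
        assert not count_transitions("A").any()

    def test_homopolymer_run(self):
        counts = count_transitions("AAAA")
        assert counts[0, 0] == 3 and counts.sum() == 3


class TestBuildTransitionTable:
    def test_identical_candidates_give_deterministic_rows(self):
        table = build_transition_table(cands("ACGT", "ACGT"))
        assert table.probs[0, 1] == 1.0
        assert table.probs[1, 2] == 1.0
        assert table.probs[2, 3] == 1.0
        assert not table.probs[3].any()

    def test_two_pair_normalization(self):
        table = build_transition_table(cands("AA", "AC"))
        assert table.probs[0, 0] == 0.5 and table.probs[0, 1] == 0.5
        assert not table.probs[1:].any()

    def test_single_base_candidate_all_zero(self):
        assert build_transition_table(cands("A")).is_all_zero()

    def test_empty_candidate_list_raises(self):
        with pytest.raises(NoCandidatesError):
            build_transition_table([])

    def test_rows_sum_to_one_or_zero_and_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seqs = [
                "".join(ALPHABET[i] for i in rng.integers(0, 4, size=rng.integers(1, 51)))
                for _ in range(rng.integers(1, 21))
            ]
            table = build_transition_table(cands(*seqs))
            oc, op = brute_force_table(seqs)
            assert (table.counts == oc).all()
            assert np.abs(table.probs - op).max() <= 1e-12
            rowsums = table.probs.sum(axis=1)
            assert all(abs(s - 1) <= 1e-9 or s == 0 for s in rowsums)


class TestGenerateAndScore:
    def test_deterministic_chain_from_a(self):
        fill = generate_fill(DETERMINISTIC, 4, "A", np.random.default_rng(0))
        assert fill.sequence == "CGTA" and not fill.partial

    def test_periodic_chain_from_t(self):
        fill = generate_fill(DETERMINISTIC, 8, "T", np.random.default_rng(0))
        assert fill.sequence == "ACGTACGT"

    def test_lowercase_anchor_uppercased(self):
        fill = generate_fill(DETERMINISTIC, 4, "a", np.random.default_rng(0))
        assert fill.sequence == "CGTA"

    def test_dead_anchor_row_gives_empty_partial(self):
        table = build_transition_table(cands("CGCG"))  # A row is all zero
        fill = generate_fill(table, 4, "A", np.random.default_rng(0))
        assert fill.sequence == "" and fill.partial

    def test_anchor_outside_alphabet(self):
        with pytest.raises(AnchorMissingError):
            generate_fill(DETERMINISTIC, 4, "N", np.random.default_rng(0))

    def test_all_zero_table_unfillable(self):
        table = TransitionTable(np.zeros((4, 4), dtype=int), np.zeros((4, 4)))
        with pytest.raises(UnfillableError):
            generate_fill(table, 4, "A", np.random.default_rng(0))

    def test_score_deterministic_path_is_one(self):
        assert score_fill("CGTA", DETERMINISTIC) == 1.0

    def test_score_is_mean_of_step_probabilities(self):
        table = build_transition_table(cands("AA", "AC"))  # A->A = 0.5
        assert score_fill("AAAA", table) == pytest.approx(0.5)

    def test_length_one_scores_zero(self):
        assert score_fill("A", DETERMINISTIC) == 0.0


class TestFillGap:
    def test_one_bp_gap_unfillable(self):
        res = fill_gap(cands("A", "C"), "g", 1, "A", np.random.default_rng(0))
        assert res.status == "unfillable" and res.reason == "gap_too_short"

    def test_deterministic_table_degenerate_sampling(self):
        res = fill_gap(cands("ACGTACGTACGT"), "g", 8, "T", np.random.default_rng(0))
        assert res.status == "filled"
        assert res.fill.sequence == "ACGTACGT"
        assert res.fill.avg_cost == 1.0

    def test_seeded_run_is_reproducible(self):
        out = [
            fill_gap(cands("AA", "AC"), "g", 12, "A", np.random.default_rng(42)).fill.sequence
            for _ in range(3)
        ]
        assert len(set(out)) == 1

    def test_missing_anchor_reported(self):
        res = fill_gap(cands("ACGT"), "g", 4, None, np.random.default_rng(0))
        assert res.reason == "anchor_missing"

    def test_no_candidates_reported(self):
        res = fill_gap([], "g", 4, "A", np.random.default_rng(0))
        assert res.reason == "no_candidates"

    def test_all_zero_table_reported(self):
        res = fill_gap(cands("A"), "g", 4, "A", np.random.default_rng(0))
        assert res.reason == "all_zero_table"

    def test_sample_count_range_enforced(self):
        with pytest.raises(ValueError):
            fill_gap(cands("ACGT"), "g", 4, "A", np.random.default_rng(0), n_samples=3)
        # and can be switched off
        res = fill_gap(
            cands("ACGTACGTACGT"), "g", 4, "A", np.random.default_rng(0),
            n_samples=2, enforce_sample_range=False,
        )
        assert res.status == "filled"

    def test_partial_fill_only_when_no_full_sample(self):
        # G row is dead: any walk reaching G stops; anchored on G everything
        # is an immediate dead end except the first emitted base
        table_cands = cands("GAGA")  # transitions G->A, A->G
        res = fill_gap(table_cands, "g", 6, "G", np.random.default_rng(1))
        assert res.status == "filled"  # A<->G alternation never dies
        res2 = fill_gap(cands("GA"), "g", 6, "G", np.random.default_rng(1))
        # only G->A known; walk emits A then hits the dead A row
        assert res2.status == "partial"
        assert res2.fill.sequence == "A" and res2.fill.partial
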