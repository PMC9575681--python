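# Methods

## Model

`markovfill` treats the sequence missing under an N-run as a realization of
a first-order Markov chain over {A, C, G, T} whose transition probabilities
are estimated locally, from long-read sequence that aligns to the gap's
flanks. The underlying assumptions are:

* reads that align to a flank at high identity and end near the gap are
  likely to continue into (or across) the gap with the true sequence;
* the dinucleotide statistics of those continuations carry a local pattern
  that a first-order chain can capture;
* anchoring generation on the last known base before the gap keeps the
  chain consistent with the immediate context instead of starting from an
  arbitrary state.

The model is *generative*, not a consensus: candidate sequences train a 4×4
transition matrix, and fills are sampled from it. Two consequences follow.
First, the method needs at least one nucleotide *pair*, so a 1 bp gap is
structurally unfillable (its candidates are single bases; the table stays
all-zero). Second, a sampled walk reproduces the candidates' transition
statistics but not their exact base sequence; see "Accuracy ceiling" below.

## Pipeline stages and parameters

| parameter | default | units | role |
|---|---|---|---|
| `flank_len` | 500 | bases | flank extracted per side; bounds query size so alignments stay gap-specific |
| `min_gap_len` | 1 | bases | smallest N-run reported (1 bp gaps are still detected, then reported unfillable) |
| `min_identity` | 97 | % | removal cutoff for hits (matches / aligned columns, indel columns included) |
| `hq_identity` | 98 | % | reporting threshold for high-quality matches (logged per gap, not a filter) |
| `min_aln_length` | 40 | bases | shortest informative alignment; suppresses spurious repeat seeds |
| `max_gap_distance` | 10 | bases | how far a hit's gap-facing end may sit from the N-run |
| `n_samples` | 8 | — | Markov generations per gap (accepted range 5–10) |
| `seed` | 42 | — | master seed; each gap derives an independent stream from seed + CRC32(gap_id) |

Flanks stop at the scaffold boundary, at a neighboring N, or at any IUPAC
ambiguity code, so a flank never spans another gap and candidates are always
plain A/C/G/T. `min_aln_length` and `max_gap_distance` have no uniquely
correct values; 40 bp is long enough that a chance k-mer chain at 97%
identity is unlikely, and 10 bp keeps extension offsets small so the
projected interval stays accurate even with small indel drift.

## Alignment

The internal aligner is seed-and-extend: exact 15-mer seeds from non-N
query positions against a hash index of the reads, chained by diagonal
(band 30), then refined with edlib infix alignment to get exact subject
coordinates and identity. Both query orientations are seeded; reverse hits
are reported with subject coordinates on the original read and the
geometric correspondence qstart↔send, qend↔sstart. Percent identity counts
matching columns over aligned columns, with the query's N columns excluded
from both: an unknown base is evidence neither for nor against a read, and
counting Ns as mismatches would reject precisely the most informative hits
(reads bridging the whole gap). A pre-computed 12-column tabular alignment
(1-based inclusive coordinates, reversed pairs allowed) can replace the
internal aligner; coordinates are normalized once at parse time and the
pipeline is otherwise identical.

Extension arithmetic: for forward hits the candidate interval is obtained
by shifting the subject coordinate by the query-space distance between the
alignment and the gap; for reverse hits the same distance is applied in the
opposite direction on the read. The gap-near index is computed and clamped
to the read first, then the far index is derived from it by the gap length,
so a clamped interval is flush with the read boundary. Reverse-orientation
rightward extension uses `new_end = sstart − (gap_start − qend)` with
`new_start = new_end − gap_length`; this is the mirror image of the leftward
reverse branch and reduces to the flush-with-gap shortcut when the
alignment touches the gap exactly.

## Transition table and generation

Raw pair counts are summed across all candidates before a single row
normalization. The alternative — averaging per-candidate probability
tables — would weight a 1-pair candidate equally with a 500-pair one and
was rejected; the frequency interpretation says evidence should scale with
the number of observed pairs. Rows with zero observations stay all-zero
(never smoothed): inventing transitions the data never showed would let the
chain wander into unsupported sequence.

Scoring uses exactly the n−1 internal transitions of an n-base fill,
excluding the anchor step; the anchor is context, not part of the generated
sequence, and including its probability would penalize gaps whose preceding
base happens to be rare. Length-1 fills score 0 by convention. Ties on
average cost break to the lexicographically smallest sequence, then lowest
sample index, making selection deterministic. Partial fills (a walk that
reached a dead state, or clamped candidates providing only short evidence)
are selected only when no full-length sample exists, and only their length
replaces Ns.

Gaps whose anchor base is missing (gap at scaffold position 0, or an
adjacent gap immediately left) are reported unfillable rather than anchored
on the right flank with a reversed walk; the chain is defined forwards, and
inventing a backwards variant would be a different model.

## Synthetic fixtures

The generator emulates a resequencing-style study at desk scale: a uniform
random genome at a chosen GC, optional planted repeat copies with
point-substitution divergence (repeats being the canonical cause of
assembly gaps, roughly half the simulated gaps are centered inside repeat
copies when repeats exist), N-masked intervals with recorded truth, and
reads sampled uniformly over position and strand with lengths
N(mean, mean/4) floored at 200 bp and errors mixed
substitution:insertion:deletion = 60:20:20. The default configuration —
the reference study used by the test suite and `scripts/acceptance.py` —
is a 50 kb genome at GC 0.5, one 100-base repeat ×5 at 2% divergence,
twenty gaps of 50–300 bp, 2 kb reads at 15×, error rate 0. These sizes keep
a full run in seconds while giving every gap well-covered flanks.

What the fixtures do **not** emulate: chimeric reads, quality values,
heterozygosity, long tandem arrays, and the length-dependent error profile
of real long reads. Passing tests therefore demonstrate the pipeline's
coordinate arithmetic, filtering and determinism under ideal-to-mild
conditions, not performance on real sequencing data.

## Accuracy ceiling of sampled fills

With error-free reads every candidate is an exact copy of the true gap
sequence, so the transition table is the truth's own dinucleotide table.
Unless each state has a unique successor (periodic or homopolymeric truth),
sampling from that table diverges from the true base sequence within a few
steps; empirically the edit-distance identity of a first-order resample to
its training sequence sits near 0.45–0.65 for random 50–300 bp sequences at
GC 0.5. The reference study measures this directly: 20/20 gaps filled,
mean fill identity ≈ 0.46 (seed 1). Choosing the highest-average-cost
sample among 8 biases toward high-probability paths, which raises the
transition score, not sequence accuracy. Fills are therefore
*statistically plausible* gap closures — correct length, correct local
composition — and downstream analyses that need base-exact sequence should
treat filled regions accordingly. A consensus or polish step over the
candidate sequences would raise base accuracy but is a different algorithm,
deliberately out of scope.

## Numerical and degenerate-input choices

* Row normalization uses exact division guarded by the row sum; rows sum to
  1 within 1e−9 or are exactly zero.
* Per-gap RNG streams derive from the master seed and a CRC32 of the gap
  id, so results are independent of gap processing order and bitwise
  reproducible.
* A gap whose flanks are both empty (N-run surrounded by N or boundaries)
  is marked `no_flanks` and skipped before alignment.
* When both flanks are truncated but non-empty, the scenario records the
  shorter side (`left_short` on ties).
* Fills longer than their gap are a hard error, never silently truncated;
  candidate intervals extracting an N are dropped, not patched.
* An empty interval after boundary clamping (read too short to hold any of
  the gap) contributes no candidate.

## Known limitations

* First-order chains cannot capture motifs longer than 2 bp; gap sequence
  accuracy is bounded as described above.
* Single-sided flanks fill from one anchor only; if reads do not extend far
  enough, the remainder stays N (partial fill).
* The internal aligner is exact-seed based: identity below ~90% or very
  short flanks (< ~40 bp of clean sequence) yield no usable hits.
* Gap length is taken from the N-run length; the true inserted sequence
  length is not re-estimated.
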