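# markovfill

Draft genome assemblies are delivered as *scaffolds*: ordered contigs joined
by runs of `N` that stand for sequence the assembler could not resolve —
very often the fallout of genomic repeats. `markovfill` closes such N-gaps
using long reads (PacBio/ONT-like), for assembly practitioners who want a
fast, statistical gap-filling pass over a draft before annotation.

## Method

For every maximal N-run the pipeline:

1. **Gap detection** — extracts up to `flank_len` (default 500 bp) of clean
   sequence on each side of the gap and forms the query
   `left_flank + N^L + right_flank`, where `L` is the gap length.
2. **Long-read alignment** — locally aligns the query against every read and
   its reverse complement (exact 15-mer seeds, diagonal chaining, edit-distance
   refinement). Hits are kept only if percent identity ≥ 97 (matches over
   aligned columns; ≥ 98 is flagged high-quality), the alignment is at least
   `min_aln_length` (40 bp), and the hit lies within `max_gap_distance`
   (10 bp) of the gap.
3. **Read extension** — each surviving flank hit is projected across the gap
   onto the read. For a left-flank hit in forward orientation the candidate
   interval starts at `send + (gap_start − qend)` and spans `L` bases; for a
   right-flank hit it ends where `sstart − (L + (qstart − gap_end))` begins,
   with the mirrored arithmetic for reverse-orientation hits and clamping at
   read boundaries (clamped intervals are shorter than `L` and drive partial
   fills). Intervals are written as BED6, minus-strand intervals are
   reverse-complemented on extraction.
4. **Transition table** — nucleotides are encoded A=0, C=1, G=2, T=3 and the
   adjacent-pair frequencies of all candidate sequences are summed into one
   4×4 table, then each row is normalized to a probability distribution
   P(next = j | current = i) (rows with no observations stay zero).
5. **Markov generation** — anchored on the (uppercased) last base before the
   gap, a first-order Markov chain samples `L` states. Generation is repeated
   `n_samples` times (5–10, default 8) and the sample with the highest
   *average transition cost* — the mean of the n−1 step probabilities of an
   n-base sequence — is spliced into the scaffold. Walking into an all-zero
   row ends a sample early; if no full-length sample exists the best partial
   one replaces only the leading Ns.

Gaps of 1 bp are reported *unfillable*: a 1-base candidate holds no
nucleotide pair, so no pattern can be learned. Everything outside reported
gap intervals is copied byte-for-byte, case included.

## Worked example

Simulate a small study with known truth, fill it, and score the fills:

```
$ markovfill simulate --out sim --genome-length 6000 --gaps 3 \
      --gap-min 30 --gap-max 60 --read-length 500 --coverage 10 --seed 5
wrote fixtures for 3 gaps to sim

$ markovfill run --scaffolds sim/scaffold.fasta --long-reads sim/reads.fasta \
      --out run --seed 5
{"filled": 3, "total": 3}

$ markovfill evaluate --filled run/filled.fasta --truth sim/truth.tsv \
      --report run/report.tsv
{"fraction_filled": 1.0, "fraction_perfect": 0.0, "mean_identity": 0.5065690690690691, "n_gaps": 3}
```

All three gaps received a full-length fill (`"filled": 3`). The
edit-distance identity of the generated sequence to the true (masked)
sequence averages ≈ 0.51: the fills reproduce the local dinucleotide
statistics of the gap region, not the exact bases — the expected behaviour
of a first-order Markov sampler (see `docs/methods.md` for why this is the
method's accuracy ceiling). `run/report.tsv` lists per-gap status, filled
length, average transition cost and candidate counts; `run/gaps.jsonl` logs
each gap's alignment and candidate statistics.

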