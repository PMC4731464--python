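# Methods

## Model and procedure

`otupick` performs closed-reference OTU picking: each amplicon read is
assigned to its first acceptable match in a fixed marker-gene reference set
at a percent-identity threshold, and reads with no acceptable match are
discarded (optionally collected for downstream de-novo handling). The
design assumption is the standard marker-gene setting: reads begin at a
common primer site (uniform start), are much shorter than the reference
genes, and most reads match some reference nearly perfectly.

### Concatesome

All references are concatenated with **no separator characters**; an offset
index records each gene's 0-based start. Separators would perturb the BWT
alphabet and search behaviour, and boundary safety is handled entirely in
parsing: an alignment covering `[start, start+span)` is rejected as a
junction artifact iff its end exceeds the next gene's start offset. An
alignment ending *flush* at the boundary is a legitimate full-length match
and is kept — with half-open intervals, the strict `end > next_start` test
is the exact equivalent of rejecting any alignment that reaches into the
subsequent gene. Coordinates are 0-based half-open everywhere inside the
package; SAM's 1-based POS is converted exactly once, in the SAM parser.

### Filtering

* Trimming keeps the first `trim_length` bases and happens before
  deduplication; reverse-complementing happens only at output writing.
  Quality-aware trimming is upstream of this tool.
* Deduplication collapses identical sequences into one entry with
  per-sample counts. The contract is the *output* (lexicographic entry
  order, counts equal to a naive tally); the internal algorithm is free.
* Read compaction (`d_level ≥ 1`) treats a sequence that is a **prefix** of
  a longer sequence as a truncated copy of it and merges its counts into
  the longest containing entry (chains merge transitively). Prefix rather
  than general substring containment matches uniform-start amplicons, where
  length variation comes from trimming, and keeps the merge target unique.
* Count filtering (`d_level ≥ 2`) removes entries with total count
  `< d_level`: level 2 removes singletons, level 3 also doubletons, etc.
  The premise is that a sequence observed twice or more is unlikely to be a
  sequencing error.
* k-mer denoising (off by default) profiles the empirical k-mer spectrum
  over the raw read multiset (before dedup) with a counter array of length
  4^k indexed by the 2-bit code A=00, C=01, G=10, T=11 (leftmost base most
  significant; k = 8 by default, practical range 8–14, giving a 2^16-slot
  array at the default). A read is discarded iff any of its k-mers occurs
  fewer than `denoise_fraction × n_reads` times. The threshold denominator
  is the number of profiled *reads* (per-read prevalence): a fraction of
  10⁻⁴ at 10⁵ reads means a k-mer must be supported by at least 10 reads.
  Windows containing non-ACGT characters are skipped entirely — never
  encoded, never counted, never grounds for discard — because the 2-bit
  code has no slot for ambiguity codes.

### Alignment

The matching criterion is percent identity: matching columns divided by
total alignment length spanning the full query, with matches to ambiguous
reference bases unpenalized and no affine gap weighting (each gap base
counts as one non-match, sequential gaps no worse than single ones). The
search terminates at the first acceptable hit.

The embedded aligner implements this contract directly:

1. **Exact path.** Backward search of the whole read in the FM-index; the
   leftmost occurrence wins (identity 1.0).
2. **Seed-and-extend.** Maximal exact matches ending at a few anchor
   positions in the read (found by leftward backward-search extension)
   serve as seeds; each candidate locus is extended by the semi-global DP
   against a reference window of the read length plus a padding of
   `ceil((1 − min_identity) × read length)` (at least 4) on both sides.
   Candidates are examined longest-seed-first, then leftmost-position, and
   the first meeting the threshold is returned. This ordering is a contract
   choice that makes first-hit behaviour deterministic; it is not a claim
   about any external aligner's internal tie-breaking.

Effort presets trade seed coverage for speed: `fast` uses one anchor (the
read end) and examines up to 4 occurrences per seed; `default` three
anchors / 16 occurrences; `max` six anchors / 64 occurrences with extra
window padding. The preset names mirror common aligner presets; the exact
parameterization is this package's own.

Ambiguity codes are kept verbatim in the concatesome but collapsed to `A`
inside the FM-index text (a 2-bit-friendly alphabet); any hit found through
the index is re-scored by the DP against the true concatesome text, where
ambiguity matches are free, so the scoring contract is preserved. Suffix
offsets are stored unsampled — desk-scale simplicity over memory fidelity.

For an external BWT aligner, the option set emitted is: no ambiguous-base
penalty, mismatch penalty 1, read/reference gap penalties 0 open / 1 per
base, minimum score `L,0,(min_identity − 1)` formatted to two decimals
(0.97 → `-0.03`), first hit only, forward strand only, headerless SAM,
unaligned reads suppressed. Reverse-complementing, if needed, is the filter
stage's job (`--rc`), which is why reverse-strand search stays off.

### Semi-global identity oracle

The DP aligns the full query with free gaps at the reference segment's
ends, minimizing mismatches + gap bases (unit costs, no affine term);
identity = matches / alignment length of the minimum-cost alignment, with
traceback preference diagonal > deletion > insertion and the leftmost
minimum-cost end column, making the reported CIGAR deterministic. The same
routine extends seeds in the aligner and re-scores reported hits in the
test suite, and is checked against exhaustive alignment enumeration (string
lengths ≤ 7) and against edlib's infix mode on random instances.

### Parsing

Row order in the OTU table is first appearance in the hit stream; column
order is lexicographic sample id — both arbitrary but deterministic, so
outputs diff cleanly. Each hit contributes its dictionary entry's full
per-sample counts. If an externally produced SAM carries several alignments
for one tag, the first line wins and later ones are warned about, matching
first-hit intent. Matched, junction-dropped and unmatched entries form a
disjoint partition of the dictionary, so table counts + junction-dropped
read counts + unmatched read counts always equal the dictionary total; the
junction count and fraction are reported in the run summary. The BIOM 1.0
writer emits the required keys of the sparse JSON dialect; its `date` field
can be pinned for byte-reproducible runs. BIOM 2.x (HDF5) is out of scope.

## Synthetic data generator

The generator emulates a small uniform-start amplicon experiment, the
setting the pipeline targets. Defaults: 5 references of 400–500 bp (the
scale of a 16S variable-region amplicon target), 3 samples, 100 reads per
sample of 150 bp (a short-read sequencing read length), a geometric
abundance profile over references (p = 0.5, order shuffled per sample —
communities dominated by a few taxa), and zero error. Substitution and
indel errors are flat per-base rates; 2% substitution is used as the noisy
condition in tests, at the high end for modern short reads so that the 97%
threshold is actually exercised. References are random sequences
rejection-sampled (shared-12-mer screen) to be far below 97% pairwise
identity, so every read has an unambiguous true OTU recorded in the
manifest.

What the generator does **not** emulate: quality-score-dependent or
homopolymer-context error models, chimeras, primer/adapter remnants,
paired-end structure, and realistic reference databases where distinct
OTUs sit near the 97% boundary. Passing tests therefore demonstrate the
pipeline's bookkeeping and contracts (conservation, coordinate mapping,
threshold semantics), not OTU-assignment accuracy on real communities.
A shotgun mode drawing reads from random concatesome positions exists only
to manufacture junction-spanning alignments for boundary tests.

## Problem sizes and numerical choices

Tests and the worked example run at desk scale: hundreds of reads, a few
kilobases of concatesome. The FM-index uses full (unsampled) suffix
offsets and dense rank tables; the suffix array is built by prefix
doubling. The minimum-score third argument is formatted to two decimals.
Degenerate inputs are handled explicitly: an empty read file yields an
empty table and a zero-count summary; an empty reference set, duplicate
OTU ids and empty sequences are rejected with the offending record named;
reads shorter than k contribute no k-mers; patterns absent from the index
return empty results rather than errors.

## Known limitations

* The embedded aligner is contract-equivalent to, not bit-identical with,
  external BWT aligners; on ties it may pick a different (equally
  acceptable) reference.
* Prefix-only compaction will not merge internal-substring containments
  (deliberate, flagged above).
* Single-threaded throughout; the intended scale is method development and
  testing, with external aligners available for production-size datasets.
* FASTA input only; demultiplexed sample ids are taken from the text before
  the last underscore of each header token.
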