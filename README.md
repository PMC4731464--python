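# otupick

Closed-reference OTU picking for marker-gene (amplicon) surveys — 16S rRNA
and similar — built around a single concatenated reference chromosome, the
**concatesome**.

Microbiome studies routinely bin millions of short amplicon reads into
Operational Taxonomic Units (OTUs) by matching each read against a fixed
reference database (e.g. a Greengenes-style 97% representative set) at a
percent-identity threshold. `otupick` does this with short-read-mapping
machinery rather than heuristic clustering: all reference genes are joined
end to end into one long sequence, an FM-index (Burrows-Wheeler transform +
rank structures) makes substring search over every reference simultaneous,
and an offset index maps alignment coordinates back to individual OTUs. A
read whose alignment crosses the boundary between two concatenated genes is
discarded as a junction artifact.

## The method

The pipeline has three stages:

1. **Filter.** Reads are optionally trimmed, then deduplicated into unique
   sequences while a *sample dictionary* records how many times each
   sequence occurred in each sample — deduplication is lossless. Optional
   lossy denoising removes probable error reads: *count filtering* drops
   sequences observed fewer than `d − 1` times (`-d 2` drops singletons),
   and *k-mer filtering* drops any read containing a k-mer whose count in
   the empirical k-mer spectrum (a counter array of length 4^k, k = 8 by
   default) falls below a prevalence threshold.
2. **Align.** Each unique sequence is aligned end-to-end against the
   concatesome under the percent-identity criterion: matches score 1,
   mismatches of any kind 0, matches to ambiguous reference bases are not
   penalized, and gaps carry no affine component; identity is matching
   columns over alignment length, and the first hit with identity ≥ the
   threshold (default 0.97) is accepted. The embedded aligner does exact
   backward search first, then seed-and-extend with a semi-global dynamic
   program (free gaps at the reference ends, full query coverage).
   Alternatively `otupick` emits the exact option set for an external
   BWT aligner — the identity threshold maps to the minimum-score function
   as `%ID/100 − 1`, e.g. `--score-min L,0,-0.03` for 97% — and consumes
   its headerless SAM.
3. **Parse.** Alignments are resolved to OTUs through the offset index
   (junction hits discarded), each unique sequence is expanded back into its
   per-sample counts, taxonomy is attached from an optional OTU→taxonomy
   map, and the sparse sample-by-OTU table is written as BIOM 1.0 JSON or
   legacy tab-delimited format.

## Worked example

Simulate a small study (5 reference genes, 3 samples, 300 error-free 150 bp
reads) and run the full pipeline with singleton filtering:

```sh
otupick simulate --seed 7 --out demo/fixtures
otupick run --refs demo/fixtures/refs.fna --reads demo/fixtures/reads.fna \
    --tax demo/fixtures/taxonomy.tsv --min-id 0.97 --d-level 2 \
    --format legacy --out demo/out
```

which prints the run summary

```json
{
 "reads_in": 300,
 "reads_denoised": 0,
 "duplicates_removed": 295,
 "unique_aligned_queries": 5,
 "reads_aligned": 300,
 "junction_hits": 0,
 "junction_reads": 0,
 "unmatched_entries": 0,
 "otus_observed": 5,
 "table_total": 300
}
```

— all 300 reads collapse to 5 unique sequences (one per reference), every
one aligns at identity 1.0, none spans a junction, and the table conserves
the full read count. `demo/out/table.txt` begins:

```
#OTU ID	S1	S2	S3	taxonomy
OTU4	46	60	7	k__Bacteria; p__Phylum4; c__Class4; o__Order4; f__Family4; g__Genus4; s__species4
OTU5	11	11	10	k__Bacteria; p__Phylum5; c__Class5; o__Order5; f__Family5; g__Genus5; s__species5
```

Each row is one picked OTU with its per-sample read counts and taxonomy
string. To drive an external BWT aligner instead, print its option set:

```sh
$ otupick align --emit-bowtie2-cmd --min-id 0.97
--np 0 --mp 1,1 --rdg 0,1 --rfg 0,1 --score-min L,0,-0.03 -k 1 --norc --no-hd --no-unal
```

then pass the resulting SAM to `otupick parse` (or `otupick run
--external-sam hits.sam ...`).

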