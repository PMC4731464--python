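"""Read parsing, dedup, compaction, count filtering and k-mer denoising."""

import io
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otupick import (
    FilterConfig,
    KmerCounter,
    ReadRecord,
    build_kmer_counter,
    compact_reads,
    deduplicate,
    denoise_reads,
    encode_kmer,
    filter_by_count,
    parse_reads,
    reverse_complement,
    run_filter,
    trim_read,
)
from otupick.filtering import DedupDictionary, DedupEntry, read_dictionary, write_filtered
from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def naive_dedup(reads):
    """Independent oracle: Counter over (sequence, sample) pairs."""
    c = Counter((r.sequence, r.sample_id) for r in reads)
    out = {}
    for (seq, sample), n in c.items():
        out.setdefault(seq, {})[sample] = n
    return out


def as_mapping(d: DedupDictionary):
    return {e.sequence: dict(e.counts) for e in d.entries}


class TestParseReads:
    def test_single_record(self):
        recs = parse_reads(io.StringIO(">S1_0\nacgt\n"))
        assert recs == [ReadRecord("S1", "S1_0", "ACGT")]

    def test_two_samples(self):
        recs = parse_reads(io.StringIO(">S1_0\nAC\n>S2_0\nGT\n"))
        assert [r.sample_id for r in recs] == ["S1", "S2"]

    def test_underscore_in_sample_name_splits_at_last(self):
        recs = parse_reads(io.StringIO(">mouse_gut_12\nAC\n"))
        assert recs[0].sample_id == "mouse_gut"

    def test_header_without_underscore_used_whole(self):
        recs = parse_reads(io.StringIO(">lonely\nAC\n"))
        assert recs[0].sample_id == "lonely"

    def test_per_sample_counts_match_generator_manifest(self, clean_dataset, tmp_path):
        path = tmp_path / "reads.fna"
        path.write_text(clean_dataset.reads_fasta())
        recs = parse_reads(str(path))
        expected = Counter(rec["sample"] for rec in clean_dataset.manifest)
        assert Counter(r.sample_id for r in recs) == expected


class TestTrimAndRc:
    def test_trim_basic(self):
        assert trim_read("ACGTACGT", 4) == "ACGT"

    def test_trim_shorter_than_limit(self):
        assert trim_read("ACG", 10) == "ACG"

    @given(dna, st.integers(min_value=1, max_value=100))
    def test_trim_never_exceeds_limit(self, seq, n):
        assert len(trim_read(seq, n)) <= n

    def test_rc_palindrome(self):
        assert reverse_complement("ACGT") == "ACGT"

    def test_rc_hand_computed(self):
        assert reverse_complement("AACG") == "CGTT"

    def test_rc_ambiguity_codes(self):
        assert reverse_complement("NRY") == "RYN"

    def test_rc_rejects_non_iupac(self):
        with pytest.raises(ValueError, match="X"):
            reverse_complement("ACXG")

    @given(st.text(alphabet="ACGTNRYSWKMBDHV", min_size=1, max_size=80))
    def test_rc_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestDeduplicate:
    def test_merges_across_samples(self):
        reads = [
            ReadRecord("S1", "S1_0", "ACGT"),
            ReadRecord("S1", "S1_1", "ACGT"),
            ReadRecord("S2", "S2_0", "ACGT"),
        ]
        d = deduplicate(reads)
        assert len(d) == 1
        assert d.entries[0].counts == {"S1": 2, "S2": 1}

    def test_distinct_sequences_stay_distinct(self):
        reads = [ReadRecord("S1", f"S1_{i}", s) for i, s in enumerate(["AA", "CC", "GG"])]
        d = deduplicate(reads)
        assert len(d) == 3
        assert all(e.total == 1 for e in d)

    def test_lexicographic_entry_order(self, rng):
        reads = [ReadRecord("S1", f"S1_{i}", random_dna(rng, 8)) for i in range(50)]
        d = deduplicate(reads)
        seqs = [e.sequence for e in d]
        assert seqs == sorted(seqs)

    def test_equals_naive_oracle_on_large_fixture(self, rng):
        reads = [
            ReadRecord(f"S{rng.integers(1, 4)}", f"r{i}", random_dna(rng, 6))
            for i in range(10_000)
        ]
        assert as_mapping(deduplicate(reads)) == naive_dedup(reads)

    def test_conservation_lossless(self, rng):
        reads = [
            ReadRecord(f"S{rng.integers(1, 4)}", f"r{i}", random_dna(rng, 10))
            for i in range(500)
        ]
        assert deduplicate(reads).total_count == len(reads)


class TestCompaction:
    def test_prefix_merged_into_container(self):
        d = DedupDictionary([
            DedupEntry("", "ACGT", {"S2": 3}),
            DedupEntry("", "ACGTAC", {"S1": 1}),
        ])
        out = compact_reads(d)
        assert as_mapping(out) == {"ACGTAC": {"S1": 1, "S2": 3}}

    def test_no_containment_is_identity(self):
        d = DedupDictionary([
            DedupEntry("", "AAAA", {"S1": 1}),
            DedupEntry("", "CCCC", {"S1": 2}),
        ])
        assert as_mapping(compact_reads(d)) == as_mapping(d)

    def test_chain_merges_transitively(self):
        d = DedupDictionary([
            DedupEntry("", "AC", {"S1": 1}),
            DedupEntry("", "ACG", {"S2": 2}),
            DedupEntry("", "ACGT", {"S1": 4}),
        ])
        out = compact_reads(d)
        assert as_mapping(out) == {"ACGT": {"S1": 5, "S2": 2}}

    def test_non_prefix_substring_not_merged(self):
        # containment is prefix containment: "CGT" is inside "ACGT" but not a prefix
        d = DedupDictionary([
            DedupEntry("", "CGT", {"S1": 1}),
            DedupEntry("", "ACGT", {"S1": 1}),
        ])
        assert len(compact_reads(d)) == 2

    @given(st.lists(st.tuples(dna, st.integers(1, 5)), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_compaction_preserves_total_and_never_grows(self, items):
        entries = {}
        for seq, n in items:
            entries[seq] = entries.get(seq, 0) + n
        d = DedupDictionary(
            [DedupEntry("", s, {"S1": n}) for s, n in sorted(entries.items())]
        )
        out = compact_reads(d)
        assert out.total_count == d.total_count
        assert len(out) <= len(d)
        # no surviving sequence is a proper prefix of another
        seqs = [e.sequence for e in out]
        for a in seqs:
            for b in seqs:
                assert a == b or not b.startswith(a)


class TestCountFilter:
    def _dict(self, totals):
        return DedupDictionary(
            [DedupEntry("", random_dna(np.random.default_rng(i), 10), {"S1": t})
             for i, t in enumerate(totals)]
        )

    def test_singleton_exclusion(self):
        d = self._dict([5, 2, 1])
        out = filter_by_count(d, 2)
        assert sorted(e.total for e in out) == [2, 5]

    def test_level_zero_identity(self):
        d = self._dict([5, 2, 1])
        assert as_mapping(filter_by_count(d, 0)) == as_mapping(d)

    def test_doubleton_exclusion(self):
        d = self._dict([5, 2, 1])
        out = filter_by_count(d, 3)
        assert [e.total for e in out] == [5]

    def test_monotone_in_d_level(self, rng):
        totals = list(rng.integers(1, 8, size=30))
        d = self._dict(totals)
        prev = None
        for level in range(0, 8):
            surv = {e.sequence for e in filter_by_count(d, level)}
            if prev is not None:
                assert surv <= prev
            prev = surv


class TestKmerCounter:
    def test_encode_all_zero(self):
        assert encode_kmer("AAAA") == 0

    def test_encode_printed_mapping(self):
        # A=00 C=01 G=10 T=11, leftmost base most significant: 0b00011011
        assert encode_kmer("ACGT") == 27

    def test_encode_all_ones(self):
        assert encode_kmer("TTTT") == 4**4 - 1

    def test_encode_rejects_ambiguity(self):
        with pytest.raises(ValueError):
            encode_kmer("ACGN")

    def test_sliding_window_counts(self):
        kc = build_kmer_counter([ReadRecord("S", "S_0", "AAAAA")], k=4)
        assert kc.counts[0] == 2
        assert kc.total_kmers == 2

    def test_read_shorter_than_k_contributes_nothing(self):
        kc = build_kmer_counter([ReadRecord("S", "S_0", "ACG")], k=4)
        assert kc.total_kmers == 0

    def test_default_k_array_length(self):
        assert len(KmerCounter.empty(8).counts) == 65536

    def test_mass_formula_with_ns(self, rng):
        reads = []
        expected = 0
        for i in range(50):
            seq = list(random_dna(rng, int(rng.integers(3, 30))))
            for j in range(len(seq)):
                if rng.random() < 0.1:
                    seq[j] = "N"
            seq = "".join(seq)
            reads.append(ReadRecord("S", f"S_{i}", seq))
            k = 5
            for w in range(max(0, len(seq) - k + 1)):
                if "N" not in seq[w : w + k]:
                    expected += 1
        kc = build_kmer_counter(reads, k=5)
        assert kc.total_kmers == expected
        assert int(kc.counts.sum()) == expected


class TestDenoise:
    def test_identical_reads_never_discarded(self):
        reads = [ReadRecord("S", f"S_{i}", "ACGTACGTACGT") for i in range(20)]
        kc = build_kmer_counter(reads, k=4)
        kept, discarded = denoise_reads(reads, kc, 0.999)
        assert discarded == []

    def test_unique_error_kmer_discards_exactly_that_read(self):
        # 10^4 clean copies of one template; one read with a single error k-mer.
        template = "ACGTACGTACGTACGTACGT"
        reads = [ReadRecord("S", f"S_{i}", template) for i in range(10_000)]
        errored = template[:9] + "G" + template[10:]  # C->G at position 9
        assert errored != template
        reads.append(ReadRecord("S", "S_err", errored))
        kc = build_kmer_counter(reads, k=8)
        kept, discarded = denoise_reads(reads, kc, 1e-3)
        assert [r.read_id for r in discarded] == ["S_err"]

    def test_discard_sets_nested_in_threshold(self, rng):
        reads = [
            ReadRecord("S", f"S_{i}", random_dna(rng, 30)) for i in range(200)
        ] + [ReadRecord("S", f"T_{i}", "ACGT" * 8) for i in range(200)]
        kc = build_kmer_counter(reads, k=6)
        _, d1 = denoise_reads(reads, kc, 0.001)
        _, d2 = denoise_reads(reads, kc, 0.005)
        assert {r.read_id for r in d1} <= {r.read_id for r in d2}

    def test_uniform_error_free_templates_survive(self, rng):
        templates = [random_dna(rng, 40) for _ in range(10)]
        reads = [
            ReadRecord("S", f"S_{i}", templates[i % 10]) for i in range(500)
        ]
        kc = build_kmer_counter(reads, k=8)
        kept, discarded = denoise_reads(reads, kc, 1.0 / (10 * 2))
        assert discarded == []


class TestWriteFiltered:
    def test_round_trip(self, rng, tmp_path):
        reads = [
            ReadRecord(f"S{rng.integers(1, 3)}", f"r{i}", random_dna(rng, 12))
            for i in range(200)
        ]
        d, _ = run_filter(reads, FilterConfig(d_level=1))
        write_filtered(d, FilterConfig(), tmp_path / "f.fna", tmp_path / "d.tsv")
        d2 = read_dictionary(tmp_path / "d.tsv")
        assert as_mapping(d2) == as_mapping(d)
        assert [e.tag for e in d2] == [str(i) for i in range(len(d))]

    def test_fasta_reverse_complemented_when_configured(self, tmp_path):
        d = DedupDictionary([DedupEntry("", "AACG", {"S1": 1})])
        cfg = FilterConfig(reverse_complement=True)
        write_filtered(d, cfg, tmp_path / "f.fna", tmp_path / "d.tsv")
        lines = (tmp_path / "f.fna").read_text().splitlines()
        assert lines == [">0", "CGTT"]
        # dictionary keeps input orientation
        assert (tmp_path / "d.tsv").read_text().split("\t")[1] == "AACG"

    def test_record_count_matches_entries(self, tmp_path):
        d = DedupDictionary(
            [DedupEntry("", s, {"S1": 1}) for s in ["AAA", "CCC", "GGG"]]
        )
        write_filtered(d, FilterConfig(), tmp_path / "f.fna", tmp_path / "d.tsv")
        assert (tmp_path / "f.fna").read_text().count(">") == 3
        assert len((tmp_path / "d.tsv").read_text().splitlines()) == 3


class TestRunFilter:
    def test_lossless_conservation(self, clean_dataset, tmp_path):
        path = tmp_path / "reads.fna"
        path.write_text(clean_dataset.reads_fasta())
        reads = parse_reads(str(path))
        d, summary = run_filter(reads, FilterConfig(d_level=1))
        assert d.total_count == len(reads) == summary.reads_in

    def test_trim_applied_before_dedup(self):
        reads = [
            ReadRecord("S1", "S1_0", "ACGTAAAA"),
            ReadRecord("S1", "S1_1", "ACGTCCCC"),
        ]
        d, _ = run_filter(reads, FilterConfig(trim_length=4, d_level=0))
        assert as_mapping(d) == {"ACGT": {"S1": 2}}
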