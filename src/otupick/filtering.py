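"""Read filtering: parsing, trimming, deduplication, compaction and denoising.

Amplicon datasets are dominated by duplicate reads, so the pipeline collapses
identical (and prefix-contained) sequences into unique representatives before
alignment while a *sample dictionary* retains per-sample multiplicities —
deduplication is lossless.  Two optional lossy denoisers remove probable
error reads: count-based filtering (drop sequences seen fewer than d-1 times)
and k-mer-spectrum filtering (drop reads containing a k-mer rarer than an
empirical prevalence threshold).
"""

from __future__ import annotations

import bisect
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

# IUPAC complement table; reverse-complement must handle ambiguity codes.
_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class ReadRecord:
    sample_id: str
    read_id: str
    sequence: str


@dataclass
class DedupEntry:
    tag: str
    sequence: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class DedupDictionary:
    """Unique-sequence → per-sample count map (the sample dictionary).

    Entries are kept in lexicographic sequence order; tags are ordinals
    assigned at write time.  The sum of all counts equals the number of
    surviving input reads, which is what makes deduplication lossless.
    """

    entries: list[DedupEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def total_count(self) -> int:
        return sum(e.total for e in self.entries)

    def by_tag(self) -> dict[str, DedupEntry]:
        return {e.tag: e for e in self.entries}

    def sample_ids(self) -> list[str]:
        ids: set[str] = set()
        for e in self.entries:
            ids.update(e.counts)
        return sorted(ids)


@dataclass(frozen=True)
class FilterConfig:
    """Knobs of the filter stage.

    d_level semantics mirror the original command-line convention:
    0 = plain dedup only; 1 = dedup + read compaction; 2 = also drop
    sequences with total count 1 (singletons); 3 = also drop doubletons; etc.
    ``denoise_fraction`` of None disables k-mer denoising (the default —
    lossy filtering is opt-in).
    """

    trim_length: Optional[int] = None
    reverse_complement: bool = False
    d_level: int = 1
    k: int = 8
    denoise_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.trim_length is not None and self.trim_length < 1:
            raise ValueError("trim_length must be >= 1")
        if self.d_level < 0:
            raise ValueError("d_level must be >= 0")
        if self.denoise_fraction is not None and not (0.0 < self.denoise_fraction < 1.0):
            raise ValueError("denoise_fraction must lie in (0, 1)")


@dataclass
class KmerCounter:
    """Counter array of length 4^k over 2-bit-encoded k-mers.

    ``counts[code]`` holds the number of occurrences of the k-mer with that
    code over all counted reads; only windows free of non-ACGT characters are
    counted.  ``n_reads`` is the number of reads profiled, which is the
    denominator of the prevalence threshold used for denoising.
    """

    k: int
    counts: np.ndarray
    total_kmers: int = 0
    n_reads: int = 0

    @classmethod
    def empty(cls, k: int) -> "KmerCounter":
        if not (1 <= k <= 14):
            raise ValueError("k must lie in [1, 14]")
        return cls(k=k, counts=np.zeros(4**k, dtype=np.int64))


def parse_reads(fasta_source: Union[str, Path, io.TextIOBase]) -> list[ReadRecord]:
    """Parse demultiplexed amplicon reads from FASTA.

    The sample id is the portion of the record id before the LAST underscore
    (demultiplexed convention ``SampleID_ReadNumber``); a header with no
    underscore is used whole as the sample id, with a warning.  Records with
    empty sequences are skipped with a warning.
    """
    records = []
    for rec in SeqIO.parse(fasta_source, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            log.warning("skipping read %r: empty sequence", rec.id)
            continue
        if "_" in rec.id:
            sample_id = rec.id.rsplit("_", 1)[0]
        else:
            log.warning("read id %r has no underscore; using it whole as sample id", rec.id)
            sample_id = rec.id
        records.append(ReadRecord(sample_id=sample_id, read_id=rec.id, sequence=seq))
    return records


def trim_read(seq: str, trim_length: int) -> str:
    """Keep the first ``trim_length`` bases (no-op on shorter reads)."""
    if trim_length < 1:
        raise ValueError("trim_length must be >= 1")
    return seq[:trim_length]


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    bad = set(seq.upper()) - set("ACGTNRYSWKMBDHV")
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def deduplicate(reads: Iterable[ReadRecord], config: Optional[FilterConfig] = None) -> DedupDictionary:
    """Collapse identical sequences, tallying per-sample multiplicity.

    Output entries are ordered lexicographically by sequence; reads are
    assumed already trimmed per the configuration.
    """
    table: dict[str, dict[str, int]] = {}
    for r in reads:
        counts = table.setdefault(r.sequence, {})
        counts[r.sample_id] = counts.get(r.sample_id, 0) + 1
    entries = [
        DedupEntry(tag="", sequence=seq, counts=table[seq]) for seq in sorted(table)
    ]
    return DedupDictionary(entries=entries)


def compact_reads(d: DedupDictionary) -> DedupDictionary:
    """Merge entries that are prefixes of longer entries into their container.

    Amplicon reads start at a common primer site, so a shorter read that is a
    prefix of a longer one is treated as a truncated copy of it; its counts
    are added to the longest containing entry (chains merge transitively).
    Entries remain lexicographically ordered.
    """
    seqs = [e.sequence for e in d.entries]
    # Lexicographic order places every prefix immediately before its
    # extensions, but the *longest* container of seqs[i] need not be adjacent;
    # scan each entry's lexicographic successors for the longest extension.
    target: dict[int, int] = {}
    # candidates sorted lexicographically allow a scan for extensions
    lex = sorted(range(len(seqs)), key=lambda i: seqs[i])
    lex_seqs = [seqs[i] for i in lex]
    for i in range(len(seqs)):
        s = seqs[i]
        # find the longest entry having s as a proper prefix
        lo = bisect.bisect_right(lex_seqs, s)
        best = -1
        best_len = len(s)
        j = lo
        while j < len(lex_seqs) and lex_seqs[j].startswith(s):
            if len(lex_seqs[j]) > best_len:
                best_len = len(lex_seqs[j])
                best = lex[j]
            j += 1
        if best >= 0:
            target[i] = best

    def resolve(i: int) -> int:
        seen = set()
        while i in target and i not in seen:
            seen.add(i)
            i = target[i]
        return i

    merged: dict[int, dict[str, int]] = {}
    for i, e in enumerate(d.entries):
        root = resolve(i)
        acc = merged.setdefault(root, {})
        for s, c in e.counts.items():
            acc[s] = acc.get(s, 0) + c
    entries = [
        DedupEntry(tag="", sequence=seqs[i], counts=merged[i])
        for i in sorted(merged, key=lambda i: seqs[i])
    ]
    return DedupDictionary(entries=entries)


def filter_by_count(d: DedupDictionary, d_level: int) -> DedupDictionary:
    """Drop entries whose total count is below ``d_level - 1``'s survival bar.

    d_level 2 removes total-count-1 entries (singletons), d_level 3 also
    removes total-count-2 entries, and so on; levels 0 and 1 are the identity
    here (they control dedup/compaction, not discarding).
    """
    if d_level <= 1:
        return DedupDictionary(entries=list(d.entries))
    return DedupDictionary(
        entries=[e for e in d.entries if e.total >= d_level]
    )


def encode_kmer(kmer: str) -> int:
    """2-bit encode a k-mer (A=00, C=01, G=10, T=11), leftmost base most significant."""
    code = 0
    for base in kmer:
        try:
            code = (code << 2) | _BASE_CODE[base]
        except KeyError:
            raise ValueError(f"non-ACGT base {base!r} in k-mer") from None
    return code


def _valid_windows(seq: str, k: int) -> Iterable[int]:
    """Yield 2-bit codes of all k-windows of ``seq`` free of non-ACGT characters."""
    n = len(seq)
    if n < k:
        return
    code = 0
    valid = 0  # run length of consecutive ACGT bases ending at current position
    mask = (1 << (2 * k)) - 1
    for ch in seq:
        b = _BASE_CODE.get(ch)
        if b is None:
            valid = 0
            code = 0
            continue
        code = ((code << 2) | b) & mask
        valid += 1
        if valid >= k:
            yield code


def build_kmer_counter(reads: Iterable[ReadRecord], k: int) -> KmerCounter:
    """Profile the empirical k-mer frequency distribution over a read set.

    Each read contributes one increment per sliding window; windows containing
    non-ACGT characters are skipped entirely.
    """
    counter = KmerCounter.empty(k)
    counts = counter.counts
    total = 0
    n_reads = 0
    for r in reads:
        n_reads += 1
        for code in _valid_windows(r.sequence, k):
            counts[code] += 1
            total += 1
    counter.total_kmers = total
    counter.n_reads = n_reads
    return counter


def denoise_reads(
    reads: Iterable[ReadRecord],
    counter: KmerCounter,
    denoise_fraction: float,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Partition reads into (kept, discarded) by k-mer prevalence.

    A read is discarded iff any of its valid k-mer windows occurs fewer than
    ``denoise_fraction * counter.n_reads`` times in the empirical spectrum —
    i.e. the k-mer appears in less than that fraction of profiled reads, the
    hallmark of a sequencing error.  Both partitions are returned so discards
    are auditable.
    """
    if not (0.0 < denoise_fraction < 1.0):
        raise ValueError("denoise_fraction must lie in (0, 1)")
    threshold = denoise_fraction * counter.n_reads
    kept: list[ReadRecord] = []
    discarded: list[ReadRecord] = []
    for r in reads:
        if any(counter.counts[code] < threshold for code in _valid_windows(r.sequence, counter.k)):
            discarded.append(r)
        else:
            kept.append(r)
    return kept, discarded


def assign_tags(d: DedupDictionary) -> DedupDictionary:
    """Set each entry's tag to its ordinal in output order (as written to FASTA)."""
    for i, e in enumerate(d.entries):
        e.tag = str(i)
    return d


def write_filtered(
    d: DedupDictionary,
    config: FilterConfig,
    fasta_path: Union[str, Path],
    dict_path: Union[str, Path],
) -> None:
    """Write the filtered FASTA (one record per entry, header = ordinal tag)
    and the sample dictionary TSV (tag, sequence, sample:count pairs).

    Reverse-complement, when configured, is applied to the FASTA output only;
    dictionary sequences stay in input orientation.
    """
    assign_tags(d)
    with open(fasta_path, "w") as fh:
        for e in d.entries:
            seq = reverse_complement(e.sequence) if config.reverse_complement else e.sequence
            fh.write(f">{e.tag}\n{seq}\n")
    with open(dict_path, "w") as fh:
        for e in d.entries:
            pairs = "\t".join(
                f"{sample}:{count}" for sample, count in sorted(e.counts.items())
            )
            fh.write(f"{e.tag}\t{e.sequence}\t{pairs}\n")


def read_dictionary(dict_path: Union[str, Path]) -> DedupDictionary:
    """Read a sample dictionary TSV written by :func:`write_filtered`."""
    entries = []
    with open(dict_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tag, seq = fields[0], fields[1]
            counts = {}
            for pair in fields[2:]:
                sample, count = pair.rsplit(":", 1)
                counts[sample] = int(count)
            entries.append(DedupEntry(tag=tag, sequence=seq, counts=counts))
    return DedupDictionary(entries=entries)


@dataclass
class FilterSummary:
    reads_in: int = 0
    reads_denoised: int = 0
    unique_sequences: int = 0
    entries_compacted: int = 0
    entries_count_filtered: int = 0
    reads_out: int = 0


def run_filter(
    reads: list[ReadRecord], config: FilterConfig
) -> tuple[DedupDictionary, FilterSummary]:
    """Apply the full filter stage in order: trim → k-mer denoise → dedup →
    compaction → count filtering.  Returns the surviving dictionary and a
    stage summary."""
    summary = FilterSummary(reads_in=len(reads))
    if config.trim_length is not None:
        reads = [
            ReadRecord(r.sample_id, r.read_id, trim_read(r.sequence, config.trim_length))
            for r in reads
        ]
    if config.denoise_fraction is not None:
        counter = build_kmer_counter(reads, config.k)
        reads, discarded = denoise_reads(reads, counter, config.denoise_fraction)
        summary.reads_denoised = len(discarded)
    d = deduplicate(reads, config)
    summary.unique_sequences = len(d)
    if config.d_level >= 1:
        before = len(d)
        d = compact_reads(d)
        summary.entries_compacted = before - len(d)
    if config.d_level >= 2:
        before = len(d)
        d = filter_by_count(d, config.d_level)
        summary.entries_count_filtered = before - len(d)
    assign_tags(d)
    summary.reads_out = d.total_count
    return d, summary
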