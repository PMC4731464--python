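"""Synthetic marker-gene references and multi-sample amplicon reads.

Everything the pipeline consumes can be generated here with a fixed seed, so
tests and examples need no downloads.  References are random sequences
rejection-sampled to be pairwise well below the 97% identity threshold, so
closed-reference assignment has an unambiguous ground truth; reads are
amplicon-like prefixes of a reference (uniform start at the primer site) with
optional substitution and indel errors at flat per-base rates.  A manifest
records every read's sample, true reference and introduced edits.

A shotgun mode draws reads from random concatesome positions purely to
manufacture junction-spanning alignments for boundary testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .concatesome import ReferenceSet

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults emulate a small 16S-like experiment: a handful of reference
    genes at amplicon-region scale (400-500 bp), a few samples with a
    geometric abundance profile over references, 150 bp error-free reads.
    """

    n_references: int = 5
    reference_length: tuple[int, int] = (400, 500)
    n_samples: int = 3
    reads_per_sample: int = 100
    read_length: int = 150
    abundance_geometric_p: float = 0.5
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    trim_length_jitter: int = 0  # uniform shortening of reads by up to this many bases
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_references < 1 or self.n_samples < 1:
            raise ValueError("need at least one reference and one sample")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


@dataclass
class SimulatedDataset:
    references: ReferenceSet
    reads: list[tuple[str, str]]  # (read_id, sequence); id = "<sample>_<n>"
    taxonomy: dict[str, str]
    manifest: list[dict]

    def reads_fasta(self) -> str:
        return "".join(f">{rid}\n{seq}\n" for rid, seq in self.reads)

    def references_fasta(self) -> str:
        return "".join(f">{oid}\n{seq}\n" for oid, seq in self.references)

    def taxonomy_tsv(self) -> str:
        return "".join(f"{oid}\t{tax}\n" for oid, tax in self.taxonomy.items())

    def true_counts(self) -> dict[tuple[str, str], int]:
        """Ground-truth (otu_id, sample_id) → read count from the manifest."""
        out: dict[tuple[str, str], int] = {}
        for rec in self.manifest:
            key = (rec["reference"], rec["sample"])
            out[key] = out.get(key, 0) + 1
        return out

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "refs.fna").write_text(self.references_fasta())
        (out / "reads.fna").write_text(self.reads_fasta())
        (out / "taxonomy.tsv").write_text(self.taxonomy_tsv())
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1) + "\n")


_TAX_RANKS = ["k__Bacteria", "p__Phylum{i}", "c__Class{i}", "o__Order{i}",
              "f__Family{i}", "g__Genus{i}", "s__species{i}"]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _identity_upper_bound(a: str, b: str) -> float:
    """Cheap upper screen on pairwise identity: shared 12-mer fraction.

    Random sequences share essentially no 12-mers, so this screen almost
    never fires; two near-identical sequences share most of theirs.
    """
    k = 12
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return len(ka & kb) / min(len(ka), len(kb))


def simulate(spec: SimulationSpec) -> SimulatedDataset:
    """Generate (references, reads, taxonomy, manifest) per the spec.

    References are rejection-sampled until pairwise dissimilar (shared-12-mer
    screen far below what 97% identity would require); an error is raised
    after a bounded number of attempts.  Reads are sampled per sample from a
    geometric abundance profile over references, taken as reference prefixes,
    then mutated at the configured substitution/indel rates.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.reference_length
    refs: list[tuple[str, str]] = []
    attempts = 0
    while len(refs) < spec.n_references:
        attempts += 1
        if attempts > 50 * spec.n_references:
            raise RuntimeError(
                "could not sample sufficiently distinct references; "
                "loosen reference_length or reduce n_references"
            )
        length = int(rng.integers(lo, hi + 1))
        cand = _random_sequence(rng, length)
        if all(_identity_upper_bound(cand, s) < 0.5 for _, s in refs):
            refs.append((f"OTU{len(refs) + 1}", cand))
    references = ReferenceSet(tuple(refs))

    taxonomy = {
        oid: "; ".join(rank.format(i=i + 1) for rank in _TAX_RANKS)
        for i, (oid, _) in enumerate(refs)
    }

    # geometric abundance over references, renormalized, ref order shuffled per sample
    p = spec.abundance_geometric_p
    base_weights = np.array([p * (1 - p) ** i for i in range(spec.n_references)])
    reads: list[tuple[str, str]] = []
    manifest: list[dict] = []
    for s in range(spec.n_samples):
        sample = f"S{s + 1}"
        order = rng.permutation(spec.n_references)
        weights = base_weights[np.argsort(order)]
        weights = weights / weights.sum()
        choices = rng.choice(spec.n_references, size=spec.reads_per_sample, p=weights)
        for n, ref_i in enumerate(choices):
            oid, ref_seq = refs[ref_i]
            length = spec.read_length
            if spec.trim_length_jitter:
                length -= int(rng.integers(0, spec.trim_length_jitter + 1))
            length = min(length, len(ref_seq))
            seq = ref_seq[:length]
            seq, edits = _mutate(rng, seq, spec.substitution_rate, spec.indel_rate)
            rid = f"{sample}_{n}"
            reads.append((rid, seq))
            manifest.append(
                {
                    "read_id": rid,
                    "sample": sample,
                    "reference": oid,
                    "length": len(seq),
                    **edits,
                }
            )
    return SimulatedDataset(
        references=references, reads=reads, taxonomy=taxonomy, manifest=manifest
    )


def simulate_shotgun_reads(
    concat_sequence: str,
    n_reads: int,
    read_length: int,
    seed: int = 0,
    sample: str = "S1",
) -> list[tuple[str, str, int]]:
    """Reads from uniform random concatesome positions: (read_id, sequence, start).

    Exists only to manufacture junction-spanning alignments for boundary
    tests; real amplicon data is emulated by :func:`simulate`.
    """
    rng = np.random.default_rng(seed)
    out = []
    hi = len(concat_sequence) - read_length
    if hi < 0:
        raise ValueError("read_length exceeds concatesome length")
    for n in range(n_reads):
        start = int(rng.integers(0, hi + 1))
        out.append((f"{sample}_{n}", concat_sequence[start : start + read_length], start))
    return out


def _mutate(
    rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float
) -> tuple[str, dict]:
    """Apply flat per-base substitution and indel errors; returns (sequence, edit tally)."""
    n_sub = n_ins = n_del = 0
    if sub_rate > 0.0:
        chars = list(seq)
        hits = np.nonzero(rng.random(len(chars)) < sub_rate)[0]
        for i in hits:
            old = chars[i]
            alternatives = [b for b in "ACGT" if b != old]
            chars[i] = alternatives[int(rng.integers(0, 3))]
            n_sub += 1
        seq = "".join(chars)
    if indel_rate > 0.0:
        out = []
        for ch in seq:
            r = rng.random()
            if r < indel_rate / 2:
                n_del += 1
                continue  # deletion
            out.append(ch)
            if indel_rate / 2 <= r < indel_rate:
                out.append(str(_BASES[int(rng.integers(0, 4))]))
                n_ins += 1
        seq = "".join(out)
    return seq, {"n_sub": n_sub, "n_ins": n_ins, "n_del": n_del}
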