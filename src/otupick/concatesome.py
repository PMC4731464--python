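"""Concatenated reference chromosome ("concatesome") construction and coordinate resolution.

Closed-reference OTU picking against a Burrows-Wheeler index requires a single
reference text.  All marker-gene references are therefore joined end to end,
with no separator characters, and an offset index records where each gene
starts so alignment coordinates can be mapped back to OTU identities.  A hit
whose aligned span crosses the boundary between two concatenated genes is
biologically meaningless and is rejected as a *junction* hit.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

# Upper-case IUPAC nucleotide codes accepted in reference sequences.
IUPAC_DNA = set("ACGTNRYSWKMBDHV")


class JunctionError(ValueError):
    """An alignment extends across the boundary between two concatenated references."""


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered collection of (otu_id, sequence) marker-gene references.

    Sequences are upper-cased on construction; ids must be unique and
    non-empty and sequences non-empty over the IUPAC DNA alphabet.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        norm = []
        for otu_id, seq in self.entries:
            if not otu_id:
                raise ValueError("reference with empty otu_id")
            if otu_id in seen:
                raise ValueError(f"duplicate otu_id: {otu_id!r}")
            seen.add(otu_id)
            seq = seq.upper()
            if not seq:
                raise ValueError(f"reference {otu_id!r} has an empty sequence")
            bad = set(seq) - IUPAC_DNA
            if bad:
                raise ValueError(
                    f"reference {otu_id!r} contains non-IUPAC characters: {sorted(bad)}"
                )
            norm.append((otu_id, seq))
        object.__setattr__(self, "entries", tuple(norm))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "ReferenceSet":
        """Read references from multi-FASTA; the first whitespace token of each header is the OTU id."""
        entries = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not entries:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(tuple(entries))


@dataclass(frozen=True)
class Concatesome:
    """The concatenated reference string plus the offset index back to OTUs.

    ``offsets[i]`` is the 0-based start of reference ``i`` in ``sequence``;
    slicing at ``[offsets[i], offsets[i+1])`` recovers reference ``i`` exactly.
    """

    sequence: str
    offsets: tuple[int, ...]
    otu_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty concatesome sequence")
        if len(self.offsets) != len(self.otu_ids):
            raise ValueError("offsets and otu_ids lengths differ")
        if not self.offsets or self.offsets[0] != 0:
            raise ValueError("offsets must start at 0")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("offsets must be strictly increasing")
        if self.offsets[-1] >= len(self.sequence):
            raise ValueError("last offset beyond sequence end")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_references(self) -> int:
        return len(self.offsets)

    def reference_bounds(self, i: int) -> tuple[int, int]:
        """Half-open [start, end) interval of reference ``i`` in the concatesome."""
        start = self.offsets[i]
        end = self.offsets[i + 1] if i + 1 < len(self.offsets) else len(self.sequence)
        return start, end

    def reference_sequence(self, i: int) -> str:
        start, end = self.reference_bounds(i)
        return self.sequence[start:end]


def build_concatesome(refs: ReferenceSet) -> Concatesome:
    """Join references into one long sequence, recording each OTU's start offset."""
    if len(refs) == 0:
        raise ValueError("cannot build a concatesome from an empty reference set")
    offsets = []
    parts = []
    pos = 0
    for _, seq in refs:
        offsets.append(pos)
        parts.append(seq)
        pos += len(seq)
    return Concatesome(
        sequence="".join(parts),
        offsets=tuple(offsets),
        otu_ids=tuple(otu_id for otu_id, _ in refs),
    )


def write_concatesome(
    c: Concatesome, fasta_path: Union[str, Path], index_path: Union[str, Path]
) -> None:
    """Write the concatesome as a single-record single-line FASTA plus a TSV offset index.

    The FASTA sequence is deliberately unwrapped: downstream BWT database
    builders and the coordinate arithmetic both assume one record on one line.
    The index is two columns, ``otu_id<TAB>start_offset``, in concatesome order.
    """
    with open(fasta_path, "w") as fh:
        fh.write(">concatesome\n")
        fh.write(c.sequence)
        fh.write("\n")
    with open(index_path, "w") as fh:
        for otu_id, off in zip(c.otu_ids, c.offsets):
            fh.write(f"{otu_id}\t{off}\n")


def read_concatesome(
    fasta_path: Union[str, Path], index_path: Union[str, Path]
) -> Concatesome:
    """Inverse of :func:`write_concatesome`."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"concatesome FASTA must hold exactly one record, found {len(records)}"
        )
    otu_ids: list[str] = []
    offsets: list[int] = []
    with open(index_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            otu_id, off = line.split("\t")
            otu_ids.append(otu_id)
            offsets.append(int(off))
    return Concatesome(
        sequence=str(records[0].seq), offsets=tuple(offsets), otu_ids=tuple(otu_ids)
    )


def locate_hit(c: Concatesome, start: int, ref_span: int) -> str:
    """Map a concatesome alignment interval back to its OTU id.

    ``start`` is 0-based and ``ref_span`` the number of reference bases the
    alignment consumes, so the alignment covers the half-open interval
    ``[start, start + ref_span)``.  If that interval extends past the start of
    the following reference the hit spans a junction between two concatenated
    genes and :class:`JunctionError` is raised; an alignment ending flush at
    the boundary (end == next start) is a legitimate full-length match and is
    kept.
    """
    if ref_span <= 0:
        raise ValueError(f"ref_span must be positive, got {ref_span}")
    if start < 0 or start + ref_span > len(c.sequence):
        raise ValueError(
            f"interval [{start}, {start + ref_span}) outside concatesome of length {len(c.sequence)}"
        )
    i = bisect.bisect_right(c.offsets, start) - 1
    end = start + ref_span
    if i + 1 < len(c.offsets) and end > c.offsets[i + 1]:
        raise JunctionError(
            f"alignment [{start}, {end}) crosses the junction at {c.offsets[i + 1]}"
        )
    return c.otu_ids[i]
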