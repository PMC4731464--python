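"""Parsing stage: SAM → taxonomy-annotated sample-by-OTU table.

Consumes the (headerless) SAM produced by the aligner, the sample dictionary
from the filter stage and an optional OTU-to-taxonomy map; resolves each
alignment to an OTU through the concatesome offset index (discarding junction
hits), expands the deduplicated read back into its per-sample multiplicities,
and writes the resulting sparse count table as BIOM 1.0 JSON or legacy
tab-delimited format.
"""

from __future__ import annotations

import datetime
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .aligner import AlignmentHit
from .concatesome import Concatesome, JunctionError, locate_hit
from .filtering import DedupDictionary

log = logging.getLogger(__name__)

UNANNOTATED = "Unassigned"

# CIGAR operations that consume reference bases
_REF_CONSUMING = set("M=XDN")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class TaxonomyMap:
    """otu_id → semicolon-delimited taxonomy string; absent ids are 'Unassigned'."""

    mapping: dict[str, str]

    def lookup(self, otu_id: str) -> str:
        return self.mapping.get(otu_id, UNANNOTATED)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "TaxonomyMap":
        mapping = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                otu_id, tax = line.split("\t", 1)
                mapping[otu_id] = tax
        return cls(mapping)


@dataclass
class OtuTable:
    """Sparse OTU × sample count table with optional per-OTU taxonomy."""

    otu_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    taxonomy: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.counts.values()):
            raise ValueError("stored counts must be >= 1 (no explicit zeros)")
        if self.taxonomy is not None and len(self.taxonomy) != len(self.otu_ids):
            raise ValueError("taxonomy list must parallel otu_ids")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.otu_ids), len(self.sample_ids))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_dense(self) -> list[list[int]]:
        n_r, n_c = self.shape
        dense = [[0] * n_c for _ in range(n_r)]
        for (r, c), v in self.counts.items():
            dense[r][c] = v
        return dense

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and self.counts == other.counts
            and self.taxonomy == other.taxonomy
        )


def ref_span_from_cigar(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string (M, =, X, D, N consume)."""
    if cigar == "*" or not cigar:
        return 0
    span = 0
    parsed = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in parsed) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    for n, op in parsed:
        if op in _REF_CONSUMING:
            span += int(n)
    return span


def parse_sam(sam_source: Union[str, Path, Iterable[str]]) -> list[AlignmentHit]:
    """Parse (headerless) SAM lines into alignment hits.

    POS is converted from SAM's 1-based convention to 0-based here — the
    single conversion point in the pipeline.  Unmapped records (FLAG bit 4 or
    RNAME '*') are skipped silently; unparseable lines are skipped with a
    counted warning.  Header lines ('@'), if present, are tolerated.
    """
    if isinstance(sam_source, (str, Path)):
        with open(sam_source) as fh:
            return parse_sam(list(fh))
    hits: list[AlignmentHit] = []
    bad = 0
    for line in sam_source:
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        try:
            qname = fields[0]
            flag = int(fields[1])
            rname = fields[2]
            pos = int(fields[3])
            cigar = fields[5]
        except (IndexError, ValueError):
            bad += 1
            continue
        if flag & 4 or rname == "*":
            continue
        try:
            span = ref_span_from_cigar(cigar)
        except ValueError:
            bad += 1
            continue
        if span == 0:
            bad += 1
            continue
        hits.append(
            AlignmentHit(
                query_tag=qname,
                concat_start=pos - 1,
                ref_span=span,
                cigar=cigar,
                identity=float("nan"),
            )
        )
    if bad:
        log.warning("skipped %d unparseable SAM line(s)", bad)
    return hits


@dataclass
class ParseSummary:
    hits_in: int = 0
    junction_hits: int = 0
    junction_reads: int = 0  # expanded read count carried by junction hits
    duplicate_tag_hits: int = 0
    matched_reads: int = 0

    @property
    def junction_fraction(self) -> float:
        return self.junction_hits / self.hits_in if self.hits_in else 0.0


def assemble_table(
    hits: Iterable[AlignmentHit],
    c: Concatesome,
    dictionary: DedupDictionary,
    tax: Optional[TaxonomyMap] = None,
    summary: Optional[ParseSummary] = None,
) -> OtuTable:
    """Bin alignment hits into a sample-by-OTU count table.

    Each surviving hit contributes its dictionary entry's FULL per-sample
    counts (the dedup expansion).  Junction hits are dropped and counted.
    Rows are ordered by first appearance in the hit stream, columns by sorted
    sample id over the whole dictionary.  A hit whose tag is missing from the
    dictionary indicates a pipeline inconsistency and raises KeyError; a
    second hit for an already-binned tag is ignored with a warning (first-hit
    semantics).
    """
    if summary is None:
        summary = ParseSummary()
    by_tag = dictionary.by_tag()
    sample_ids = dictionary.sample_ids()
    col = {s: i for i, s in enumerate(sample_ids)}
    otu_ids: list[str] = []
    row: dict[str, int] = {}
    counts: dict[tuple[int, int], int] = {}
    seen_tags: set[str] = set()
    for hit in hits:
        summary.hits_in += 1
        if hit.query_tag not in by_tag:
            raise KeyError(
                f"alignment tag {hit.query_tag!r} not present in the sample dictionary"
            )
        if hit.query_tag in seen_tags:
            summary.duplicate_tag_hits += 1
            log.warning("extra alignment for tag %r ignored (first hit wins)", hit.query_tag)
            continue
        entry = by_tag[hit.query_tag]
        try:
            otu_id = locate_hit(c, hit.concat_start, hit.ref_span)
        except JunctionError:
            summary.junction_hits += 1
            summary.junction_reads += entry.total
            seen_tags.add(hit.query_tag)
            continue
        seen_tags.add(hit.query_tag)
        if otu_id not in row:
            row[otu_id] = len(otu_ids)
            otu_ids.append(otu_id)
        r = row[otu_id]
        for sample, n in entry.counts.items():
            key = (r, col[sample])
            counts[key] = counts.get(key, 0) + n
            summary.matched_reads += n
    taxonomy = [tax.lookup(o) for o in otu_ids] if tax is not None else None
    return OtuTable(
        otu_ids=otu_ids, sample_ids=sample_ids, counts=counts, taxonomy=taxonomy
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

BIOM_FORMAT = "Biological Observation Matrix 1.0.0"
BIOM_FORMAT_URL = "http://biom-format.org"


def write_biom(
    t: OtuTable, path: Union[str, Path], generated_by: str = "otupick", date: Optional[str] = None
) -> None:
    """Write the table as a sparse BIOM 1.0 JSON document.

    ``date`` may be pinned for byte-reproducible output; it defaults to now.
    """
    doc = {
        "id": None,
        "format": BIOM_FORMAT,
        "format_url": BIOM_FORMAT_URL,
        "type": "OTU table",
        "generated_by": generated_by,
        "date": date or datetime.datetime.now().isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(t.shape),
        "rows": [
            {
                "id": otu_id,
                "metadata": (
                    {"taxonomy": t.taxonomy[i].split("; ")} if t.taxonomy else None
                ),
            }
            for i, otu_id in enumerate(t.otu_ids)
        ],
        "columns": [{"id": s, "metadata": None} for s in t.sample_ids],
        "data": [
            [r, c, v] for (r, c), v in sorted(t.counts.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def read_biom(path: Union[str, Path]) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "sparse":
        raise ValueError("only sparse BIOM 1.0 documents are supported")
    otu_ids = [r["id"] for r in doc["rows"]]
    has_tax = any(r.get("metadata") and "taxonomy" in r["metadata"] for r in doc["rows"])
    taxonomy = (
        [
            "; ".join(r["metadata"]["taxonomy"]) if r.get("metadata") else UNANNOTATED
            for r in doc["rows"]
        ]
        if has_tax
        else None
    )
    sample_ids = [c["id"] for c in doc["columns"]]
    counts = {(r, c): v for r, c, v in doc["data"]}
    return OtuTable(otu_ids=otu_ids, sample_ids=sample_ids, counts=counts, taxonomy=taxonomy)


def write_legacy(t: OtuTable, path: Union[str, Path]) -> None:
    """Write the table in legacy tab-delimited format (dense counts, '#OTU ID' header)."""
    with open(path, "w") as fh:
        header = ["#OTU ID"] + list(t.sample_ids)
        if t.taxonomy is not None:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        dense = t.to_dense()
        for i, otu_id in enumerate(t.otu_ids):
            fields = [otu_id] + [str(v) for v in dense[i]]
            if t.taxonomy is not None:
                fields.append(t.taxonomy[i])
            fh.write("\t".join(fields) + "\n")


def read_legacy(path: Union[str, Path]) -> OtuTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.rstrip("\n")]
    if not lines or not lines[0].startswith("#OTU ID"):
        raise ValueError("not a legacy OTU table (missing '#OTU ID' header)")
    header = lines[0].split("\t")
    has_tax = header[-1] == "taxonomy"
    sample_ids = header[1 : -1 if has_tax else len(header)]
    otu_ids: list[str] = []
    taxonomy: list[str] = []
    counts: dict[tuple[int, int], int] = {}
    for r, line in enumerate(lines[1:]):
        fields = line.split("\t")
        otu_ids.append(fields[0])
        values = fields[1 : 1 + len(sample_ids)]
        if has_tax:
            taxonomy.append(fields[1 + len(sample_ids)])
        for ci, v in enumerate(values):
            iv = int(v)
            if iv:
                counts[(r, ci)] = iv
    return OtuTable(
        otu_ids=otu_ids,
        sample_ids=sample_ids,
        counts=counts,
        taxonomy=taxonomy if has_tax else None,
    )


def collect_unmatched(
    dictionary: DedupDictionary,
    hits: Iterable[AlignmentHit],
    path: Union[str, Path],
) -> list[str]:
    """Write dictionary sequences the aligner reported no hit for to a FASTA file.

    Junction-rejected entries are not written here: they are accounted for by
    the junction statistics, keeping matched / junction-dropped / unmatched a
    disjoint partition of the dictionary.  Returns the list of unmatched tags.
    """
    matched = {hit.query_tag for hit in hits}
    unmatched = [e.tag for e in dictionary if e.tag not in matched]
    by_tag = dictionary.by_tag()
    with open(path, "w") as fh:
        for tag in unmatched:
            fh.write(f">{tag}\n{by_tag[tag].sequence}\n")
    return unmatched
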