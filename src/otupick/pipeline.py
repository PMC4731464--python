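"""One-command orchestration: prep → filter → align → parse.

The pipeline reads a multi-FASTA of marker-gene references and a FASTA of
demultiplexed amplicon reads, builds the concatesome, filters and
deduplicates the reads, aligns the surviving unique sequences (embedded
FM-index aligner, or a user-supplied SAM from an external BWT aligner), and
writes a taxonomy-annotated OTU table.  All intermediate files land in the
output directory so every stage is auditable, and identical inputs plus
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import aligner as _aligner
from . import concatesome as _concat
from . import filtering as _filter
from . import parse as _parse

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    refs_path: Union[str, Path]
    reads_path: Union[str, Path]
    out_dir: Union[str, Path]
    taxonomy_path: Optional[Union[str, Path]] = None
    filter_config: _filter.FilterConfig = field(default_factory=_filter.FilterConfig)
    min_identity: float = 0.97
    preset: str = "default"
    external_sam: Optional[Union[str, Path]] = None  # skip embedded alignment
    output_format: str = "biom"  # or "legacy"
    write_unmatched: bool = False
    biom_date: Optional[str] = None  # pin for byte-reproducible output

    def __post_init__(self) -> None:
        if self.preset not in ("fast", "default", "max"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.output_format not in ("biom", "legacy"):
            raise ValueError(f"unknown output format {self.output_format!r}")
        _aligner.ScoringContract(min_identity=self.min_identity)  # validate


@dataclass
class RunSummary:
    reads_in: int = 0
    reads_denoised: int = 0
    duplicates_removed: int = 0
    unique_aligned_queries: int = 0
    reads_aligned: int = 0
    junction_hits: int = 0
    junction_reads: int = 0
    unmatched_entries: int = 0
    otus_observed: int = 0
    table_total: int = 0
    stage_seconds: dict[str, float] = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> RunSummary:
    """Run all stages; outputs are written into ``cfg.out_dir``.

    Produces: ``concatesome.fna`` + ``concatesome.idx``, ``filtered.fna`` +
    ``samples.tsv``, ``hits.sam`` (embedded mode), ``table.biom`` or
    ``table.txt``, and optionally ``unmatched.fna``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = RunSummary()

    # --- prep ---
    t0 = time.perf_counter()
    refs = _concat.ReferenceSet.from_fasta(cfg.refs_path)
    c = _concat.build_concatesome(refs)
    _concat.write_concatesome(c, out / "concatesome.fna", out / "concatesome.idx")
    summary.stage_seconds["prep"] = time.perf_counter() - t0
    log.info("prep: %d references, concatesome length %d", len(refs), len(c))

    # --- filter ---
    t0 = time.perf_counter()
    reads = _filter.parse_reads(str(cfg.reads_path))
    dictionary, fsum = _filter.run_filter(reads, cfg.filter_config)
    _filter.write_filtered(
        dictionary, cfg.filter_config, out / "filtered.fna", out / "samples.tsv"
    )
    summary.reads_in = fsum.reads_in
    summary.reads_denoised = fsum.reads_denoised
    summary.duplicates_removed = fsum.reads_in - fsum.reads_denoised - len(dictionary)
    summary.stage_seconds["filter"] = time.perf_counter() - t0
    log.info(
        "filter: %d reads in, %d denoised, %d unique sequences out",
        fsum.reads_in, fsum.reads_denoised, len(dictionary),
    )

    # --- align ---
    t0 = time.perf_counter()
    if cfg.external_sam is not None:
        hits = _parse.parse_sam(cfg.external_sam)
    else:
        idx = _aligner.build_fm_index(c)
        contract = _aligner.ScoringContract(min_identity=cfg.min_identity)
        hits = []
        for entry in dictionary:
            hit = _aligner.align_read(
                idx, c, entry.sequence, contract, effort=cfg.preset, query_tag=entry.tag
            )
            if hit is not None:
                hits.append(hit)
        write_sam(hits, out / "hits.sam")
    summary.unique_aligned_queries = len(hits)
    summary.stage_seconds["align"] = time.perf_counter() - t0
    log.info("align: %d of %d unique sequences hit", len(hits), len(dictionary))

    # --- parse ---
    t0 = time.perf_counter()
    tax = (
        _parse.TaxonomyMap.from_tsv(cfg.taxonomy_path)
        if cfg.taxonomy_path is not None
        else None
    )
    psum = _parse.ParseSummary()
    table = _parse.assemble_table(hits, c, dictionary, tax, summary=psum)
    if cfg.output_format == "biom":
        _parse.write_biom(table, out / "table.biom", date=cfg.biom_date)
    else:
        _parse.write_legacy(table, out / "table.txt")
    if cfg.write_unmatched:
        unmatched = _parse.collect_unmatched(dictionary, hits, out / "unmatched.fna")
        summary.unmatched_entries = len(unmatched)
    summary.reads_aligned = psum.matched_reads
    summary.junction_hits = psum.junction_hits
    summary.junction_reads = psum.junction_reads
    summary.otus_observed = len(table.otu_ids)
    summary.table_total = table.total
    summary.stage_seconds["parse"] = time.perf_counter() - t0
    log.info(
        "parse: %d OTUs, %d reads binned, %d junction hit(s) discarded (%.2g of hits)",
        summary.otus_observed, summary.table_total,
        psum.junction_hits, psum.junction_fraction,
    )
    return summary


def write_sam(hits: list[_aligner.AlignmentHit], path: Union[str, Path]) -> None:
    """Write hits as headerless SAM (mandatory 11 columns; POS 1-based)."""
    with open(path, "w") as fh:
        for h in hits:
            fields = [
                h.query_tag,
                "0",
                "concatesome",
                str(h.concat_start + 1),
                "255",
                h.cigar,
                "*", "0", "0", "*", "*",
            ]
            fh.write("\t".join(fields) + "\n")
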