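"""Alignment against the concatesome under a percent-identity criterion.

Three related pieces live here:

* an embedded FM-index (Burrows-Wheeler transform + rank structures) over the
  concatesome with exact backward search, plus a seed-and-extend aligner that
  accepts the *first* candidate meeting the minimum identity — mirroring the
  terminate-on-first-acceptable-hit behaviour of a ``-k 1`` BWT aligner;
* the exact option set for driving an external BWT aligner (bowtie2-style)
  under the same criterion, including the minimum-score function derived from
  the identity threshold as ``%ID/100 - 1``;
* the semi-global dynamic-programming scorer used both to extend seeds and as
  the accuracy oracle: the full query is aligned, gaps at the reference ends
  are free, each mismatch and each gap base costs one unit (no affine
  component), and identity is matching columns over alignment length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .concatesome import Concatesome

_ALPHABET = "$ACGT"
_CHAR_TO_CODE = {c: i for i, c in enumerate(_ALPHABET)}

# IUPAC ambiguity expansion: a reference ambiguity code matches any base it covers.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class ScoringContract:
    """The percent-identity matching criterion.

    Matches weigh 1, mismatches of any type 0, matches to ambiguous reference
    bases are not penalized, and gaps carry no affine component (every gap
    base counts equally as a non-match).  ``min_identity`` is the acceptance
    threshold on matching columns / alignment length.
    """

    min_identity: float = 0.97

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must lie in (0, 1]")


@dataclass(frozen=True)
class AlignmentHit:
    query_tag: str
    concat_start: int  # 0-based position in the concatesome
    ref_span: int  # reference bases consumed (M/=/X/D/N)
    cigar: str
    identity: float


# ---------------------------------------------------------------------------
# FM-index
# ---------------------------------------------------------------------------


@dataclass
class FmIndex:
    """FM-index over the concatesome text (terminated by '$').

    ``bwt`` is the Burrows-Wheeler transform; ``suffix_offsets`` maps BWT rows
    to text positions (kept unsampled — simplicity over memory fidelity);
    ``occ[c, i]`` counts occurrences of character code ``c`` in ``bwt[:i]``
    and ``char_starts[c]`` is the first row of the ``c`` block in the sorted
    rotation matrix.  Ambiguity codes in the concatesome are replaced by 'A'
    in the indexed text only; acceptance is always re-scored by the DP, where
    ambiguity matches are free.
    """

    bwt: str
    suffix_offsets: np.ndarray
    occ: np.ndarray
    char_starts: np.ndarray

    def __len__(self) -> int:
        return len(self.bwt)


def suffix_array(text: str) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n))."""
    n = len(text)
    rank = np.frombuffer(text.encode("ascii"), dtype=np.uint8).astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        new_rank = np.empty(n, dtype=np.int64)
        boundary = np.empty(n, dtype=np.int64)
        boundary[0] = 0
        if n > 1:
            boundary[1:] = np.cumsum(
                (rank[sa[1:]] != rank[sa[:-1]]) | (key2[sa[1:]] != key2[sa[:-1]])
            )
        new_rank[sa] = boundary
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            break
        k *= 2
    return sa


def bwt_transform(text: str) -> tuple[str, np.ndarray]:
    """Return (BWT, suffix array) of ``text + '$'``."""
    if "$" in text:
        raise ValueError("text must not contain the sentinel '$'")
    t = text + "$"
    sa = suffix_array(t)
    chars = np.frombuffer(t.encode("ascii"), dtype=np.uint8)
    bwt = chars[(sa - 1) % len(t)].tobytes().decode("ascii")
    return bwt, sa


def invert_bwt(bwt: str) -> str:
    """Reconstruct the original text from its BWT via the LF walk."""
    n = len(bwt)
    codes = np.array([_CHAR_TO_CODE[c] for c in bwt], dtype=np.int64)
    counts = np.bincount(codes, minlength=5)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    # rank of each bwt character among its equals, in order of appearance
    rank = np.zeros(n, dtype=np.int64)
    seen = np.zeros(5, dtype=np.int64)
    for i, c in enumerate(codes):
        rank[i] = seen[c]
        seen[c] += 1
    lf = starts[codes] + rank
    out = []
    row = 0  # the first sorted rotation starts with '$'
    for _ in range(n):
        out.append(bwt[row])
        row = lf[row]
    text = "".join(reversed(out))
    assert text[0] == "$"
    return text[1:]


def build_fm_index(c: Concatesome) -> FmIndex:
    """Index the concatesome for backward search.

    Non-ACGT characters (IUPAC ambiguity codes) are replaced by 'A' in the
    indexed text; the concatesome itself is untouched.
    """
    text = "".join(ch if ch in "ACGT" else "A" for ch in c.sequence)
    bwt, sa = bwt_transform(text)
    n = len(bwt)
    codes = np.array([_CHAR_TO_CODE[ch] for ch in bwt], dtype=np.int64)
    occ = np.zeros((5, n + 1), dtype=np.int64)
    for code in range(5):
        occ[code, 1:] = np.cumsum(codes == code)
    counts = np.bincount(codes, minlength=5)
    char_starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return FmIndex(bwt=bwt, suffix_offsets=sa, occ=occ, char_starts=char_starts)


def _backward_interval(
    idx: FmIndex, pattern: str, lo: Optional[int] = None, hi: Optional[int] = None
) -> tuple[int, int]:
    """Narrow the BWT row interval by prepending ``pattern`` (right to left).

    Returns an empty interval (lo >= hi) as soon as the pattern is absent.
    """
    if lo is None:
        lo, hi = 0, len(idx.bwt)
    for ch in reversed(pattern):
        code = _CHAR_TO_CODE.get(ch)
        if code is None or code == 0:
            return 0, 0
        lo = idx.char_starts[code] + idx.occ[code, lo]
        hi = idx.char_starts[code] + idx.occ[code, hi]
        if lo >= hi:
            return 0, 0
    return int(lo), int(hi)


def backward_search(idx: FmIndex, pattern: str) -> list[int]:
    """All occurrence positions of ``pattern`` in the indexed text, ascending."""
    if not pattern:
        raise ValueError("empty pattern")
    lo, hi = _backward_interval(idx, pattern)
    return sorted(int(p) for p in idx.suffix_offsets[lo:hi])


# ---------------------------------------------------------------------------
# Semi-global percent-identity dynamic programming
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SemiGlobalAlignment:
    identity: float
    cigar: str
    ref_start: int  # start of the aligned interval within the reference segment
    ref_span: int
    matches: int
    alignment_length: int
    cost: int  # mismatches + gap bases


def _bases_match(q: str, r: str) -> bool:
    return q in IUPAC_SETS.get(r, "")


def semi_global_align(query: str, reference_segment: str, contract: ScoringContract | None = None) -> SemiGlobalAlignment:
    """Optimal semi-global alignment of the full query against a reference segment.

    Gaps at the reference's ends are free; the query must be covered end to
    end.  Mismatches and interior gap bases each cost one unit; matches
    (including matches to reference ambiguity codes) cost nothing.  The
    minimum-cost alignment is recovered by traceback with the deterministic
    preference diagonal > deletion > insertion, ending at the leftmost
    minimum-cost reference column.
    """
    m, n = len(query), len(reference_segment)
    if m == 0 or n == 0:
        raise ValueError("query and reference segment must be non-empty")
    # D[i][j]: min cost of aligning query[:i] with some suffix of ref[:j]
    # (leading reference bases free).  Stored row-wise as Python lists —
    # the j-dependency of deletions defeats straight vectorization.
    prev = [0] * (n + 1)
    rows = [prev]
    for i in range(1, m + 1):
        qc = query[i - 1]
        cur = [i] + [0] * n
        pi = prev
        for j in range(1, n + 1):
            sub = pi[j - 1] + (0 if _bases_match(qc, reference_segment[j - 1]) else 1)
            ins = pi[j] + 1  # query base against a gap
            dele = cur[j - 1] + 1  # reference base against a gap
            cur[j] = sub if sub <= ins else ins
            if dele < cur[j]:
                cur[j] = dele
        rows.append(cur)
        prev = cur
    last = rows[m]
    best_cost = min(last)
    j = last.index(best_cost)  # leftmost minimum-cost end column
    # traceback
    ops: list[str] = []
    matches = 0
    i = m
    end_j = j
    while i > 0:
        sub_cost = (
            rows[i - 1][j - 1] + (0 if _bases_match(query[i - 1], reference_segment[j - 1]) else 1)
            if j > 0
            else None
        )
        if j > 0 and sub_cost == rows[i][j]:
            if _bases_match(query[i - 1], reference_segment[j - 1]):
                matches += 1
            ops.append("M")
            i -= 1
            j -= 1
        elif j > 0 and rows[i][j - 1] + 1 == rows[i][j]:
            ops.append("D")
            j -= 1
        else:
            ops.append("I")
            i -= 1
    ops.reverse()
    # trailing reference deletions before the first query base are free
    # (they were never emitted: traceback stops at i == 0, leaving [0, j) unaligned)
    alignment_length = len(ops)
    cigar = _ops_to_cigar(ops)
    ref_span = sum(1 for o in ops if o in "MD")
    return SemiGlobalAlignment(
        identity=matches / alignment_length,
        cigar=cigar,
        ref_start=end_j - ref_span,
        ref_span=ref_span,
        matches=matches,
        alignment_length=alignment_length,
        cost=best_cost,
    )


def _ops_to_cigar(ops: Sequence[str]) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def semi_global_identity(
    query: str, reference_segment: str, contract: ScoringContract | None = None
) -> tuple[float, str]:
    """Percent identity (fraction) and CIGAR of the optimal semi-global alignment."""
    aln = semi_global_align(query, reference_segment, contract)
    return aln.identity, aln.cigar


# ---------------------------------------------------------------------------
# Embedded seed-and-extend aligner
# ---------------------------------------------------------------------------

# effort presets: (number of seed anchor positions, max occurrences examined
# per seed, extra reference-window padding)
_PRESETS = {
    "fast": (1, 4, 0),
    "default": (3, 16, 2),
    "max": (6, 64, 6),
}


def align_read(
    idx: FmIndex,
    c: Concatesome,
    read: str,
    contract: ScoringContract,
    effort: str = "default",
    query_tag: str = "read",
) -> Optional[AlignmentHit]:
    """Align one read end-to-end against the concatesome; first acceptable hit wins.

    Strategy: exact match of the whole read by backward search first; on
    failure, maximal exact suffix matches ending at a few anchor positions
    serve as seeds, each extended by the semi-global DP against a bounded
    reference window.  Candidates are examined in deterministic order
    (longest seed first, then leftmost concatesome position) and the first
    meeting ``contract.min_identity`` is returned; forward strand only.
    Returns None when no candidate qualifies.
    """
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    m = len(read)
    if effort not in _PRESETS:
        raise ValueError(f"unknown effort preset {effort!r}; choose from {sorted(_PRESETS)}")
    n_anchors, max_occ, extra_pad = _PRESETS[effort]

    # exact path: a perfect full-length match always satisfies any threshold
    if set(read) <= set("ACGT"):
        positions = backward_search(idx, read)
        for p in positions:  # ascending = leftmost first
            if p + m <= len(c.sequence):
                # re-score against the true concatesome text: index text has
                # ambiguity codes collapsed, so confirm via DP when the slice
                # is not a verbatim match
                segment = c.sequence[p : p + m]
                if segment == read:
                    return AlignmentHit(query_tag, p, m, f"{m}M", 1.0)
                aln = semi_global_align(read, segment)
                if aln.identity >= contract.min_identity:
                    return AlignmentHit(
                        query_tag, p + aln.ref_start, aln.ref_span, aln.cigar, aln.identity
                    )

    # seed-and-extend path
    anchors = _anchor_ends(m, n_anchors)
    seeds = []
    for end in anchors:
        length, lo, hi = _maximal_suffix_match(idx, read, end)
        if length >= 8:  # seeds shorter than 8 bp are noise
            seeds.append((length, end, lo, hi))
    seeds.sort(key=lambda s: (-s[0], s[1]))
    pad = max(4, int(np.ceil((1.0 - contract.min_identity) * m))) + extra_pad
    tried: set[tuple[int, int]] = set()
    for length, end, lo, hi in seeds:
        s_off = end - length  # seed start within the read
        occs = sorted(int(p) for p in idx.suffix_offsets[lo:hi])[:max_occ]
        for p in occs:
            win_start = max(0, p - s_off - pad)
            win_end = min(len(c.sequence), p - s_off + m + pad)
            key = (win_start, win_end)
            if key in tried:
                continue
            tried.add(key)
            if win_end <= win_start:
                continue
            aln = semi_global_align(read, c.sequence[win_start:win_end])
            if aln.identity >= contract.min_identity:
                return AlignmentHit(
                    query_tag,
                    win_start + aln.ref_start,
                    aln.ref_span,
                    aln.cigar,
                    aln.identity,
                )
    return None


def _anchor_ends(read_length: int, n_anchors: int) -> list[int]:
    """Evenly spaced seed anchor end-positions, read end first."""
    if n_anchors <= 1 or read_length <= 16:
        return [read_length]
    lo = min(16, read_length)
    ends = np.linspace(read_length, lo, n_anchors).astype(int)
    out: list[int] = []
    for e in ends:
        if int(e) not in out:
            out.append(int(e))
    return out


def _maximal_suffix_match(idx: FmIndex, read: str, end: int) -> tuple[int, int, int]:
    """Longest exact match ending at read position ``end`` (exclusive).

    Extends the pattern leftward one character at a time via backward search
    until the interval would empty; returns (length, lo, hi) of the last
    non-empty interval.
    """
    lo, hi = 0, len(idx.bwt)
    best = (0, 0, 0)
    i = end
    while i > 0:
        code = _CHAR_TO_CODE.get(read[i - 1])
        if code is None or code == 0:
            break
        nlo = idx.char_starts[code] + idx.occ[code, lo]
        nhi = idx.char_starts[code] + idx.occ[code, hi]
        if nlo >= nhi:
            break
        lo, hi = int(nlo), int(nhi)
        i -= 1
        best = (end - i, lo, hi)
    return best


# ---------------------------------------------------------------------------
# External aligner parameterization
# ---------------------------------------------------------------------------


def external_aligner_args(min_identity: float, effort: str = "default") -> list[str]:
    """Option set for an external bowtie2-style BWT aligner under the %ID criterion.

    No ambiguous-base penalty, unit mismatch and per-base gap penalties with
    no affine component, a minimum-score line whose slope term is
    ``min_identity - 1`` (so an L-base read must reach at least
    ``(min_identity - 1) * L``), first acceptable hit only, forward strand
    only, headerless SAM and suppression of unaligned reads.
    """
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must lie in (0, 1]")
    args = [
        "--np", "0",
        "--mp", "1,1",
        "--rdg", "0,1",
        "--rfg", "0,1",
        "--score-min", f"L,0,{min_identity - 1.0:.2f}",
        "-k", "1",
        "--norc",
        "--no-hd",
        "--no-unal",
    ]
    if effort == "fast":
        args.append("--fast")
    elif effort == "max":
        args.append("--very-sensitive")
    elif effort != "default":
        raise ValueError(f"unknown effort preset {effort!r}")
    return args
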