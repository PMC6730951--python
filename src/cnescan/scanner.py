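"""Sliding-window identity scan of Axt alignments — the core detector.

A window of C alignment columns slides over each block with a step of one
column. A window qualifies when it contains no excluded (exon/repeat)
column and at least ``min_matches = ceil(I/100 * C)`` matched columns, where
a match is the same A/C/G/T nucleotide in both rows (case-insensitive; gaps
and N never match). Qualifying windows whose spans overlap are unioned into
maximal segments, each segment is trimmed so it starts and ends on a matched
column, and segments are materialised into genomic coordinates on both
assemblies.

The window moves in alignment-column space, not reference-bp space: gap
columns occupy window slots and count as mismatches, keeping the window a
fixed number of columns wide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alignment_io import GAP, AxtBlock, project_query_to_forward
from .filters import FilterSet, masked_columns
from .ranges import ChromSizes, GenomicRange


def min_matches(identity_pct: float, window: int) -> int:
    """Minimum matched columns for a window to reach the identity threshold:
    ceil(identity_pct/100 * window).

    Uses exact rational arithmetic — binary floating point would turn
    70% of 30 into 21.000000000000004 and ceil it to 22.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if not (0 < identity_pct <= 100):
        raise ValueError(f"identity_pct must be in (0, 100], got {identity_pct}")
    return math.ceil(Fraction(identity_pct) * window / 100)


@dataclass(frozen=True)
class ScanParams:
    """Identity threshold I (percent) over a window of C alignment columns,
    conventionally written I*C/100 '/' C, e.g. 21/30 for 70% over 30 bp."""

    window: int
    identity_pct: float

    def __post_init__(self) -> None:
        min_matches(self.identity_pct, self.window)  # validates both

    @property
    def min_matches(self) -> int:
        return min_matches(self.identity_pct, self.window)

    @property
    def label(self) -> str:
        return f"{self.min_matches}/{self.window}"


@dataclass(frozen=True)
class CNE:
    """A conserved element: paired ranges on the two assemblies plus match
    statistics.

    ``range1`` is always forward-strand on the first assembly; ``range2`` is
    forward-projected on the second; ``strand_pair`` is the orientation of
    range2 relative to range1. ``identity`` is matches/columns for scanned
    elements; for elements produced by merging two scan orientations it is
    the minimum of the constituents and ``merged`` is set.
    """

    range1: GenomicRange
    range2: GenomicRange
    strand_pair: str
    matches: int
    columns: int
    identity: float
    merged: bool = False

    def __post_init__(self) -> None:
        if self.strand_pair not in ("+", "-"):
            raise ValueError(f"bad strand_pair {self.strand_pair!r}")
        if self.matches > self.columns:
            raise ValueError("matches cannot exceed columns")

    def swapped(self) -> "CNE":
        """The same homology statement with the two assemblies exchanged."""
        return replace(self, range1=self.range2, range2=self.range1)


Segment = Tuple[int, int, int]  # (start_col, end_col, matches over the span)


def match_vector(block: AxtBlock) -> np.ndarray:
    """Boolean per column: identical A/C/G/T in both rows (case-insensitive).
    Gap columns and columns involving N (or any ambiguity code) are False —
    ambiguity is not conservation evidence."""
    t = np.frombuffer(block.target_aln.upper().encode("ascii"), dtype=np.uint8)
    q = np.frombuffer(block.query_aln.upper().encode("ascii"), dtype=np.uint8)
    acgt = np.isin(t, np.frombuffer(b"ACGT", dtype=np.uint8))
    return (t == q) & acgt


def scan_block(
    block: AxtBlock,
    mask: Optional[np.ndarray],
    params: ScanParams,
) -> List[Segment]:
    """Raw conserved segments of one block as column spans.

    Windows touching any masked column are disqualified outright, so output
    never overlaps an annotation. Blocks shorter than the window yield
    nothing. Returns (start_col, end_col, matches) with ends trimmed to
    matched columns.
    """
    C = params.window
    ncols = block.ncols
    if mask is None:
        mask = np.zeros(ncols, dtype=bool)
    if len(mask) != ncols:
        raise ValueError(f"mask length {len(mask)} != {ncols} columns")
    if ncols < C:
        return []

    match = match_vector(block)
    # windowed sums via cumulative sums; window i covers columns [i, i+C)
    csum_match = np.concatenate(([0], np.cumsum(match)))
    csum_mask = np.concatenate(([0], np.cumsum(mask)))
    win_match = csum_match[C:] - csum_match[:-C]
    win_mask = csum_mask[C:] - csum_mask[:-C]
    ok = (win_mask == 0) & (win_match >= params.min_matches)
    starts = np.flatnonzero(ok)
    if starts.size == 0:
        return []

    segments: List[Segment] = []
    run_start = int(starts[0])
    prev = int(starts[0])
    match_idx = np.flatnonzero(match)
    for s in starts[1:]:
        s = int(s)
        if s < prev + C:  # windows [prev, prev+C) and [s, s+C) share a column
            prev = s
            continue
        segments.append(_trim(run_start, prev + C, match, match_idx, csum_match))
        run_start = s
        prev = s
    segments.append(_trim(run_start, prev + C, match, match_idx, csum_match))
    return segments


def _trim(
    start: int,
    end: int,
    match: np.ndarray,
    match_idx: np.ndarray,
    csum_match: np.ndarray,
) -> Segment:
    """Shrink [start, end) so both boundary columns are matches, and count
    matches over the trimmed span. A qualifying window always contains at
    least one match, so the span cannot vanish."""
    lo = int(match_idx[np.searchsorted(match_idx, start)])
    hi = int(match_idx[np.searchsorted(match_idx, end) - 1])
    n = int(csum_match[hi + 1] - csum_match[lo])
    return (lo, hi + 1, n)


def segments_to_cnes(
    block: AxtBlock,
    segments: Sequence[Segment],
    chrom_sizes: ChromSizes,
) -> List[CNE]:
    """Materialise column spans into paired genomic ranges.

    range1 covers the target positions of non-gap target columns within the
    span; range2 the query positions, projected to the forward strand.
    """
    if not segments:
        return []
    t_gap = np.frombuffer(
        block.target_aln.encode("ascii"), dtype=np.uint8
    ) == ord(GAP)
    q_gap = np.frombuffer(
        block.query_aln.encode("ascii"), dtype=np.uint8
    ) == ord(GAP)
    # position offset of each column on each side (in strand frame)
    t_off = np.concatenate(([0], np.cumsum(~t_gap)))
    q_off = np.concatenate(([0], np.cumsum(~q_gap)))

    strand = block.query.strand
    q_size = chrom_sizes[block.query.chrom] if strand == "-" else 0
    out: List[CNE] = []
    for start_col, end_col, matches in segments:
        t_start = block.target.start + int(t_off[start_col])
        t_end = block.target.start + int(t_off[end_col])
        q_start = block.query.start + int(q_off[start_col])
        q_end = block.query.start + int(q_off[end_col])
        if strand == "-":
            q_start, q_end = q_size - q_end, q_size - q_start
        columns = end_col - start_col
        out.append(
            CNE(
                range1=replace(block.target, start=t_start, end=t_end),
                range2=replace(
                    block.query, start=q_start, end=q_end, strand="+"
                ),
                strand_pair=strand,
                matches=matches,
                columns=columns,
                identity=matches / columns,
            )
        )
    return out


def scan_axt(
    blocks: Sequence[AxtBlock],
    target_filter: Optional[FilterSet],
    query_filter: Optional[FilterSet],
    params: ScanParams,
    chrom_sizes: ChromSizes,
) -> List[CNE]:
    """Scan every block and concatenate per-block results in deterministic
    order (block order, then span start)."""
    cnes: List[CNE] = []
    for block in blocks:
        mask = masked_columns(block, target_filter, query_filter, chrom_sizes)
        segments = scan_block(block, mask, params)
        cnes.extend(segments_to_cnes(block, segments, chrom_sizes))
    return cnes
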