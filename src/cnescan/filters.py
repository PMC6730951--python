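"""Exon/repeat exclusion ranges and overlap queries against alignments.

Elements overlapping annotated exons or repeats are not credible noncoding
conservation, so scanning skips any window touching them. Filters are kept
as per-chromosome sorted, merged interval arrays; membership tests are
binary searches. Query-side filtering is applied in forward-strand
coordinates (BED annotations are forward-strand), so '-' strand alignment
positions are projected before lookup.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .alignment_io import GAP, AxtBlock
from .ranges import ChromSizes

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or adjacent 0-based half-open intervals."""
    merged: List[Interval] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


@dataclass
class FilterSet:
    """Excluded ranges for one assembly, keyed by chromosome.

    Intervals within a chromosome are sorted, disjoint and non-adjacent
    (merged on construction).
    """

    assembly: str
    intervals: Dict[str, List[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {
            chrom: merge_intervals(ivs) for chrom, ivs in self.intervals.items()
        }
        # flattened boundary arrays for O(log n) point queries
        self._bounds = {
            chrom: [x for iv in ivs for x in iv]
            for chrom, ivs in self.intervals.items()
        }

    def masked(self, chrom: str, pos: int) -> bool:
        """True iff ``pos`` falls inside an excluded interval. Unknown
        chromosomes are never masked."""
        bounds = self._bounds.get(chrom)
        if not bounds:
            return False
        # odd insertion index <=> pos is inside an interval (half-open)
        return bisect.bisect_right(bounds, pos) % 2 == 1

    def total_bp(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def __len__(self) -> int:
        return sum(len(ivs) for ivs in self.intervals.values())


EMPTY_FILTER = FilterSet(assembly="none")


def load_filter_bed(paths: Sequence[str] | str, assembly: str) -> FilterSet:
    """Union of intervals from one or more BED3+ files, merged per
    chromosome. Strand and any columns beyond the third are ignored."""
    if isinstance(paths, str):
        paths = [paths]
    raw: Dict[str, List[Interval]] = {}
    for path in paths:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: BED record needs >= 3 fields"
                    )
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if start >= end:
                    raise ValueError(
                        f"{path}:{lineno}: start {start} >= end {end}"
                    )
                raw.setdefault(chrom, []).append((start, end))
    return FilterSet(assembly=assembly, intervals=raw)


def write_filter_bed(filt: FilterSet, path: str) -> None:
    """Write the merged intervals back out as BED3."""
    with open(path, "w") as fh:
        for chrom in sorted(filt.intervals):
            for start, end in filt.intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def masked_columns(
    block: AxtBlock,
    target_filter: Optional[FilterSet] = None,
    query_filter: Optional[FilterSet] = None,
    chrom_sizes_query: Optional[ChromSizes] = None,
) -> np.ndarray:
    """Boolean vector over alignment columns: True where the column's target
    base is excluded on the target side OR its query base (projected to the
    forward strand) is excluded on the query side.

    A gap contributes no mask on its own side — the column can still be
    masked through the other row. Absent filters mask nothing.
    """
    ncols = block.ncols
    mask = np.zeros(ncols, dtype=bool)
    if target_filter is None and query_filter is None:
        return mask

    t_chrom, q_chrom = block.target.chrom, block.query.chrom
    minus = block.query.strand == "-"
    if query_filter is not None and minus and chrom_sizes_query is None:
        raise ValueError("chrom_sizes_query required for '-' strand query filtering")
    q_size = chrom_sizes_query[q_chrom] if (minus and chrom_sizes_query) else 0

    t_pos = block.target.start
    q_pos = block.query.start  # in strand frame
    for col in range(ncols):
        t_gap = block.target_aln[col] == GAP
        q_gap = block.query_aln[col] == GAP
        if target_filter is not None and not t_gap:
            if target_filter.masked(t_chrom, t_pos):
                mask[col] = True
        if query_filter is not None and not q_gap and not mask[col]:
            fwd = (q_size - 1 - q_pos) if minus else q_pos
            if query_filter.masked(q_chrom, fwd):
                mask[col] = True
        if not t_gap:
            t_pos += 1
        if not q_gap:
            q_pos += 1
    return mask
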