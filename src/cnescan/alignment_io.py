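"""Reading, writing and summarising Axt pairwise net alignments.

An Axt file stores one aligned block as a 9-field header line, a gapped
target sequence line and a gapped query sequence line, with blocks separated
by blank lines and '#' comment lines allowed anywhere::

    0 chr19 3001012 3001075 chr11 70568380 70568443 - 3500
    TCAGCTCATAAATCACCTCCTG...
    TGGCTCACAAATCACCACCTCC...

Header coordinates are 1-based inclusive; this module converts them to the
package-internal 0-based half-open convention on read and back on write.
When the query strand is '-', the query coordinates refer to the
reverse-complemented query sequence (the UCSC Axt convention); they are kept
in that frame and projected to the forward strand only on demand, which
preserves bit-exact round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .ranges import ChromSizes, GenomicRange

GAP = "-"
_BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class AxtFormatError(ValueError):
    """Raised for structurally invalid Axt input."""


@dataclass(frozen=True)
class AxtBlock:
    """One aligned block of a pairwise net alignment.

    ``target`` is always on the '+' strand. ``query`` may be on either
    strand; for '-' its coordinates are in the reverse-complement frame.
    """

    index: int
    target: GenomicRange
    query: GenomicRange
    target_aln: str
    query_aln: str
    score: int

    def __post_init__(self) -> None:
        if self.target.strand != "+":
            raise ValueError("Axt target strand must be '+'")
        if len(self.target_aln) != len(self.query_aln):
            raise AxtFormatError(
                f"block {self.index}: alignment rows differ in length "
                f"({len(self.target_aln)} vs {len(self.query_aln)})"
            )
        if len(self.target_aln) == 0:
            raise AxtFormatError(f"block {self.index}: empty alignment")
        n_t = len(self.target_aln) - self.target_aln.count(GAP)
        n_q = len(self.query_aln) - self.query_aln.count(GAP)
        if n_t != self.target.width:
            raise AxtFormatError(
                f"block {self.index}: target range width {self.target.width} "
                f"!= {n_t} non-gap characters"
            )
        if n_q != self.query.width:
            raise AxtFormatError(
                f"block {self.index}: query range width {self.query.width} "
                f"!= {n_q} non-gap characters"
            )
        for col, (t, q) in enumerate(zip(self.target_aln, self.query_aln)):
            if t == GAP and q == GAP:
                raise AxtFormatError(
                    f"block {self.index}: column {col} gapped in both rows"
                )

    @property
    def ncols(self) -> int:
        return len(self.target_aln)


def read_axt(
    path: str,
    target_assembly: str = "target",
    query_assembly: str = "query",
    chrom_sizes: Optional[ChromSizes] = None,
) -> List[AxtBlock]:
    """Parse an Axt file into a list of validated :class:`AxtBlock`.

    ``chrom_sizes``, when given, is used to bounds-check query coordinates
    after projection to the forward strand.
    """
    blocks: List[AxtBlock] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        fields = line.split()
        if len(fields) != 9:
            raise AxtFormatError(
                f"line {i + 1}: expected 9 header fields, got {len(fields)}"
            )
        if i + 2 >= n:
            raise AxtFormatError(f"line {i + 1}: truncated block")
        (idx_s, t_chrom, t_start, t_end, q_chrom, q_start, q_end,
         strand, score_s) = fields
        try:
            idx = int(idx_s)
            t0, t1 = int(t_start), int(t_end)
            q0, q1 = int(q_start), int(q_end)
            score = int(score_s)
        except ValueError as exc:
            raise AxtFormatError(f"line {i + 1}: non-integer header field") from exc
        if t0 > t1 or q0 > q1:
            raise AxtFormatError(
                f"block {idx} (line {i + 1}): start > end in header"
            )
        if strand not in ("+", "-"):
            raise AxtFormatError(f"block {idx}: bad strand {strand!r}")
        target = GenomicRange(target_assembly, t_chrom, t0 - 1, t1, "+")
        query = GenomicRange(query_assembly, q_chrom, q0 - 1, q1, strand)
        block = AxtBlock(
            index=idx,
            target=target,
            query=query,
            target_aln=lines[i + 1].strip(),
            query_aln=lines[i + 2].strip(),
            score=score,
        )
        if chrom_sizes is not None:
            chrom_sizes.validate(project_query_to_forward(block, chrom_sizes))
        blocks.append(block)
        i += 3
    return blocks


def write_axt(blocks: Sequence[AxtBlock], path: str) -> None:
    """Write blocks in the standard Axt dialect (1-based inclusive headers,
    blank line after each block) such that ``read_axt`` inverts it exactly."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"{b.index} {b.target.chrom} {b.target.start + 1} {b.target.end} "
                f"{b.query.chrom} {b.query.start + 1} {b.query.end} "
                f"{b.query.strand} {b.score}\n"
            )
            fh.write(b.target_aln + "\n")
            fh.write(b.query_aln + "\n\n")


def project_query_to_forward(block: AxtBlock, chrom_sizes: ChromSizes) -> GenomicRange:
    """Query range of a block in forward-strand coordinates.

    '-' strand Axt coordinates count from the start of the reverse-complement
    of the chromosome; reflecting through the chromosome length recovers the
    forward-strand interval. Applying the reflection twice is the identity.
    """
    q = block.query
    if q.strand == "+":
        return q
    size = chrom_sizes[q.chrom]
    return replace(q, start=size - q.end, end=size - q.start, strand="+")


def match_composition(blocks: Sequence[AxtBlock]) -> np.ndarray:
    """5x5 count matrix of target base (row) vs query base (column) over
    {A,C,G,T,N}, case-insensitive. Columns with a gap in either row are
    excluded, so the grand total equals the number of gapless columns.
    Non-ACGT characters are tallied as N."""
    counts = np.zeros((5, 5), dtype=np.int64)
    for b in blocks:
        for t, q in zip(b.target_aln.upper(), b.query_aln.upper()):
            if t == GAP or q == GAP:
                continue
            counts[_BASE_INDEX.get(t, 4), _BASE_INDEX.get(q, 4)] += 1
    return counts


def match_composition_frame(blocks: Sequence[AxtBlock]):
    """``match_composition`` as a labelled pandas DataFrame."""
    import pandas as pd

    m = match_composition(blocks)
    return pd.DataFrame(m, index=list(_BASES), columns=list(_BASES))


def synteny_segments(
    blocks: Sequence[AxtBlock],
    chrom_sizes: ChromSizes,
    min_len: int = 0,
) -> List[Tuple[GenomicRange, GenomicRange]]:
    """(target, forward-projected query) pairs for blocks whose target width
    is at least ``min_len`` — the raw material of a syntenic dotplot."""
    return [
        (b.target, project_query_to_forward(b, chrom_sizes))
        for b in blocks
        if b.target.width >= min_len
    ]
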