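"""CNE cluster (genomic regulatory block-like) detection.

Clusters of CNEs around developmental genes mark regulatory blocks whose
boundaries coincide with topologically associating domains. Here clusters
are called by distance-based single linkage: consecutive elements on a
chromosome chain together while the gap between them stays within
``max_gap``, and chains with fewer than ``min_elements`` members are
discarded. The two parameters are deliberately exposed — boundary calling
has no single canonical definition and sensible values depend on the
evolutionary distance of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List

import pandas as pd

from .pipeline import CNESet
from .ranges import GenomicRange


@dataclass(frozen=True)
class CNECluster:
    """A chained run of CNEs: its spanning range, member count and member
    indices into the originating CNESet's element list."""

    range: GenomicRange
    n_elements: int
    members: tuple

    def __post_init__(self) -> None:
        if self.n_elements != len(self.members):
            raise ValueError("n_elements must equal number of members")


def find_clusters(
    aset: CNESet,
    which: str,
    max_gap: int,
    min_elements: int = 1,
) -> List[CNECluster]:
    """Single-linkage chaining of CNEs on one assembly.

    The gap between an element and the running cluster is measured from the
    furthest end reached so far, so contained or overlapping elements count
    as gap 0. Clusters are returned in (chrom, start) order.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if min_elements < 1:
        raise ValueError("min_elements must be >= 1")
    if which not in (aset.assembly1, aset.assembly2):
        raise ValueError(f"unknown assembly selector {which!r}")
    first = which == aset.assembly1

    indexed = sorted(
        range(len(aset.elements)),
        key=lambda i: (
            (aset.elements[i].range1 if first else aset.elements[i].range2).chrom,
            (aset.elements[i].range1 if first else aset.elements[i].range2).start,
        ),
    )
    clusters: List[CNECluster] = []
    cur: List[int] = []
    cur_chrom = None
    cur_start = cur_end = 0

    def flush() -> None:
        if len(cur) >= min_elements:
            clusters.append(
                CNECluster(
                    range=GenomicRange(which, cur_chrom, cur_start, cur_end, "+"),
                    n_elements=len(cur),
                    members=tuple(cur),
                )
            )

    for i in indexed:
        rng = aset.elements[i].range1 if first else aset.elements[i].range2
        if cur and rng.chrom == cur_chrom and rng.start - cur_end <= max_gap:
            cur.append(i)
            cur_end = max(cur_end, rng.end)
        else:
            if cur:
                flush()
            cur = [i]
            cur_chrom, cur_start, cur_end = rng.chrom, rng.start, rng.end
    if cur:
        flush()
    return clusters


def cluster_report(clusters: List[CNECluster], aset: CNESet) -> pd.DataFrame:
    """One row per cluster: coordinates, width and element count.
    TSV-writable via ``DataFrame.to_csv(..., sep='\\t')``."""
    return pd.DataFrame(
        [
            {
                "chrom": c.range.chrom,
                "start": c.range.start,
                "end": c.range.end,
                "width": c.range.width,
                "n_elements": c.n_elements,
            }
            for c in clusters
        ],
        columns=["chrom", "start", "end", "width", "n_elements"],
    )


def export_cluster_bed(clusters: List[CNECluster], path: str) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            fh.write(
                f"{c.range.chrom}\t{c.range.start}\t{c.range.end}\t"
                f"cluster{i}\t{c.n_elements}\t+\n"
            )
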