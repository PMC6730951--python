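"""Genomic coordinate primitives.

All coordinates inside the package are 0-based half-open. The only place
1-based inclusive coordinates appear is Axt text I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping


@dataclass(frozen=True, order=True)
class GenomicRange:
    """A strand-aware interval on a chromosome of a named assembly.

    ``start``/``end`` are 0-based half-open. For ranges taken from the query
    side of an Axt block on the '-' strand, coordinates are in the
    reverse-complement frame (the Axt convention) until projected with
    :func:`cnescan.alignment_io.project_query_to_forward`.
    """

    assembly: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid range {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRange") -> bool:
        """True if the two ranges share at least one base on the same
        chromosome (assembly and strand are not compared)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def union_span(self, other: "GenomicRange") -> "GenomicRange":
        """Smallest range containing both (same chrom required)."""
        if self.chrom != other.chrom:
            raise ValueError("cannot span ranges on different chromosomes")
        return replace(
            self, start=min(self.start, other.start), end=max(self.end, other.end)
        )


@dataclass(frozen=True)
class ChromSizes:
    """Chromosome lengths for one assembly, as read from a chrom.sizes file."""

    assembly: str
    sizes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {chrom}: {length}")

    def __getitem__(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise KeyError(
                f"chromosome {chrom!r} not in sizes for assembly {self.assembly!r}"
            ) from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self.sizes)

    def validate(self, rng: GenomicRange) -> None:
        """Raise if a range exceeds its chromosome bounds."""
        if rng.end > self[rng.chrom]:
            raise ValueError(
                f"{rng.chrom}:{rng.start}-{rng.end} exceeds chromosome "
                f"length {self[rng.chrom]}"
            )


def read_chrom_sizes(path: str, assembly: str) -> ChromSizes:
    """Read a 2-column UCSC chrom.sizes file (chrom<TAB>length)."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"malformed chrom.sizes line: {line!r}")
            sizes[fields[0]] = int(fields[1])
    return ChromSizes(assembly=assembly, sizes=sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.sizes.items():
            fh.write(f"{chrom}\t{length}\n")
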