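"""Full CNE detection pipeline.

Net alignments keep only the best match per reference region, so a single
scan misses legitimate 1:many orthology created by whole-genome duplication.
The pipeline therefore scans two nets — one per choice of reference genome —
brings both element sets into a common frame, merges pairs that overlap on
*both* assemblies (the same element seen from both directions), keeps pairs
overlapping on only one assembly (paralogs), and finally discards elements
whose sequence hits the genomes too many times (repeat-derived false
positives that survived annotation filtering).

Results persist in an SQLite file, one table per (assembly pair, threshold).
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import reverse_complement

from .alignment_io import AxtBlock
from .filters import FilterSet
from .ranges import ChromSizes, GenomicRange
from .scanner import CNE, ScanParams, scan_axt


def _sort_key(cne: CNE):
    return (
        cne.range1.chrom, cne.range1.start, cne.range1.end,
        cne.range2.chrom, cne.range2.start, cne.range2.end,
        cne.strand_pair,
    )


@dataclass
class CNESet:
    """An ordered collection of CNEs between one assembly pair at one
    threshold, with provenance free-text describing its inputs and stage."""

    assembly1: str
    assembly2: str
    params: ScanParams
    elements: List[CNE] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        for cne in self.elements:
            if (cne.range1.assembly, cne.range2.assembly) != (
                self.assembly1,
                self.assembly2,
            ):
                raise ValueError(
                    f"element {cne.range1.chrom}:{cne.range1.start} does not "
                    f"match assembly pair ({self.assembly1}, {self.assembly2})"
                )
        self.elements = sorted(self.elements, key=_sort_key)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)


def scan_both(
    axt_12: Sequence[AxtBlock],
    axt_21: Sequence[AxtBlock],
    assembly1: str,
    assembly2: str,
    filters: Mapping[str, Optional[FilterSet]],
    params: ScanParams,
    sizes: Mapping[str, ChromSizes],
    provenance: str = "",
) -> Tuple[CNESet, CNESet]:
    """Scan the two reference orientations and return both element sets in
    the common frame (range1 on ``assembly1``).

    ``axt_12`` has assembly1 as target; ``axt_21`` has assembly2 as target.
    ``filters`` and ``sizes`` are keyed by assembly name.
    """
    cnes_12 = scan_axt(
        axt_12, filters.get(assembly1), filters.get(assembly2),
        params, sizes[assembly2],
    )
    cnes_21 = scan_axt(
        axt_21, filters.get(assembly2), filters.get(assembly1),
        params, sizes[assembly1],
    )
    set1 = CNESet(assembly1, assembly2, params, list(cnes_12),
                  provenance=provenance or "scan axt(1->2)")
    # reorient: the second scan reports range1 on assembly2; swapping the
    # ranges preserves the homology statement (strand_pair is symmetric)
    set2 = CNESet(assembly1, assembly2, params,
                  [c.swapped() for c in cnes_21],
                  provenance=provenance or "scan axt(2->1), reoriented")
    return set1, set2


def _both_overlap(a: CNE, b: CNE) -> bool:
    return (
        a.strand_pair == b.strand_pair
        and a.range1.overlaps(b.range1)
        and a.range2.overlaps(b.range2)
    )


def _merge_two(a: CNE, b: CNE) -> CNE:
    return CNE(
        range1=a.range1.union_span(b.range1),
        range2=a.range2.union_span(b.range2),
        strand_pair=a.strand_pair,
        matches=a.matches + b.matches,
        columns=a.columns + b.columns,
        identity=min(a.identity, b.identity),
        merged=True,
    )


def cne_merge(set1: CNESet, set2: CNESet) -> CNESet:
    """Merge two scan orientations into one reliable set.

    Elements merge iff they share chromosomes on both assemblies, have the
    same orientation, and their intervals overlap on BOTH assemblies;
    merging repeats until no such pair remains. Elements overlapping on only
    one assembly are all kept — that is exactly the paralog signal the
    two-reference strategy exists to preserve. Merged identity is the
    minimum of the constituents (conservative; per-column data is gone).
    """
    if (set1.assembly1, set1.assembly2) != (set2.assembly1, set2.assembly2):
        raise ValueError(
            f"assembly frame mismatch: ({set1.assembly1},{set1.assembly2}) "
            f"vs ({set2.assembly1},{set2.assembly2})"
        )
    groups: Dict[Tuple[str, str, str], List[CNE]] = {}
    for cne in list(set1.elements) + list(set2.elements):
        key = (cne.range1.chrom, cne.range2.chrom, cne.strand_pair)
        groups.setdefault(key, []).append(cne)

    merged_all: List[CNE] = []
    for elems in groups.values():
        merged_all.extend(_merge_group(elems))
    return CNESet(
        set1.assembly1, set1.assembly2, set1.params, merged_all,
        provenance="merged two scan orientations",
    )


def _merge_group(elems: List[CNE]) -> List[CNE]:
    """Fixed-point pairwise merging within one (chrom1, chrom2, strand)
    group: absorb each element into the first accumulated element it merges
    with, and repeat whole passes until nothing changes (a grown span can
    newly overlap an element placed earlier). Quadratic within a group,
    which is fine — groups are per chromosome pair and orientation."""
    work = elems
    changed = True
    while changed:
        changed = False
        work = sorted(work, key=_sort_key)
        out: List[CNE] = []
        for cne in work:
            for i, acc in enumerate(out):
                if _both_overlap(acc, cne):
                    out[i] = _merge_two(acc, cne)
                    changed = True
                    break
            else:
                out.append(cne)
        work = out
    return work


def realignment_filter(
    cnes: CNESet,
    genome1: Mapping[str, str],
    genome2: Mapping[str, str],
    max_hits: int = 4,
    hit_counts: Optional[Sequence[Tuple[int, int]]] = None,
) -> CNESet:
    """Discard elements whose sequence occurs too often in either genome.

    The default counter is internal and exact: for each element it counts
    overlapping occurrences of its sequence and reverse complement across
    the genome it came from (hits of range1's sequence in genome1, range2's
    in genome2). An element with more than ``max_hits`` hits in either
    genome is treated as repeat-derived and dropped. For the external
    aligner path, precomputed per-element ``hit_counts`` (pairs of counts,
    e.g. from :func:`psl_hit_counts`) override the internal counter.

    ``genome1``/``genome2`` map chromosome name to sequence string.
    """
    if max_hits < 0:
        raise ValueError("max_hits must be non-negative")
    kept: List[CNE] = []
    for i, cne in enumerate(cnes.elements):
        if hit_counts is not None:
            h1, h2 = hit_counts[i]
        else:
            h1 = count_genome_hits(_fetch(genome1, cne.range1), genome1)
            h2 = count_genome_hits(_fetch(genome2, cne.range2), genome2)
        if h1 <= max_hits and h2 <= max_hits:
            kept.append(cne)
    return CNESet(
        cnes.assembly1, cnes.assembly2, cnes.params, kept,
        provenance=cnes.provenance + f"; realignment filter max_hits={max_hits}",
    )


def _fetch(genome: Mapping[str, str], rng: GenomicRange) -> str:
    try:
        seq = genome[rng.chrom]
    except KeyError:
        raise ValueError(f"no sequence for chromosome {rng.chrom!r}") from None
    if rng.end > len(seq):
        raise ValueError(
            f"range {rng.chrom}:{rng.start}-{rng.end} beyond sequence "
            f"length {len(seq)}"
        )
    return seq[rng.start:rng.end]


def count_occurrences(needle: str, haystack: str) -> int:
    """Overlapping exact occurrences of ``needle`` in ``haystack``
    (case-insensitive)."""
    needle = needle.upper()
    haystack = haystack.upper()
    n = 0
    pos = haystack.find(needle)
    while pos != -1:
        n += 1
        pos = haystack.find(needle, pos + 1)
    return n


def count_genome_hits(seq: str, genome: Mapping[str, str]) -> int:
    """Occurrences of ``seq`` or its reverse complement anywhere in the
    genome. A palindromic sequence is not double-counted."""
    rc = reverse_complement(seq.upper())
    hits = 0
    for chrom_seq in genome.values():
        hits += count_occurrences(seq, chrom_seq)
        if rc != seq.upper():
            hits += count_occurrences(rc, chrom_seq)
    return hits


def psl_hit_counts(
    psl_path: str,
    n_elements: int,
    min_identity: float = 0.9,
) -> List[int]:
    """Count PSL records per query above an identity cutoff.

    Queries must be named ``cne<i>`` for element index i (the convention
    used when exporting element FASTA for an external aligner). Identity is
    matches / qSize. Skips the optional PSL header."""
    counts = [0] * n_elements
    with open(psl_path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 21 or not fields[0].isdigit():
                continue  # header / separator lines
            matches = int(fields[0])
            q_name, q_size = fields[9], int(fields[10])
            if not q_name.startswith("cne"):
                continue
            idx = int(q_name[3:])
            if q_size > 0 and matches / q_size >= min_identity:
                counts[idx] += 1
    return counts


# ---------------------------------------------------------------------------
# SQLite persistence

_COLUMNS = (
    "chrom1 TEXT, start1 INTEGER, end1 INTEGER, "
    "chrom2 TEXT, start2 INTEGER, end2 INTEGER, "
    "strand TEXT, matches INTEGER, columns INTEGER, "
    "identity REAL, merged INTEGER"
)


def _table_name(aset: CNESet) -> str:
    pct = aset.params.identity_pct
    ident = str(int(pct)) if float(pct).is_integer() else str(pct).replace(".", "_")
    return f"cne_{aset.assembly1}_{aset.assembly2}_{ident}_{aset.params.window}"


def save_cnes(aset: CNESet, store: str) -> str:
    """Persist a CNE set; the table name encodes assembly pair and
    threshold. Returns the table name."""
    table = _table_name(aset)
    con = sqlite3.connect(store)
    try:
        con.execute(
            "CREATE TABLE IF NOT EXISTS cne_meta ("
            "tbl TEXT PRIMARY KEY, assembly1 TEXT, assembly2 TEXT, "
            "identity_pct REAL, window INTEGER, provenance TEXT)"
        )
        con.execute(f'DROP TABLE IF EXISTS "{table}"')
        con.execute(f'CREATE TABLE "{table}" ({_COLUMNS})')
        con.executemany(
            f'INSERT INTO "{table}" VALUES (?,?,?,?,?,?,?,?,?,?,?)',
            [
                (
                    c.range1.chrom, c.range1.start, c.range1.end,
                    c.range2.chrom, c.range2.start, c.range2.end,
                    c.strand_pair, c.matches, c.columns, c.identity,
                    int(c.merged),
                )
                for c in aset.elements
            ],
        )
        con.execute(
            "INSERT OR REPLACE INTO cne_meta VALUES (?,?,?,?,?,?)",
            (table, aset.assembly1, aset.assembly2,
             float(aset.params.identity_pct), aset.params.window,
             aset.provenance),
        )
        con.commit()
    finally:
        con.close()
    return table


def load_cnes(
    store: str,
    table: str,
    chrom: Optional[str] = None,
    start: Optional[int] = None,
    end: Optional[int] = None,
) -> CNESet:
    """Load a stored set, optionally restricted to elements whose range1
    overlaps (chrom, start, end)."""
    con = sqlite3.connect(store)
    try:
        meta = con.execute(
            "SELECT assembly1, assembly2, identity_pct, window, provenance "
            "FROM cne_meta WHERE tbl = ?", (table,)
        ).fetchone()
        if meta is None:
            raise KeyError(f"no stored CNE table {table!r}")
        assembly1, assembly2, identity_pct, window, provenance = meta
        sql = f'SELECT * FROM "{table}"'
        args: tuple = ()
        if chrom is not None:
            sql += " WHERE chrom1 = ?"
            args = (chrom,)
            if start is not None and end is not None:
                sql += " AND start1 < ? AND end1 > ?"
                args = (chrom, end, start)
        rows = con.execute(sql, args).fetchall()
    finally:
        con.close()
    elements = [
        CNE(
            range1=GenomicRange(assembly1, c1, s1, e1, "+"),
            range2=GenomicRange(assembly2, c2, s2, e2, "+"),
            strand_pair=strand,
            matches=matches,
            columns=columns,
            identity=identity,
            merged=bool(merged),
        )
        for c1, s1, e1, c2, s2, e2, strand, matches, columns, identity, merged
        in rows
    ]
    if identity_pct == int(identity_pct):
        identity_pct = int(identity_pct)
    return CNESet(
        assembly1, assembly2, ScanParams(window, identity_pct), elements,
        provenance=provenance,
    )


def list_cne_tables(store: str) -> List[str]:
    con = sqlite3.connect(store)
    try:
        rows = con.execute("SELECT tbl FROM cne_meta ORDER BY tbl").fetchall()
    finally:
        con.close()
    return [r[0] for r in rows]


def export_bed(aset: CNESet, which: str, path: str) -> None:
    """Write elements as BED6 on the chosen assembly.

    The name field carries the partner coordinates, score is
    round(1000 x identity) and strand is the orientation of the pair.
    """
    if which not in (aset.assembly1, aset.assembly2):
        raise ValueError(
            f"{which!r} is not one of ({aset.assembly1!r}, {aset.assembly2!r})"
        )
    first = which == aset.assembly1
    with open(path, "w") as fh:
        for c in aset.elements:
            own, other = (c.range1, c.range2) if first else (c.range2, c.range1)
            name = f"{other.chrom}:{other.start}-{other.end}"
            score = min(1000, round(1000 * c.identity))
            fh.write(
                f"{own.chrom}\t{own.start}\t{own.end}\t{name}\t{score}\t"
                f"{c.strand_pair}\n"
            )
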