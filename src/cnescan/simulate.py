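"""Synthetic genome pairs with planted conserved elements.

Builds two genomes plus the Axt net alignments between them directly, so
the ground truth (element positions, realized identities, copy numbers) is
exact by construction and no external aligner is ever involved. The layout
emulates what the detection pipeline sees in real data:

* a background alignment in which columns match with a fixed probability
  (divergent neutral sequence),
* planted elements whose mismatch count is placed exactly (not sampled), at
  deterministic interior offsets, so their realized identity is known,
* decoy regions of perfect identity that are listed in the exon/repeat
  filter BEDs — a scanner that ignores annotation filters will report them,
* paralogous extra copies of an element present only in genome2. These
  appear only in the genome2-referenced net (a net keeps the single best
  match per reference region, so the genome1-referenced net shows one copy
  while each genome2 copy gets its own block in the other orientation).

Everything is deterministic under the seed, including file bytes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import reverse_complement

from .alignment_io import AxtBlock, write_axt
from .filters import FilterSet, write_filter_bed
from .ranges import ChromSizes, GenomicRange, write_chrom_sizes

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CHROM1 = "chr1"
CHROM2 = "chr2"
ASSEMBLY1 = "genome1"
ASSEMBLY2 = "genome2"


@dataclass(frozen=True)
class PlantSpec:
    """One element to embed: length, percent identity, copy number in
    genome2, whether a filter interval overlaps it (to exercise masking),
    and orientation of the genome2 copy relative to genome1."""

    length: int
    identity: float = 100.0
    copies: int = 1
    overlap_filter: bool = False
    orientation: str = "+"
    position: Optional[int] = None  # genome1 start; auto-placed when None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("plant length must be positive")
        if not (50 <= self.identity <= 100):
            raise ValueError("plant identity must be in [50, 100]")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")

    @property
    def n_mismatches(self) -> int:
        return round((1 - self.identity / 100) * self.length)


@dataclass(frozen=True)
class TruthRecord:
    """Realized placement of one copy of one planted element."""

    plant_index: int
    copy_index: int
    range1: GenomicRange
    range2: GenomicRange
    realized_identity: float
    orientation: str
    copies: int


@dataclass
class SyntheticPair:
    """A generated genome pair with its alignments, filters and truth."""

    genome1: Dict[str, str]
    genome2: Dict[str, str]
    axt_12: List[AxtBlock]
    axt_21: List[AxtBlock]
    filter1: FilterSet
    filter2: FilterSet
    sizes1: ChromSizes
    sizes2: ChromSizes
    truth: List[TruthRecord] = field(default_factory=list)

    def write(self, out_dir: str) -> Dict[str, str]:
        """Write all fixture files; returns name -> path."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "genome1": os.path.join(out_dir, "genome1.fa"),
            "genome2": os.path.join(out_dir, "genome2.fa"),
            "axt_12": os.path.join(out_dir, "genome1.genome2.net.axt"),
            "axt_21": os.path.join(out_dir, "genome2.genome1.net.axt"),
            "filter1": os.path.join(out_dir, "filter1.bed"),
            "filter2": os.path.join(out_dir, "filter2.bed"),
            "sizes1": os.path.join(out_dir, "genome1.sizes"),
            "sizes2": os.path.join(out_dir, "genome2.sizes"),
            "truth": os.path.join(out_dir, "truth.tsv"),
        }
        _write_fasta(self.genome1, paths["genome1"])
        _write_fasta(self.genome2, paths["genome2"])
        write_axt(self.axt_12, paths["axt_12"])
        write_axt(self.axt_21, paths["axt_21"])
        write_filter_bed(self.filter1, paths["filter1"])
        write_filter_bed(self.filter2, paths["filter2"])
        write_chrom_sizes(self.sizes1, paths["sizes1"])
        write_chrom_sizes(self.sizes2, paths["sizes2"])
        with open(paths["truth"], "w") as fh:
            fh.write(
                "plant\tcopy\tchrom1\tstart1\tend1\tchrom2\tstart2\tend2\t"
                "identity\torientation\tcopies\n"
            )
            for t in self.truth:
                fh.write(
                    f"{t.plant_index}\t{t.copy_index}\t"
                    f"{t.range1.chrom}\t{t.range1.start}\t{t.range1.end}\t"
                    f"{t.range2.chrom}\t{t.range2.start}\t{t.range2.end}\t"
                    f"{t.realized_identity:.4f}\t{t.orientation}\t{t.copies}\n"
                )
        return paths


def _write_fasta(genome: Dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, base: np.uint8) -> np.uint8:
    """A uniformly chosen base different from ``base``."""
    others = _BASES[_BASES != base]
    return others[rng.integers(0, 3)]


def _allocate_slots(
    lengths: Sequence[int],
    lo: int,
    hi: int,
    margin: int,
) -> List[Tuple[int, int]]:
    """Evenly spaced non-overlapping slots for features of the given
    lengths inside [lo, hi)."""
    n = len(lengths)
    if n == 0:
        return []
    cell = (hi - lo) // n
    slots = []
    for i, length in enumerate(lengths):
        start = lo + i * cell + margin
        end = start + length
        if end + margin > lo + (i + 1) * cell:
            raise ValueError(
                f"cannot place feature of length {length} in cell of size "
                f"{cell} with margin {margin}; enlarge the genome"
            )
        slots.append((start, end))
    return slots


def generate_pair(
    plants: Sequence[PlantSpec],
    background_identity: float = 70.0,
    genome_lengths: Tuple[int, int] = (100_000, 120_000),
    seed: int = 0,
    n_decoys: int = 0,
    decoy_length: int = 500,
    margin: int = 300,
    out_dir: Optional[str] = None,
) -> SyntheticPair:
    """Generate a genome pair with planted elements and exact truth.

    Genome1 is one chromosome of ``genome_lengths[0]`` bp, fully covered by
    a gap-free alignment to the first part of genome2's single chromosome;
    the tail of genome2 hosts paralogous extra copies. ``background_identity``
    is the per-column match probability outside planted/decoy regions.
    """
    L1, L2 = genome_lengths
    if L2 < L1:
        raise ValueError("genome2 must be at least as long as genome1")
    if not (0 < background_identity <= 100):
        raise ValueError("background_identity must be in (0, 100]")
    rng = np.random.default_rng(seed)

    g1 = _random_seq(rng, L1)

    # --- place plants and decoys on genome1
    auto = [i for i, p in enumerate(plants) if p.position is None]
    fixed = [(i, p.position, p.position + p.length)
             for i, p in enumerate(plants) if p.position is not None]
    auto_lengths = [plants[i].length for i in auto] + [decoy_length] * n_decoys
    slots = _allocate_slots(auto_lengths, 0, L1, margin)
    plant_slots: Dict[int, Tuple[int, int]] = {
        i: slots[k] for k, i in enumerate(auto)
    }
    decoy_slots = slots[len(auto):]
    for i, s, e in fixed:
        plant_slots[i] = (s, e)
    occupied = sorted(list(plant_slots.values()) + decoy_slots)
    for (s1, e1), (s2, e2) in zip(occupied, occupied[1:]):
        if s2 < e1:
            raise ValueError(
                f"planted features overlap: ({s1},{e1}) and ({s2},{e2})"
            )
    if occupied and (occupied[0][0] < 0 or occupied[-1][1] > L1):
        raise ValueError("planted feature outside genome1 bounds")

    # --- build the aligned portion of genome2 (coordinates mirror genome1)
    g2_aligned = g1.copy()
    in_feature = np.zeros(L1, dtype=bool)
    for s, e in list(plant_slots.values()) + decoy_slots:
        in_feature[s:e] = True
    bg_positions = np.flatnonzero(~in_feature)
    mismatch = rng.random(len(bg_positions)) >= background_identity / 100
    for pos in bg_positions[mismatch]:
        g2_aligned[pos] = _mutate(rng, g1[pos])
    # guaranteed mismatch immediately flanking every feature, so a detected
    # element cannot extend into the background and truth spans are exact
    for s, e in occupied:
        if s > 0 and not in_feature[s - 1]:
            g2_aligned[s - 1] = _mutate(rng, g1[s - 1])
        if e < L1 and not in_feature[e]:
            g2_aligned[e] = _mutate(rng, g1[e])

    truth: List[TruthRecord] = []
    minus_slots: List[Tuple[int, int]] = []
    copy_requests: List[Tuple[int, np.ndarray]] = []  # (plant idx, g2 element seq)
    for i, plant in enumerate(plants):
        s, e = plant_slots[i]
        elem = g1[s:e].copy()
        n_mm = plant.n_mismatches
        if n_mm:
            # deterministic interior offsets, clear of the element ends
            offsets = np.linspace(3, plant.length - 4, n_mm).round().astype(int)
            if len(np.unique(offsets)) != n_mm:
                raise ValueError(
                    f"plant {i}: cannot place {n_mm} distinct mismatches "
                    f"in {plant.length} bp"
                )
            for off in offsets:
                elem[off] = _mutate(rng, elem[off])
        realized = 100.0 * (plant.length - n_mm) / plant.length
        if plant.orientation == "-":
            g2_aligned[s:e] = _revcomp_arr(elem)
            minus_slots.append((s, e))
        else:
            g2_aligned[s:e] = elem
        truth.append(
            TruthRecord(
                plant_index=i, copy_index=0,
                range1=GenomicRange(ASSEMBLY1, CHROM1, s, e, "+"),
                range2=GenomicRange(ASSEMBLY2, CHROM2, s, e, "+"),
                realized_identity=realized,
                orientation=plant.orientation,
                copies=plant.copies,
            )
        )
        for _ in range(plant.copies - 1):
            copy_requests.append((i, g2_aligned[s:e].copy()))

    # --- genome2 tail with paralog copies
    tail = _random_seq(rng, L2 - L1)
    copy_slot_list = _allocate_slots(
        [len(seq) for _, seq in copy_requests], L1, L2, margin
    ) if copy_requests else []
    g2 = np.concatenate([g2_aligned, tail])
    copy_counter: Dict[int, int] = {}
    for (plant_idx, seq), (cs, ce) in zip(copy_requests, copy_slot_list):
        g2[cs:ce] = seq
        copy_counter[plant_idx] = copy_counter.get(plant_idx, 0) + 1
        plant = plants[plant_idx]
        s, e = plant_slots[plant_idx]
        truth.append(
            TruthRecord(
                plant_index=plant_idx,
                copy_index=copy_counter[plant_idx],
                range1=GenomicRange(ASSEMBLY1, CHROM1, s, e, "+"),
                range2=GenomicRange(ASSEMBLY2, CHROM2, cs, ce, "+"),
                realized_identity=100.0 * (plant.length - plant.n_mismatches)
                / plant.length,
                orientation=plant.orientation,
                copies=plant.copies,
            )
        )

    g1_str = g1.tobytes().decode("ascii")
    g2_str = g2.tobytes().decode("ascii")

    # --- Axt blocks: '+' stretches in bulk blocks, '-' plants as own blocks
    axt_12 = _build_axt_12(g1_str, g2_str, minus_slots, L1, L2)
    axt_21 = _build_axt_21(
        g1_str, g2_str, minus_slots, L1, L2,
        [(plant_slots[i], (cs, ce), plants[i].orientation)
         for (i, _), (cs, ce) in zip(copy_requests, copy_slot_list)],
    )

    # --- filters: decoys masked on both sides; flagged plants masked too
    f1_ivs: List[Tuple[int, int]] = list(decoy_slots)
    f2_ivs: List[Tuple[int, int]] = list(decoy_slots)
    for i, plant in enumerate(plants):
        if plant.overlap_filter:
            s, e = plant_slots[i]
            mid = (s + e) // 2
            f1_ivs.append((mid, mid + 1))
    filter1 = FilterSet(ASSEMBLY1, {CHROM1: f1_ivs} if f1_ivs else {})
    filter2 = FilterSet(ASSEMBLY2, {CHROM2: f2_ivs} if f2_ivs else {})

    pair = SyntheticPair(
        genome1={CHROM1: g1_str},
        genome2={CHROM2: g2_str},
        axt_12=axt_12,
        axt_21=axt_21,
        filter1=filter1,
        filter2=filter2,
        sizes1=ChromSizes(ASSEMBLY1, {CHROM1: L1}),
        sizes2=ChromSizes(ASSEMBLY2, {CHROM2: L2}),
        truth=truth,
    )
    if out_dir is not None:
        pair.write(out_dir)
    return pair


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    seq = arr.tobytes().decode("ascii")
    return np.frombuffer(reverse_complement(seq).encode("ascii"), dtype=np.uint8)


def _segments(minus_slots: List[Tuple[int, int]], L: int):
    """Split [0, L) into alternating '+' stretches and '-' plant slots."""
    pos = 0
    for s, e in sorted(minus_slots):
        if pos < s:
            yield (pos, s, "+")
        yield (s, e, "-")
        pos = e
    if pos < L:
        yield (pos, L, "+")


def _build_axt_12(
    g1: str, g2: str, minus_slots, L1: int, L2: int
) -> List[AxtBlock]:
    blocks = []
    for idx, (s, e, strand) in enumerate(_segments(minus_slots, L1)):
        if strand == "+":
            query = GenomicRange(ASSEMBLY2, CHROM2, s, e, "+")
            q_aln = g2[s:e]
        else:
            query = GenomicRange(ASSEMBLY2, CHROM2, L2 - e, L2 - s, "-")
            q_aln = reverse_complement(g2[s:e])
        blocks.append(
            AxtBlock(
                index=idx,
                target=GenomicRange(ASSEMBLY1, CHROM1, s, e, "+"),
                query=query,
                target_aln=g1[s:e],
                query_aln=q_aln,
                score=(e - s) * 100,
            )
        )
    return blocks


def _build_axt_21(
    g1: str, g2: str, minus_slots, L1: int, L2: int, copies
) -> List[AxtBlock]:
    """Mirror of the genome1-referenced net, plus one block per paralog
    copy (each genome2 region keeps its own best match to genome1)."""
    blocks = []
    idx = 0
    for s, e, strand in _segments(minus_slots, L1):
        if strand == "+":
            query = GenomicRange(ASSEMBLY1, CHROM1, s, e, "+")
            q_aln = g1[s:e]
        else:
            query = GenomicRange(ASSEMBLY1, CHROM1, L1 - e, L1 - s, "-")
            q_aln = reverse_complement(g1[s:e])
        blocks.append(
            AxtBlock(
                index=idx,
                target=GenomicRange(ASSEMBLY2, CHROM2, s, e, "+"),
                query=query,
                target_aln=g2[s:e],
                query_aln=q_aln,
                score=(e - s) * 100,
            )
        )
        idx += 1
    for (ps, pe), (cs, ce), orientation in copies:
        if orientation == "+":
            query = GenomicRange(ASSEMBLY1, CHROM1, ps, pe, "+")
            q_aln = g1[ps:pe]
        else:
            query = GenomicRange(ASSEMBLY1, CHROM1, L1 - pe, L1 - ps, "-")
            q_aln = reverse_complement(g1[ps:pe])
        blocks.append(
            AxtBlock(
                index=idx,
                target=GenomicRange(ASSEMBLY2, CHROM2, cs, ce, "+"),
                query=query,
                target_aln=g2[cs:ce],
                query_aln=q_aln,
                score=(ce - cs) * 100,
            )
        )
        idx += 1
    return blocks
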