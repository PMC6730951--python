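"""CNE density tracks and genomic-distribution summaries.

CNE density is the percentage of base pairs inside a smoothing window that
the union of CNEs covers. Windows start at every ``step`` bp and extend
``window`` bp (truncated at the chromosome end, with the truncated length as
denominator so density does not artificially decay at chromosome ends).
Tracks export to bedGraph and bigWig for genome browsers; each exported
interval is the step-sized interval at a window start carrying that
window's value, so with step == window the export is an exact tiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .filters import merge_intervals
from .pipeline import CNESet
from .ranges import ChromSizes


@dataclass
class DensityTrack:
    """Percent-coverage values at stepped window starts, per chromosome."""

    assembly: str
    window: int
    step: int
    chrom_sizes: ChromSizes
    # chrom -> (window starts, percent values), parallel arrays
    data: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def chroms(self) -> List[str]:
        return sorted(self.data)


def _covered_intervals(aset: CNESet, which: str) -> Dict[str, List[Tuple[int, int]]]:
    first = which == aset.assembly1
    raw: Dict[str, List[Tuple[int, int]]] = {}
    for cne in aset.elements:
        rng = cne.range1 if first else cne.range2
        raw.setdefault(rng.chrom, []).append((rng.start, rng.end))
    return {chrom: merge_intervals(ivs) for chrom, ivs in raw.items()}


def compute_density(
    aset: CNESet,
    which: str,
    sizes: ChromSizes,
    window: int = 300_000,
    step: int | None = None,
) -> DensityTrack:
    """Smoothed CNE density along every chromosome of one assembly.

    Overlapping CNEs are counted once (coverage of the interval union).
    ``step`` defaults to window/100.
    """
    if which not in (aset.assembly1, aset.assembly2):
        raise ValueError(f"unknown assembly selector {which!r}")
    if window <= 0:
        raise ValueError("window must be positive")
    if step is None:
        step = max(1, window // 100)
    if step <= 0 or window < step:
        raise ValueError(f"need 0 < step <= window, got step={step} window={window}")

    covered = _covered_intervals(aset, which)
    track = DensityTrack(assembly=which, window=window, step=step, chrom_sizes=sizes)
    for chrom in sizes:
        length = sizes[chrom]
        starts = np.arange(0, length, step, dtype=np.int64)
        values = np.zeros(len(starts), dtype=float)
        ivs = covered.get(chrom, [])
        if ivs:
            iv_starts = np.array([s for s, _ in ivs], dtype=np.int64)
            iv_ends = np.array([e for _, e in ivs], dtype=np.int64)
            cum = np.concatenate(([0], np.cumsum(iv_ends - iv_starts)))
            for i, w_start in enumerate(starts):
                w_end = min(w_start + window, length)
                values[i] = 100.0 * _coverage_in(
                    int(w_start), int(w_end), iv_starts, iv_ends, cum
                ) / (w_end - w_start)
        track.data[chrom] = (starts, values)
    return track


def _coverage_in(
    w_start: int,
    w_end: int,
    iv_starts: np.ndarray,
    iv_ends: np.ndarray,
    cum: np.ndarray,
) -> int:
    """bp of [w_start, w_end) covered by sorted disjoint intervals, using a
    prefix-sum of interval lengths plus boundary corrections."""
    lo = int(np.searchsorted(iv_ends, w_start, side="right"))
    hi = int(np.searchsorted(iv_starts, w_end, side="left"))
    if lo >= hi:
        return 0
    total = int(cum[hi] - cum[lo])
    total -= max(0, w_start - int(iv_starts[lo]))
    total -= max(0, int(iv_ends[hi - 1]) - w_end)
    return total


def export_track(track: DensityTrack, fmt: str, path: str) -> None:
    """Write a track as 4-column bedGraph or bigWig.

    Intervals are [start, min(start+step, chrom end)); zero-valued
    intervals are omitted.
    """
    if fmt == "bedGraph":
        with open(path, "w") as fh:
            for chrom in track.chroms():
                starts, values = track.data[chrom]
                length = track.chrom_sizes[chrom]
                for s, v in zip(starts, values):
                    if v == 0:
                        continue
                    e = min(int(s) + track.step, length)
                    fh.write(f"{chrom}\t{int(s)}\t{e}\t{v:g}\n")
    elif fmt == "bigWig":
        import pyBigWig

        bw = pyBigWig.open(path, "w")
        header = [
            (chrom, track.chrom_sizes[chrom]) for chrom in track.chroms()
        ]
        bw.addHeader(header)
        for chrom in track.chroms():
            starts, values = track.data[chrom]
            length = track.chrom_sizes[chrom]
            keep = values != 0
            if not keep.any():
                continue
            s = starts[keep].astype(int)
            e = np.minimum(s + track.step, length).astype(int)
            bw.addEntries(
                [chrom] * len(s), [int(x) for x in s],
                ends=[int(x) for x in e],
                values=[float(v) for v in values[keep]],
            )
        bw.close()
    else:
        raise ValueError(f"unknown track format {fmt!r}")


def read_bedgraph(path: str) -> Dict[str, List[Tuple[int, int, float]]]:
    """Parse a bedGraph back into per-chromosome (start, end, value) lists."""
    out: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            out.setdefault(chrom, []).append((int(s), int(e), float(v)))
    return out


def cumulative_positions(
    aset: CNESet, which: str
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: sorted CNE start positions paired with cumulative
    counts 1..n. A CNE cluster appears as a sharp rise over a short
    x-interval when plotted."""
    if which not in (aset.assembly1, aset.assembly2):
        raise ValueError(f"unknown assembly selector {which!r}")
    first = which == aset.assembly1
    per_chrom: Dict[str, List[int]] = {}
    for cne in aset.elements:
        rng = cne.range1 if first else cne.range2
        per_chrom.setdefault(rng.chrom, []).append(rng.start)
    return {
        chrom: (
            np.array(sorted(starts), dtype=np.int64),
            np.arange(1, len(starts) + 1, dtype=np.int64),
        )
        for chrom, starts in per_chrom.items()
    }
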