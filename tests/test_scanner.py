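"""Core sliding-window scan: threshold arithmetic, oracle equivalence,
coordinate materialisation."""

import numpy as np
import pytest

import cnescan as cs
from cnescan.scanner import match_vector

from conftest import make_block


# --- independent brute-force oracle -------------------------------------

def oracle_match(t_aln, q_aln):
    out = []
    for t, q in zip(t_aln.upper(), q_aln.upper()):
        out.append(t == q and t in "ACGT")
    return out


def oracle_scan(t_aln, q_aln, mask, window, min_matches):
    """Enumerate every window, test the predicate, union overlapping
    qualifying spans, trim each span to matched end columns."""
    n = len(t_aln)
    match = oracle_match(t_aln, q_aln)
    spans = []
    for i in range(n - window + 1):
        cols = range(i, i + window)
        if any(mask[c] for c in cols):
            continue
        if sum(match[c] for c in cols) < min_matches:
            continue
        spans.append((i, i + window))
    # union of overlapping spans
    unioned = []
    for s, e in spans:
        if unioned and s < unioned[-1][1]:
            unioned[-1] = (unioned[-1][0], max(unioned[-1][1], e))
        else:
            unioned.append((s, e))
    segments = []
    for s, e in unioned:
        while not match[s]:
            s += 1
        while not match[e - 1]:
            e -= 1
        segments.append((s, e, sum(match[s:e])))
    return segments


# --- min_matches ----------------------------------------------------------

@pytest.mark.parametrize(
    "identity, window, expected",
    [(70, 30, 21), (98, 50, 49), (96, 50, 48), (100, 50, 50),
     (70.0, 30, 21), (90, 30, 27), (80, 30, 24)],
)
def test_min_matches_threshold_arithmetic(identity, window, expected):
    """The I/C track labels: ceil(I/100 * C), exact under float inputs."""
    assert cs.min_matches(identity, window) == expected
    assert cs.ScanParams(window=window, identity_pct=identity).min_matches == expected


def test_min_matches_rejects_bad_arguments():
    with pytest.raises(ValueError):
        cs.min_matches(70, 0)
    with pytest.raises(ValueError):
        cs.min_matches(0, 30)
    with pytest.raises(ValueError):
        cs.min_matches(101, 30)


def test_scan_params_label():
    assert cs.ScanParams(window=30, identity_pct=70).label == "21/30"


# --- scan_block -----------------------------------------------------------

def perfect_block(n):
    seq = ("ACGT" * (n // 4 + 1))[:n]
    return cs.AxtBlock(
        index=0,
        target=cs.GenomicRange("a", "c", 0, n),
        query=cs.GenomicRange("b", "d", 0, n),
        target_aln=seq, query_aln=seq, score=0,
    )


def test_perfect_run_yields_single_full_segment():
    block = perfect_block(60)
    params = cs.ScanParams(window=50, identity_pct=100)
    assert cs.scan_block(block, None, params) == [(0, 60, 60)]


def test_single_masked_column_disqualifies_all_windows():
    block = perfect_block(30)
    mask = np.zeros(30, dtype=bool)
    mask[15] = True
    params = cs.ScanParams(window=30, identity_pct=70)
    assert cs.scan_block(block, mask, params) == []


def test_block_shorter_than_window_yields_nothing():
    block = perfect_block(20)
    assert cs.scan_block(block, None, cs.ScanParams(50, 100)) == []


def test_mask_length_mismatch_raises():
    block = perfect_block(30)
    with pytest.raises(ValueError, match="mask length"):
        cs.scan_block(block, np.zeros(29, dtype=bool), cs.ScanParams(10, 100))


def test_scan_block_matches_exhaustive_oracle(rng):
    """500 fuzzed alignments (random gaps, Ns, case, masks; window <= 12,
    <= 200 columns) produce segment sets identical to brute force."""
    for trial in range(500):
        ncols = int(rng.integers(5, 200))
        window = int(rng.integers(2, 13))
        identity = float(rng.integers(50, 101))
        block = make_block(
            rng, ncols=ncols,
            gap_prob=float(rng.uniform(0, 0.25)),
            match_prob=float(rng.uniform(0.4, 1.0)),
            n_prob=0.05,
        )
        mask = rng.random(ncols) < rng.uniform(0, 0.2)
        params = cs.ScanParams(window=window, identity_pct=identity)
        got = cs.scan_block(block, mask, params)
        expected = oracle_scan(
            block.target_aln, block.query_aln, list(mask),
            window, params.min_matches,
        )
        assert got == expected, f"trial {trial}"


def test_scan_properties(rng):
    """Each reported segment starts/ends on a match, contains no masked
    column, contains a qualifying window, and raising the threshold only
    shrinks segments into segments at the lower threshold."""
    for trial in range(100):
        ncols = int(rng.integers(30, 200))
        block = make_block(rng, ncols=ncols, match_prob=0.85)
        mask = rng.random(ncols) < 0.05
        match = match_vector(block)
        lo = cs.ScanParams(window=10, identity_pct=70)
        hi = cs.ScanParams(window=10, identity_pct=90)
        segs_lo = cs.scan_block(block, mask, lo)
        segs_hi = cs.scan_block(block, mask, hi)
        for s, e, m in segs_lo:
            assert match[s] and match[e - 1]
            assert not mask[s:e].any()
            assert m == int(match[s:e].sum())
            # a qualifying window overlaps the (trimmed) span
            assert any(
                match[i:i + 10].sum() >= lo.min_matches
                and not mask[i:i + 10].any()
                for i in range(max(0, s - 9), min(ncols - 10, e - 1) + 1)
            )
        for s, e, _ in segs_hi:
            assert any(ls <= s and e <= le for ls, le, _ in segs_lo), (
                "high-threshold segment not contained in a low-threshold one"
            )


# --- segments_to_cnes -----------------------------------------------------

def test_gap_free_span_widths(q_sizes):
    block = perfect_block(60)
    sizes = cs.ChromSizes("b", {"d": 100})
    [cne] = cs.segments_to_cnes(block, [(0, 60, 60)], sizes)
    assert cne.range1.width == 60 and cne.range2.width == 60
    assert cne.identity == 1.0


def test_target_gaps_shrink_range1():
    t_aln = "ACGTA" + "-" * 3 + "CGTACGTA"
    q_aln = "ACGTA" + "GGG" + "CGTACGTA"
    block = cs.AxtBlock(
        index=0,
        target=cs.GenomicRange("a", "c", 100, 113),
        query=cs.GenomicRange("b", "d", 0, 16),
        target_aln=t_aln, query_aln=q_aln, score=0,
    )
    sizes = cs.ChromSizes("b", {"d": 100})
    [cne] = cs.segments_to_cnes(block, [(0, 16, 13)], sizes)
    assert cne.columns == 16
    assert cne.range1.width == 13  # 3 target-gap columns removed
    assert cne.range2.width == 16


def test_coordinates_match_cursor_walk(rng, q_sizes):
    """Materialised ranges equal an explicit per-column cursor walk on
    random gapped blocks, both strands."""
    for trial in range(60):
        strand = "+-"[trial % 2]
        block = make_block(rng, ncols=150, strand=strand, match_prob=0.9)
        params = cs.ScanParams(window=8, identity_pct=75)
        segments = cs.scan_block(block, None, params)
        cnes = cs.segments_to_cnes(block, segments, q_sizes)
        for (s, e, m), cne in zip(segments, cnes):
            # cursor walk
            t_pos, q_pos = block.target.start, block.query.start
            t_cols, q_cols = [], []
            for col in range(block.ncols):
                if s <= col < e:
                    if block.target_aln[col] != "-":
                        t_cols.append(t_pos)
                    if block.query_aln[col] != "-":
                        q_cols.append(q_pos)
                if block.target_aln[col] != "-":
                    t_pos += 1
                if block.query_aln[col] != "-":
                    q_pos += 1
            assert (cne.range1.start, cne.range1.end) == (t_cols[0], t_cols[-1] + 1)
            if strand == "+":
                assert (cne.range2.start, cne.range2.end) == (q_cols[0], q_cols[-1] + 1)
            else:
                size = q_sizes["chrQ"]
                assert (cne.range2.start, cne.range2.end) == (
                    size - (q_cols[-1] + 1), size - q_cols[0])
            assert cne.matches == m
            assert cne.strand_pair == strand


# --- scan_axt -------------------------------------------------------------

def test_scan_axt_empty():
    sizes = cs.ChromSizes("b", {"d": 100})
    assert cs.scan_axt([], None, None, cs.ScanParams(10, 80), sizes) == []


def test_scan_axt_concatenates_per_block(rng, q_sizes):
    blocks = [make_block(rng, ncols=120, index=i, match_prob=0.9)
              for i in range(8)]
    params = cs.ScanParams(window=10, identity_pct=80)
    got = cs.scan_axt(blocks, None, None, params, q_sizes)
    expected = []
    for b in blocks:
        expected.extend(
            cs.segments_to_cnes(b, cs.scan_block(b, None, params), q_sizes)
        )
    assert got == expected
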