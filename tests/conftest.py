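"""Shared fixtures and random-structure builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cnescan import AxtBlock, ChromSizes, GenomicRange

BASES = "ACGT"


def random_alignment(rng: np.random.Generator, ncols: int, gap_prob: float = 0.1,
                     match_prob: float = 0.7, n_prob: float = 0.02):
    """A random gapped alignment pair with no double-gap columns."""
    t_chars, q_chars = [], []
    for _ in range(ncols):
        r = rng.random()
        if r < gap_prob / 2:
            t_chars.append("-")
            q_chars.append(BASES[rng.integers(4)])
        elif r < gap_prob:
            t_chars.append(BASES[rng.integers(4)])
            q_chars.append("-")
        else:
            t = BASES[rng.integers(4)]
            if rng.random() < n_prob:
                t = "N"
            if rng.random() < match_prob:
                q = t
            else:
                q = BASES[rng.integers(4)]
            # random case to exercise case-insensitivity
            if rng.random() < 0.2:
                t = t.lower()
            if rng.random() < 0.2:
                q = q.lower()
            t_chars.append(t)
            q_chars.append(q)
    return "".join(t_chars), "".join(q_chars)


def make_block(rng: np.random.Generator, ncols: int = 100, index: int = 0,
               t_chrom: str = "chrT", q_chrom: str = "chrQ",
               strand: str = "+", q_size: int = 10_000, **aln_kw) -> AxtBlock:
    """A valid random AxtBlock whose ranges are consistent with its rows."""
    t_aln, q_aln = random_alignment(rng, ncols, **aln_kw)
    t_w = len(t_aln) - t_aln.count("-")
    q_w = len(q_aln) - q_aln.count("-")
    # re-roll degenerate all-gap rows
    while t_w == 0 or q_w == 0:
        t_aln, q_aln = random_alignment(rng, ncols, **aln_kw)
        t_w = len(t_aln) - t_aln.count("-")
        q_w = len(q_aln) - q_aln.count("-")
    t_start = int(rng.integers(0, 1000))
    q_start = int(rng.integers(0, q_size - q_w))
    return AxtBlock(
        index=index,
        target=GenomicRange("asm1", t_chrom, t_start, t_start + t_w, "+"),
        query=GenomicRange("asm2", q_chrom, q_start, q_start + q_w, strand),
        target_aln=t_aln,
        query_aln=q_aln,
        score=int(rng.integers(0, 100_000)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)


@pytest.fixture
def q_sizes() -> ChromSizes:
    return ChromSizes("asm2", {"chrQ": 10_000})
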