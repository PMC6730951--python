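"""Synthetic fixture generator: determinism, validity, exact truth."""

import numpy as np
import pytest

import cnescan as cs


def test_deterministic_under_seed(tmp_path):
    spec = [cs.PlantSpec(length=60), cs.PlantSpec(length=80, orientation="-"),
            cs.PlantSpec(length=70, copies=2)]
    d1, d2 = tmp_path / "a", tmp_path / "b"
    cs.generate_pair(spec, seed=123, genome_lengths=(30_000, 50_000),
                     n_decoys=2, out_dir=str(d1))
    cs.generate_pair(spec, seed=123, genome_lengths=(30_000, 50_000),
                     n_decoys=2, out_dir=str(d2))
    for name in ("genome1.fa", "genome2.fa", "genome1.genome2.net.axt",
                 "genome2.genome1.net.axt", "filter1.bed", "filter2.bed",
                 "genome1.sizes", "genome2.sizes", "truth.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
    different = cs.generate_pair(spec, seed=124,
                                 genome_lengths=(30_000, 50_000), n_decoys=2)
    pair = cs.generate_pair(spec, seed=123,
                            genome_lengths=(30_000, 50_000), n_decoys=2)
    assert different.genome1 != pair.genome1


def test_generated_axt_passes_validation(tmp_path):
    """Written Axt re-reads into blocks identical to the in-memory ones,
    and every block satisfies the format invariants (checked on
    construction)."""
    pair = cs.generate_pair(
        [cs.PlantSpec(length=60, orientation="-"), cs.PlantSpec(length=90)],
        seed=5, genome_lengths=(20_000, 20_000), n_decoys=1,
        out_dir=str(tmp_path),
    )
    again_12 = cs.read_axt(str(tmp_path / "genome1.genome2.net.axt"),
                           "genome1", "genome2", chrom_sizes=pair.sizes2)
    again_21 = cs.read_axt(str(tmp_path / "genome2.genome1.net.axt"),
                           "genome2", "genome1", chrom_sizes=pair.sizes1)
    assert again_12 == pair.axt_12
    assert again_21 == pair.axt_21


def test_alignment_consistent_with_genomes():
    """Block rows are literal genome substrings (reverse-complemented on
    the '-' strand), so the alignment and FASTA outputs agree."""
    from Bio.Seq import reverse_complement

    pair = cs.generate_pair(
        [cs.PlantSpec(length=60, orientation="-"), cs.PlantSpec(length=90)],
        seed=8, genome_lengths=(20_000, 24_000),
    )
    g1, g2 = pair.genome1["chr1"], pair.genome2["chr2"]
    L2 = len(g2)
    for b in pair.axt_12:
        assert b.target_aln.replace("-", "") == g1[b.target.start:b.target.end]
        if b.query.strand == "+":
            assert b.query_aln.replace("-", "") == g2[b.query.start:b.query.end]
        else:
            fwd = g2[L2 - b.query.end:L2 - b.query.start]
            assert b.query_aln.replace("-", "") == reverse_complement(fwd)


def test_truth_identity_realized_exactly():
    """Mismatch counts are placed, not sampled: the realized identity is
    within 2 points of the requested one and matches the alignment."""
    from cnescan.scanner import match_vector

    pair = cs.generate_pair(
        [cs.PlantSpec(length=100, identity=90.0),
         cs.PlantSpec(length=60, identity=95.0)],
        seed=6, genome_lengths=(20_000, 20_000),
    )
    block = pair.axt_12[0]
    match = match_vector(block)
    for t, spec in zip(pair.truth, (90.0, 95.0)):
        assert abs(t.realized_identity - spec) <= 2.0
        s, e = t.range1.start, t.range1.end
        realized = 100.0 * match[s:e].sum() / (e - s)
        assert realized == pytest.approx(t.realized_identity)


def test_background_identity_is_calibrated():
    pair = cs.generate_pair([], background_identity=70.0,
                            genome_lengths=(50_000, 50_000), seed=2)
    from cnescan.scanner import match_vector

    frac = match_vector(pair.axt_12[0]).mean()
    assert abs(frac - 0.70) < 0.02  # binomial noise at n=50k


def test_overlapping_plants_raise():
    with pytest.raises(ValueError, match="overlap"):
        cs.generate_pair(
            [cs.PlantSpec(length=100, position=1000),
             cs.PlantSpec(length=100, position=1050)],
            seed=1, genome_lengths=(20_000, 20_000),
        )


def test_plant_spec_validation():
    with pytest.raises(ValueError):
        cs.PlantSpec(length=0)
    with pytest.raises(ValueError):
        cs.PlantSpec(length=50, identity=40)
    with pytest.raises(ValueError):
        cs.PlantSpec(length=50, copies=0)
    with pytest.raises(ValueError):
        cs.PlantSpec(length=50, orientation="x")


def test_decoys_are_masked_and_otherwise_detectable():
    """Decoy regions align perfectly, so scanning without filters reports
    them and scanning with filters does not — the mask is load-bearing."""
    pair = cs.generate_pair([], seed=4, genome_lengths=(30_000, 30_000),
                            n_decoys=3, decoy_length=400)
    params = cs.ScanParams(window=50, identity_pct=100)
    sizes = {"genome1": pair.sizes1, "genome2": pair.sizes2}
    unfiltered = cs.scan_axt(pair.axt_12, None, None, params, pair.sizes2)
    assert len(unfiltered) == 3
    filtered = cs.scan_axt(pair.axt_12, pair.filter1, pair.filter2,
                           params, pair.sizes2)
    assert filtered == []


def test_filter_overlapping_plant_is_not_recovered():
    pair = cs.generate_pair(
        [cs.PlantSpec(length=80), cs.PlantSpec(length=80, overlap_filter=True)],
        seed=10, genome_lengths=(20_000, 20_000),
    )
    params = cs.ScanParams(window=50, identity_pct=100)
    cnes = cs.scan_axt(pair.axt_12, pair.filter1, pair.filter2,
                       params, pair.sizes2)
    assert len(cnes) >= 1  # the clean plant is still found
    masked_truth = pair.truth[1]
    masked_pos = (masked_truth.range1.start + masked_truth.range1.end) // 2
    for c in cnes:
        assert not (c.range1.start <= masked_pos < c.range1.end), (
            "reported element covers an annotation-masked position"
        )
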