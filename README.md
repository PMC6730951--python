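# cnescan

Detection and exploration of **conserved noncoding elements (CNEs)** from
pairwise whole-genome net alignments.

CNEs are short genomic segments showing extreme sequence conservation
between distantly related species, located outside exons and repeats. They
cluster around developmental regulator genes into *genomic regulatory
blocks* (GRBs) whose extents coincide with topologically associating
domains. `cnescan` is for comparative and regulatory genomicists who want
to call CNE sets for an arbitrary species pair — including draft genome
assemblies — and turn them into genome-browser tracks, cluster calls and
horizon-plot data.

## Method

The detector slides a fixed window of `C` alignment columns along each
block of an Axt net alignment with a step of one column. A window
*qualifies* when

* it contains no column overlapping an annotated exon or repeat on either
  assembly, and
* it contains at least `ceil(I/100 · C)` matched columns, where a match is
  the same A/C/G/T nucleotide in both rows (gaps and N count as
  mismatches).

Thresholds are conventionally written `matches/window`: 21/30 is 70%
identity over 30 bp, 49/50 is 98% over 50 bp, 48/50 is 96% over 50 bp.
Overlapping qualifying windows are unioned into maximal segments, which
are trimmed to matched end columns and materialised as paired genomic
ranges on the two assemblies.

Because a net alignment keeps only the best match per reference region, a
single scan misses legitimate 1:many orthology created by whole-genome
duplication. `cnescan` therefore scans **both** net orientations (each
genome as reference in turn), merges element pairs that overlap on *both*
assemblies with equal orientation, and keeps pairs overlapping on only one
assembly — those are the paralogs. Finally, elements whose sequence occurs
more than `max_hits` times in either genome (exact occurrence counting of
the sequence and its reverse complement; or hit counts parsed from an
external aligner's PSL output) are discarded as repeat-derived. The
remainder is the reliable CNE set, persisted in SQLite.

Downstream, CNE **density** (percent of a smoothing window covered by the
union of CNEs) exports to bedGraph/bigWig, single-linkage gap chaining
calls GRB-like **clusters**, and the **horizon transform** slices density
into stacked clipped bands (band *i* holds `clip(v − i·h, 0, h)`) to widen
the dynamic range of density visualisation.

A synthetic-fixture generator (`cnescan.generate_pair`) builds genome
pairs with planted elements, decoy repeats and paralog copies — with exact,
deterministic ground truth — so the whole pipeline is testable without any
genome downloads or external aligners.

## Worked example

```sh
python examples/01_detect_cnes.py
```

prints

```
scanning at 50/50 (100% over 50 bp)
orientation 1 -> 2: 12 elements
orientation 2 -> 1: 12 elements
after merge:        12 elements
after hit filter:   12 elements (planted: 12)
  chr1:300-383 <-> chr2:300-383 identity 1.00
  chr1:6550-6635 <-> chr2:6550-6635 identity 1.00
  chr1:12800-12902 <-> chr2:12800-12902 identity 1.00
```

Twelve perfectly conserved elements were planted in a 100 kb synthetic
genome pair over a 70%-identity background with decoy repeats; the
pipeline recovers exactly the twelve planted loci and nothing else. Each
output line pairs a genome1 interval with its conserved genome2 partner.
The other examples cover density/horizon tracks (`02`), cluster calling
and cumulative distributions (`03`) and alignment QC (`04`).

The same pipeline is scriptable from a shell:

```sh
cnescan simulate --seed 5 --out-dir fix
cnescan scan --axt-12 fix/genome1.genome2.net.axt \
             --axt-21 fix/genome2.genome1.net.axt \
             --filter1 fix/filter1.bed --filter2 fix/filter2.bed \
             --sizes1 fix/genome1.sizes --sizes2 fix/genome2.sizes \
             --assembly1 genome1 --assembly2 genome2 \
             --identity 100 --window 50 --out cne.db
cnescan export --store cne.db --table cne_genome1_genome2_100_50 \
               --which genome1 --bed cnes.bed
```

For real comparisons, produce the two net Axt files upstream with the
standard UCSC-style pipeline (LASTZ/LAST → chaining → netting → Axt, run
once per reference choice) and extract exon/repeat BED files from your
annotation source; `cnescan` takes over from there.

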