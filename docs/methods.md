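# Methods

## The scanning model

The unit of input is an Axt net alignment block: a gap-padded pair of
sequences with target coordinates always on the '+' strand and query
coordinates given, for '-' strand blocks, on the reverse-complemented
query (the UCSC convention). Internally every coordinate is 0-based
half-open; the 1-based inclusive convention exists only at the Axt text
boundary. Query '-' coordinates are stored exactly as read and reflected
through the chromosome length (`start' = L − end`, `end' = L − start`)
only when a forward-strand interval is needed; this keeps Axt round-trips
byte-exact and makes the projection an involution.

Detection slides a window of `C` alignment columns with step one column.
Definitions, chosen so that every reported element is defensible:

* **Match** — identical A/C/G/T in both rows, case-insensitive. N (or any
  ambiguity code) never matches, including N–N: ambiguity is not evidence
  of conservation. Gap columns occupy a window slot and contribute no
  match, so the window is fixed-width in column space and indels dilute
  identity rather than being silently skipped.
* **Threshold** — a window needs `ceil(I/100 · C)` matches. The ceiling is
  computed with exact rational arithmetic (`Fraction`); naive binary
  floating point turns 70% of 30 into 21.000000000000004 and would demand
  22 matches instead of 21.
* **Masking** — a window containing *any* column whose target or
  (forward-projected) query base lies in an exon/repeat interval is
  disqualified entirely, rather than counting masked columns as
  mismatches. This is the stronger reading of "skipped", and it guarantees
  the output never overlaps annotation — an invariant the tests assert. A
  gap contributes no mask on its own side, only through the other row.
* **Segment formation** — qualifying windows whose spans share at least
  one column are unioned into maximal segments; each segment is trimmed so
  its first and last columns are matches (untrimmed flanks would deflate
  reported identity with dangling mismatches). Because merging happens
  after per-window thresholding, a merged segment's aggregate identity can
  dip slightly below `I` in pathological mismatch layouts; what every
  segment does guarantee is that it contains at least one qualifying
  window, begins and ends on a match, and touches no masked column. The
  reference behaviour is pinned by an exhaustive-enumeration oracle test
  over 500 random alignments.

Filter intervals live in per-chromosome sorted merged arrays; point
queries are binary searches on the flattened boundaries (odd insertion
index ⇔ inside). Annotation is the only masking channel — soft-masked
lowercase sequence is parsed verbatim and ignored as such, since repeat
handling is annotation-driven.

## Two-orientation scanning and merging

A net keeps one best alignment per reference region, so paralogy created
by whole-genome duplication is only visible when each genome takes its
turn as reference. Both scans are brought into a common frame (element =
(range1 on assembly 1, forward-projected range2 on assembly 2,
orientation)); swapping the ranges of the second scan is sufficient
because the orientation relation is symmetric. Two elements merge iff
they share both chromosomes, have equal orientation, and overlap on
*both* assemblies; merging repeats to a fixed point (a grown span can
newly overlap a third element). Elements overlapping on one assembly only
are all kept — that is the paralog signal. Opposite-orientation overlaps
are distinct homology statements and never merge.

Per-column data is gone after scanning, so a merged element's statistics
cannot be recomputed: matches and columns are summed, the stored identity
is the minimum of the constituents (conservative), and a `merged` flag is
set.

## Re-alignment multiplicity filter

Elements surviving annotation filtering can still be unannotated repeats.
Each element's sequence (range1's in genome 1, range2's in genome 2) is
counted against its genome — overlapping occurrences of the sequence and
its reverse complement, palindromes counted once — and elements with more
than `max_hits` (default 4) occurrences in either genome are discarded.
The internal counter is exact string matching, appropriate for the
perfect or near-perfect identities CNE work targets; for divergence-
tolerant counting, hit counts parsed from an external aligner's PSL
output (records at ≥90% identity by default) can be supplied instead.
Both cutoffs are parameters, not facts: no canonical values exist, and
the defaults are deliberately permissive (a handful of legitimate WGD
copies must survive).

## Density, clusters, horizon bands

Density at a window start is `100 · covered/effective`, where covered is
the bp of the window intersected with the union of CNE intervals and
effective is the window truncated at the chromosome end (truncating the
denominator avoids artificial decay at ends). Defaults: 300 kb window,
step = window/100 — genome-browser-scale smoothing, fully configurable.
bedGraph/bigWig export writes one step-sized interval per window start
carrying that window's value, omitting zeros; with step = window the
export tiles the chromosome and window sums conserve total covered bp
exactly, which is the invariant the tests use.

Clusters are called by single-linkage gap chaining: sorted elements chain
while the gap from the furthest end reached so far is ≤ `max_gap`
(overlapping or contained elements are gap 0), and chains shorter than
`min_elements` are dropped. This is a deliberate simplification with an
assertable contract — it reproduces the visible behaviour (sharp
boundaries around dense arrays) without claiming equivalence to any
specific published boundary algorithm. With `min_elements` = 1 the
cluster count is monotonically non-increasing in `max_gap`; the
minimum-size filter can break that monotonicity (two sub-threshold chains
can merge into one passing cluster), which is why the property is tested
at size 1.

The horizon transform maps a track value `v` to bands
`b_i = clip(v − i·h, 0, h)` for `i = 0..n−1`; bands are overlaid, not
mirrored, since density is non-negative. `Σ b_i = min(v, n·h)` exactly —
the reconstruction identity tested on random tracks. The default height
`max/n` makes the full range representable. Rendering (horizon, dotplot,
cumulative) is a thin matplotlib layer, smoke-tested for valid and
deterministic output only; all numerical content lives in the transform.

## The synthetic generator

`generate_pair` emulates the inputs of a real comparison without any
aligner: genome 1 is uniform random sequence; the aligned portion of
genome 2 mirrors it coordinate-for-coordinate, with background columns
matching independently with probability `background_identity` (default
70%, a plausible neutral-divergence level for the evolutionary distances
where CNE scanning is informative). Planted elements receive an exact
mismatch count (`round((1−I/100)·len)`) at evenly spaced interior
offsets; decoys are perfect-identity regions listed in the filter BEDs,
so they are detected precisely when masking is broken. A guaranteed
mismatch flanks every feature so detected spans equal truth spans
exactly. '-' orientation elements are realized as separate Axt blocks
with reverse-complement query coordinates. Paralog extra copies are
placed in a genome 2 tail region and appear only in the genome2-
referenced net — one block per copy — mimicking net asymmetry; the
genome1-referenced net shows only the primary copy.

What the generator does **not** emulate: indels within the background
(alignments are gap-free except as users construct them), realistic
substitution processes (no transition bias, no CpG effects), base
composition structure, assembly fragmentation, and alignment error.
Passing the planted-recovery tests therefore demonstrates correctness of
the scanning/merging/filtering logic under known truth, not calling
performance on real genomes, where sensitivity is bounded by upstream
alignment quality.

Test and example problem sizes (100 kb genomes, tens of elements, 500
fuzz cases with windows ≤ 12 over ≤ 200 columns) were chosen so exact
oracles — per-base coverage masks, exhaustive window enumeration,
quadratic transitive-closure merging — remain feasible as independent
checks of the optimised implementations.

## Degenerate inputs and tie-breaks

Blocks shorter than the window yield nothing. Blocks with a column gapped
in both rows are rejected at parse time (no aligner emits them; they
poison identity accounting). Empty filter = nothing masked; unknown
chromosome in a filter query = unmasked; unknown chromosome in a size
lookup is an error. Element order everywhere is (chrom1, start1, end1,
chrom2, start2, end2, orientation), making outputs deterministic.
SQLite persistence stores one table per (assembly pair, identity, window)
plus a metadata table; identity values that are whole numbers are encoded
without a decimal part in table names.
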