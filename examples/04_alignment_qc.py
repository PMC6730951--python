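"""Alignment-level quality control: match composition and synteny segments.

The base-by-base match matrix shows how often each target base aligns to
each query base — closely related genomes have a heavy diagonal. Synteny
segments are the (target, query) block ranges a dotplot draws.
"""

import cnescan as cs

pair = cs.generate_pair(
    [cs.PlantSpec(length=80)], background_identity=85.0,
    genome_lengths=(30_000, 30_000), seed=4,
)

comp = cs.match_composition_frame(pair.axt_12)
total = comp.values.sum()
diag = sum(comp.values[i, i] for i in range(4))
print("match composition (counts of target base vs query base):")
print(comp.to_string())
print(f"diagonal fraction: {diag / total:.3f} "
      "(matched bases / gapless columns; ~0.85 by construction)")

segs = cs.synteny_segments(pair.axt_12, pair.sizes2, min_len=0)
print(f"{len(segs)} syntenic segment(s):")
for target, query in segs:
    print(f"  {target.chrom}:{target.start}-{target.end} ~ "
          f"{query.chrom}:{query.start}-{query.end}")
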