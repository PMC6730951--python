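"""CNE density track, bedGraph export and horizon-plot bands.

Density is the percentage of a smoothing window covered by the union of
CNEs. The horizon transform slices that signal into stacked clipped bands
so low peaks stay visible next to tall ones.
"""

import os
import tempfile

import numpy as np

import cnescan as cs

# a clustered CNE landscape: two dense clusters plus scattered elements
starts = sorted(
    [20_000 + 400 * i for i in range(25)]     # dense cluster
    + [70_000 + 900 * i for i in range(10)]   # looser cluster
    + list(np.random.default_rng(2).integers(0, 95_000, 8))
)
elements = [
    cs.CNE(
        range1=cs.GenomicRange("genome1", "chr1", s, s + 80, "+"),
        range2=cs.GenomicRange("genome2", "chr2", s, s + 80, "+"),
        strand_pair="+", matches=80, columns=80, identity=1.0,
    )
    for s in starts
]
cnes = cs.CNESet("genome1", "genome2", cs.ScanParams(50, 100), elements)
sizes = cs.ChromSizes("genome1", {"chr1": 100_000})

track = cs.compute_density(cnes, "genome1", sizes, window=10_000, step=1000)
starts_arr, values = track.data["chr1"]
print(f"density windows: {len(starts_arr)}, peak {values.max():.1f}% "
      f"at {int(starts_arr[values.argmax()])} bp")

bands = cs.horizon_transform(track, n_bands=3)
print(f"horizon: 3 bands of height {bands.band_height:.2f}% each")
print("band occupancy (non-zero windows per band):",
      [int((bands.data['chr1'][1][i] > 0).sum()) for i in range(3)])
# Higher bands light up only where density exceeds multiples of the band
# height — the dense cluster reaches band 3, the loose one stays lower.

out = tempfile.mkdtemp(prefix="cnescan_example_")
cs.export_track(track, "bedGraph", os.path.join(out, "density.bedGraph"))
cs.render_horizon(bands, os.path.join(out, "horizon.png"))
print(f"wrote {out}/density.bedGraph and {out}/horizon.png")
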