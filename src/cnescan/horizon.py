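"""Horizon-plot band transform and basic figure rendering.

A standard density plot at genome-browser scale hides low peaks next to
tall ones. The horizon transform slices the signal into ``n_bands`` stacked
bands of height ``band_height`` and overlays the clipped slices, extending
the visible dynamic range: band i holds clip(value - i*h, 0, h). Density is
non-negative, so only positive bands exist (no mirrored negatives). The sum
of the bands reconstructs min(value, n_bands * band_height) exactly — the
transform loses nothing below the top band's ceiling.

All logic lives in :func:`horizon_transform`; rendering is a thin
matplotlib layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

from .density import DensityTrack


@dataclass
class HorizonBands:
    """Clipped band values aligned to a density track's windows."""

    n_bands: int
    band_height: float
    # chrom -> (window starts, band matrix of shape (n_bands, n_windows))
    data: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def reconstruct(self, chrom: str) -> np.ndarray:
        """Sum of bands == original values clipped at n_bands*band_height."""
        return self.data[chrom][1].sum(axis=0)


def horizon_transform(
    track: DensityTrack,
    n_bands: int = 3,
    band_height: float | None = None,
) -> HorizonBands:
    """Slice a density track into stacked clipped bands.

    ``band_height`` defaults to max(track)/n_bands so the full range fits
    exactly in the bands; an all-zero track gets height 1 (bands are then
    all zero anyway).
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if band_height is None:
        peak = max(
            (float(v.max()) for _, v in track.data.values() if v.size), default=0.0
        )
        band_height = peak / n_bands if peak > 0 else 1.0
    if band_height <= 0:
        raise ValueError("band_height must be positive")

    bands = HorizonBands(n_bands=n_bands, band_height=band_height)
    for chrom, (starts, values) in track.data.items():
        mat = np.empty((n_bands, len(values)), dtype=float)
        for i in range(n_bands):
            mat[i] = np.clip(values - i * band_height, 0.0, band_height)
        bands.data[chrom] = (starts.copy(), mat)
    return bands


def _new_figure():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def render_horizon(
    bands: HorizonBands,
    path: str,
    chrom: str | None = None,
    cmap_name: str = "Blues",
) -> None:
    """Overlaid filled bands, darker shades for higher bands. With a single
    band this degenerates to an ordinary area plot."""
    plt = _new_figure()
    fig, ax = plt.subplots(figsize=(10, 2.2))
    chroms = [chrom] if chrom is not None else sorted(bands.data)
    cmap = plt.get_cmap(cmap_name)
    for c in chroms:
        starts, mat = bands.data[c]
        for i in range(bands.n_bands):
            shade = cmap(0.35 + 0.6 * i / max(1, bands.n_bands - 1))
            ax.fill_between(starts, 0, mat[i], step="post", color=shade,
                            linewidth=0)
    ax.set_ylim(0, bands.band_height * 1.05 if bands.band_height else 1)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("density band")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_dotplot(
    segments: Sequence[tuple],
    path: str,
) -> None:
    """Syntenic dotplot from (target range, forward query range) pairs, one
    diagonal segment per alignment block."""
    plt = _new_figure()
    fig, ax = plt.subplots(figsize=(5, 5))
    for target, query in segments:
        ax.plot([target.start, target.end], [query.start, query.end],
                color="tab:blue", linewidth=1)
    ax.set_xlabel("target position (bp)")
    ax.set_ylabel("query position (bp)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_cumulative(
    cumulative: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    path: str,
) -> None:
    """Cumulative CNE count against chromosomal position, one panel track
    per chromosome; sharp rises mark CNE clusters."""
    plt = _new_figure()
    fig, ax = plt.subplots(figsize=(8, 3))
    for chrom in sorted(cumulative):
        x, y = cumulative[chrom]
        ax.step(x, y, where="post", label=chrom)
    if cumulative:
        ax.legend(fontsize=7)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("cumulative CNEs")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
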