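"""GC/AT composition profiles and smoothed density curves with mode detection.

Works on any sequence class (reads, transcripts, exons, introns, genome
segments).  GC is computed over unambiguous bases only; records with no
unambiguous base are flagged and excluded from summaries.  Density curves are
Gaussian-kernel estimates (Silverman's rule bandwidth by default) alongside a
plain histogram; modes are strict local maxima of the smoothed density with a
prominence floor of 5% of the maximum density, reported in descending density
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._seq import encode

MODE_PROMINENCE = 0.05  # fraction of max density a mode must reach


@dataclass(frozen=True)
class CompositionProfile:
    """Per-record GC/AT fractions: columns id, gc, at, n_unambiguous, usable."""

    records: pd.DataFrame = field(repr=False)

    @property
    def usable(self) -> pd.DataFrame:
        return self.records[self.records.usable]


@dataclass(frozen=True)
class DensityCurve:
    grid: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)
    histogram: pd.DataFrame = field(repr=False)
    modes: tuple[float, ...] = ()
    bandwidth: float = 0.0


def per_record_gc(records) -> CompositionProfile:
    """gc = (#G + #C) / (#A + #C + #G + #T) per record, N excluded entirely."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    rows = []
    for r in records:
        codes = encode(r.seq)
        n_valid = int(np.count_nonzero(codes < 4))
        gc_count = int(np.count_nonzero((codes == 1) | (codes == 2)))
        if n_valid > 0:
            gc = gc_count / n_valid
            rows.append((r.id, gc, 1.0 - gc, n_valid, True))
        else:
            rows.append((r.id, np.nan, np.nan, 0, False))
    df = pd.DataFrame(rows, columns=["id", "gc", "at", "n_unambiguous", "usable"])
    return CompositionProfile(records=df)


def density_with_modes(
    profile: CompositionProfile,
    bin_width: float = 0.01,
    bandwidth: float | None = None,
    grid_step: float = 0.002,
) -> DensityCurve:
    """Histogram + Gaussian-KDE density of per-record GC with mode detection.

    ``bandwidth`` is the kernel sd in GC units; None applies Silverman's rule.
    Modes are strict local maxima of the density on the grid, filtered at
    MODE_PROMINENCE of the max, in descending density order.
    """
    gc = profile.usable["gc"].to_numpy()
    if gc.size < 2:
        raise ValueError("density estimation needs at least 2 usable records")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, _ = np.histogram(gc, bins=edges)
    hist = pd.DataFrame({"bin_lower": edges[:-1], "count": counts})
    grid = np.arange(0.0, 1.0 + grid_step, grid_step)

    if np.ptp(gc) == 0.0:
        # degenerate: all records identical; the density is a point mass
        density = np.zeros_like(grid)
        i = int(np.argmin(np.abs(grid - gc[0])))
        density[i] = 1.0 / grid_step
        return DensityCurve(
            grid=grid,
            density=density,
            histogram=hist,
            modes=(float(grid[i]),),
            bandwidth=0.0,
        )

    if bandwidth is None:
        kde = gaussian_kde(gc, bw_method="silverman")
    else:
        kde = gaussian_kde(gc, bw_method=bandwidth / np.std(gc, ddof=1))
    density = kde(grid)
    bw = float(kde.factor * np.std(gc, ddof=1))

    interior = np.arange(1, grid.size - 1)
    is_max = (density[interior] > density[interior - 1]) & (
        density[interior] > density[interior + 1]
    )
    cand = interior[is_max]
    cand = cand[density[cand] >= MODE_PROMINENCE * density.max()]
    order = np.argsort(density[cand])[::-1]
    modes = tuple(float(grid[i]) for i in cand[order])
    return DensityCurve(
        grid=grid, density=density, histogram=hist, modes=modes, bandwidth=bw
    )
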