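"""Sliding-window grid shared by diversity, FST and selection-scan tracks.

Windows are 40 kb wide with a 20 kb step, anchored at position 1 of each
chromosome; the last window is truncated at the chromosome end.  With this
overlap every SNP falls in up to two windows.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_WIDTH = 40_000
DEFAULT_STEP = 20_000


@dataclass
class WindowTrack:
    """Per-window statistic values on the fixed grid.

    ``data`` columns: chrom, start, end (1-based inclusive), n_snps, value.
    """

    data: pd.DataFrame
    statistic: str = ""

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def window_grid(chrom_length: int, width: int = DEFAULT_WIDTH,
                step: int = DEFAULT_STEP) -> np.ndarray:
    """(start, end) pairs, 1-based inclusive, truncated at the chromosome end."""
    if chrom_length < 1:
        return np.zeros((0, 2), dtype=np.int64)
    starts = np.arange(1, chrom_length + 1, step, dtype=np.int64)
    ends = np.minimum(starts + width - 1, chrom_length)
    return np.column_stack((starts, ends))


def chrom_sizes(gm) -> dict[str, int]:
    """Chromosome sizes from metadata, falling back to the last SNP position."""
    chroms = gm.variants["chrom"].astype(str)
    pos = gm.variants["pos"].to_numpy()
    sizes: dict[str, int] = {}
    for c in pd.unique(chroms):
        sizes[c] = int(pos[(chroms == c).to_numpy()].max())
    if gm.chrom_lengths:
        for c, ln in gm.chrom_lengths.items():
            sizes[str(c)] = int(ln)
    return sizes


def windowed_statistic(
    chrom: np.ndarray,
    pos: np.ndarray,
    values: np.ndarray,
    sizes: dict[str, int],
    width: int = DEFAULT_WIDTH,
    step: int = DEFAULT_STEP,
    reducer: str = "sum",
    min_snps: int = 0,
) -> pd.DataFrame:
    """Aggregate per-SNP values on the window grid.

    reducer 'sum' keeps empty windows (value 0); 'mean' drops windows with
    fewer than ``min_snps`` contributing SNPs.  NaN values do not contribute.
    """
    out = []
    chrom = np.asarray(chrom, dtype=object).astype(str)
    for c in sizes:
        grid = window_grid(sizes[c], width, step)
        sel = chrom == c
        p = pos[sel]
        v = values[sel]
        ok = ~np.isnan(v)
        p, v = p[ok], v[ok]
        order = np.argsort(p, kind="stable")
        p, v = p[order], v[order]
        csum = np.concatenate(([0.0], np.cumsum(v)))
        for start, end in grid:
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, end, side="right")
            n = int(hi - lo)
            total = csum[hi] - csum[lo]
            if reducer == "sum":
                out.append((c, int(start), int(end), n, float(total)))
            else:
                if n < max(min_snps, 1):
                    continue
                out.append((c, int(start), int(end), n, float(total / n)))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_snps", "value"])
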