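"""Pairwise r², LD-decay curves and PLINK-style LD pruning.

Decay is computed in genotype mode by default (squared Pearson correlation
of alt-dosage vectors over jointly called samples), matching the usual
decay tools; haplotype mode is available for phased data.  Distances up to
1 kb are binned at full (per-bp) resolution, then 1 kb-wide bins out to
500 kb.

Pruning replicates ``--indep-pairwise``: sliding windows of 50 SNPs with a
5-SNP step; in every violating pair the later SNP (by position) is dropped,
making the result deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from ._kernels import ld_decay_kernel, ld_prune_kernel
from .gio import MISSING, GenotypeMatrix, PopulationMap

MAX_DIST_DEFAULT = 500_000


@dataclass
class DecayCurve:
    """Mean r² per distance bin for one population.

    ``data`` columns: bin_start, bin_end (bp, inclusive), mean_r2, n_pairs.
    """

    population: str
    data: pd.DataFrame

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def pair_r2(site_a: np.ndarray, site_b: np.ndarray, mode: str = "genotype") -> float:
    """r² between two sites.

    haplotype mode: inputs are 0/1 haplotype vectors;
    r² = D² / (p_A(1-p_A) p_B(1-p_B)) with D the gametic covariance.
    genotype mode: inputs are dosage vectors with -1 missing; squared
    Pearson correlation over jointly called samples.
    Returns NaN when either site is monomorphic among the considered
    samples.
    """
    a = np.asarray(site_a, dtype=float)
    b = np.asarray(site_b, dtype=float)
    if mode == "haplotype":
        p_a, p_b = a.mean(), b.mean()
        if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
            return float("nan")
        d = (a * b).mean() - p_a * p_b
        return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))
    if mode != "genotype":
        raise ValueError(f"unknown mode {mode!r}")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or np.var(a) == 0 or np.var(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _bin_edges(max_dist: int) -> tuple[np.ndarray, np.ndarray]:
    starts_fine = np.arange(1, 1001)
    ends_fine = starts_fine.copy()
    n_coarse = (max_dist - 1000 + 999) // 1000
    starts_coarse = 1001 + 1000 * np.arange(n_coarse)
    ends_coarse = np.minimum(starts_coarse + 999, max_dist)
    return (np.concatenate([starts_fine, starts_coarse]),
            np.concatenate([ends_fine, ends_coarse]))


def ld_decay(
    gm: GenotypeMatrix,
    pop_map: PopulationMap | None = None,
    population: str | None = None,
    max_dist: int = MAX_DIST_DEFAULT,
    sample_fraction: float = 1.0,
    seed: int = 0,
) -> DecayCurve:
    """Mean genotype r² against distance for all intra-chromosomal pairs
    within ``max_dist``.

    ``sample_fraction`` < 1 subsamples pairs for desk-scale runtime; a
    warning notes when it is active.
    """
    if population is not None:
        idx = pop_map.indices(gm, population)
        if len(idx) < 2:
            raise ValueError("population needs at least 2 samples")
        calls = gm.calls[idx]
    else:
        calls = gm.calls
    if sample_fraction < 1.0:
        warnings.warn(f"LD decay subsampling pairs at fraction {sample_fraction}",
                      stacklevel=2)
    n_bins = 1000 + (max_dist - 1000 + 999) // 1000
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    chrom = gm.variants["chrom"].astype(str).to_numpy()
    pos = gm.variants["pos"].to_numpy(dtype=np.int64)
    state = np.array([seed * 2654435761 + 1], dtype=np.uint64)
    for c in pd.unique(chrom):
        sel = chrom == c
        G = np.ascontiguousarray(calls[:, sel])
        ld_decay_kernel(G, pos[sel], max_dist, sums, counts,
                        float(sample_fraction), state)
    starts, ends = _bin_edges(max_dist)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    data = pd.DataFrame({
        "bin_start": starts, "bin_end": ends,
        "mean_r2": means, "n_pairs": counts,
    })
    data = data[data["n_pairs"] > 0].reset_index(drop=True)
    return DecayCurve(population=population or "all", data=data)


def ld_prune(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Indices of SNPs retained by the greedy sliding-window prune.

    Within each 50-SNP window every pair with genotype r² > ``r2_max``
    drops the later SNP; the window advances by ``step`` SNPs.  The scan is
    repeated over the surviving SNPs until nothing changes, so pruning the
    pruned set again is a no-op and no within-window pair of survivors
    violates the threshold.
    """
    chrom = gm.variants["chrom"].astype(str).to_numpy()
    kept_all = np.ones(gm.n_variants, dtype=bool)
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        live = sel
        for _ in range(100):
            G = np.ascontiguousarray(gm.calls[:, live])
            kept = np.ones(len(live), dtype=np.bool_)
            ld_prune_kernel(G, kept, window, step, r2_max)
            if kept.all():
                break
            kept_all[live[~kept]] = False
            live = live[kept]
    return np.flatnonzero(kept_all)
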