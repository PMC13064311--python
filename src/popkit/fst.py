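"""Weir–Cockerham variance-component FST (two populations).

Per-site components a (among populations), b (among individuals within
populations) and c (within individuals) follow the classic
variance-component estimator for r = 2 sampled populations with observed
heterozygote fractions; the "weighted" window and genome-wide values are
ratio-of-sums, sum(a) / sum(a+b+c), never means of per-window ratios.
Negative estimates are reported as computed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gio import MISSING, GenotypeMatrix, PopulationMap
from .windows import DEFAULT_STEP, DEFAULT_WIDTH, WindowTrack, chrom_sizes, window_grid


@dataclass
class SiteComponents:
    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        return self.a / denom if denom != 0 else float("nan")


def wc_components(
    pop1: tuple[float, float, float],
    pop2: tuple[float, float, float],
) -> SiteComponents:
    """Variance components for one biallelic site.

    Each population is (n diploids with calls, alt frequency p, observed
    heterozygote fraction h).  Monomorphic-across-both sites return
    (0, 0, 0), flagged uninformative by the caller.
    """
    n1, p1, h1 = pop1
    n2, p2, h2 = pop2
    if n1 < 2 or n2 < 2:
        raise ValueError("both populations need at least 2 diploids")
    a, b, c = _components_arrays(
        np.array([n1]), np.array([p1]), np.array([h1]),
        np.array([n2]), np.array([p2]), np.array([h2]),
    )
    return SiteComponents(float(a[0]), float(b[0]), float(c[0]))


def _components_arrays(n1, p1, h1, n2, p2, h2):
    """Vectorised a, b, c for r = 2 populations (the formulae keep r
    symbolic for readability)."""
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
    c = h_bar / 2.0
    mono = (p_bar == 0.0) | (p_bar == 1.0)
    a = np.where(mono, 0.0, a)
    b = np.where(mono, 0.0, b)
    c = np.where(mono, 0.0, c)
    return a, b, c


def _pop_site_stats(gm: GenotypeMatrix, idx: np.ndarray):
    sub = gm.calls[idx]
    called = sub != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(called, sub, 0).sum(axis=0) / (2.0 * n)
        h = (sub == 1).sum(axis=0) / n
    return n, p, h


def site_components(
    gm: GenotypeMatrix, pop_map: PopulationMap, pop_a: str, pop_b: str
):
    """Per-site (a, b, c) arrays plus an informative-site mask.

    Sites where either population has fewer than 2 called diploids, or that
    are monomorphic across both populations, are uninformative.
    """
    idx_a = pop_map.indices(gm, pop_a)
    idx_b = pop_map.indices(gm, pop_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("both populations need at least 2 samples")
    n1, p1, h1 = _pop_site_stats(gm, idx_a)
    n2, p2, h2 = _pop_site_stats(gm, idx_b)
    ok = (n1 >= 2) & (n2 >= 2)
    safe = lambda x: np.where(ok, x, 0.0)  # noqa: E731
    a, b, c = _components_arrays(safe(n1) + 2 * ~ok, safe(p1), safe(h1),
                                 safe(n2) + 2 * ~ok, safe(p2), safe(h2))
    mono = np.zeros_like(ok)
    with np.errstate(invalid="ignore"):
        p_pool = (n1 * p1 + n2 * p2) / (n1 + n2)
    mono = (p_pool == 0.0) | (p_pool == 1.0)
    informative = ok & ~mono
    a = np.where(informative, a, 0.0)
    b = np.where(informative, b, 0.0)
    c = np.where(informative, c, 0.0)
    return a, b, c, informative


def windowed_fst(
    gm: GenotypeMatrix,
    pop_map: PopulationMap,
    pop_a: str,
    pop_b: str,
    width: int = DEFAULT_WIDTH,
    step: int = DEFAULT_STEP,
) -> tuple[WindowTrack, float]:
    """Weighted FST per window plus the genome-wide ratio-of-sums value.

    Windows with no informative site get NaN.
    """
    a, b, c, informative = site_components(gm, pop_map, pop_a, pop_b)
    denom_site = a + b + c
    chrom = gm.variants["chrom"].astype(str).to_numpy()
    pos = gm.variants["pos"].to_numpy()
    sizes = chrom_sizes(gm)
    rows = []
    for ch, size in sizes.items():
        sel = chrom == ch
        p = pos[sel]
        av, dv, iv = a[sel], denom_site[sel], informative[sel]
        order = np.argsort(p, kind="stable")
        p, av, dv, iv = p[order], av[order], dv[order], iv[order]
        ca = np.concatenate(([0.0], np.cumsum(av)))
        cd = np.concatenate(([0.0], np.cumsum(dv)))
        ci = np.concatenate(([0], np.cumsum(iv.astype(int))))
        for start, end in window_grid(size, width, step):
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, end, side="right")
            n_inf = int(ci[hi] - ci[lo])
            num = ca[hi] - ca[lo]
            den = cd[hi] - cd[lo]
            val = num / den if n_inf > 0 and den != 0 else float("nan")
            rows.append((ch, int(start), int(end), n_inf, val))
    track = WindowTrack(
        data=pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "value"]),
        statistic=f"fst_weighted[{pop_a},{pop_b}]",
    )
    total_den = float(denom_site[informative].sum())
    genome_wide = float(a[informative].sum() / total_den) if total_den else float("nan")
    return track, genome_wide


def pairwise_matrix(
    gm: GenotypeMatrix,
    pop_map: PopulationMap,
    chrom: str | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of genome-wide weighted FST over all population pairs.

    Pairs involving a population with fewer than 2 samples are NaN; the
    diagonal is 0.  With ``chrom`` the matrix is restricted to a single
    chromosome (per-chromosome differentiation profiles).
    """
    pops = pop_map.populations()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    if chrom is not None:
        sel = np.flatnonzero(gm.variants["chrom"].astype(str) == str(chrom))
        gm = gm.take_variants(sel)
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            try:
                _, value = windowed_fst(gm, pop_map, pa, pb)
            except ValueError:
                value = float("nan")
            mat.loc[pa, pb] = mat.loc[pb, pa] = value
    return mat
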