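"""Nucleotide diversity, heterozygosity and method-of-moments inbreeding.

Windowed pi follows the VCFtools convention: per-site mean pairwise
difference summed over the SNPs in a 40 kb window and divided by the full
window span in bp (invariant positions count in the denominator), reported
in percent.  Individual heterozygosity and the method-of-moments F follow
the ``--het`` convention: expected homozygosity per site uses the unbiased
2p(1-p)·n/(n-1) with allele frequencies from the analysed sample set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gio import MISSING, GenotypeMatrix, PopulationMap, allele_counts
from .windows import DEFAULT_STEP, DEFAULT_WIDTH, WindowTrack, chrom_sizes, window_grid


@dataclass
class IndividualHet:
    """Per-sample homozygosity bookkeeping.

    O_hom / E_hom are observed and expected homozygous site counts over the
    S called polymorphic sites; H_o = 1 - O_hom/S;
    F = (O_hom - E_hom)/(S - E_hom), NaN when S == E_hom.
    """

    sample: str
    o_hom: float
    e_hom: float
    s: int
    h_o: float
    f: float


def site_pi(n_alt: np.ndarray, n_called: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference 2·a·(n-a)/(n·(n-1)).

    Sites with fewer than two called alleles get NaN (caller excludes).
    """
    n_alt = np.asarray(n_alt, dtype=float)
    n_called = np.asarray(n_called, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * n_alt * (n_called - n_alt) / (n_called * (n_called - 1.0))
    return np.where(n_called >= 2, pi, np.nan)


def windowed_pi(
    gm: GenotypeMatrix,
    pop_map: PopulationMap | None = None,
    population: str | None = None,
    width: int = DEFAULT_WIDTH,
    step: int = DEFAULT_STEP,
) -> WindowTrack:
    """Nucleotide diversity per sliding window, in percent of the span."""
    n_alt, n_called = allele_counts(gm, pop_map, population)
    pi = site_pi(n_alt, n_called)
    pi = np.nan_to_num(pi, nan=0.0)
    chrom = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    sizes = chrom_sizes(gm)
    rows = []
    for c, size in sizes.items():
        sel = chrom.astype(str) == c
        p = pos[sel]
        v = pi[sel]
        order = np.argsort(p, kind="stable")
        p, v = p[order], v[order]
        csum = np.concatenate(([0.0], np.cumsum(v)))
        for start, end in window_grid(size, width, step):
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, end, side="right")
            span = end - start + 1
            rows.append((c, int(start), int(end), int(hi - lo),
                         100.0 * (csum[hi] - csum[lo]) / span))
    data = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "value"])
    return WindowTrack(data=data, statistic="pi_percent")


def _expected_hom_per_site(n_alt: np.ndarray, n_called: np.ndarray) -> np.ndarray:
    """1 - 2p(1-p)·n/(n-1), the per-site expected homozygosity."""
    n_alt = np.asarray(n_alt, dtype=float)
    n = np.asarray(n_called, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = n_alt / n
        e_het = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return 1.0 - e_het


def individual_het(gm: GenotypeMatrix) -> list[IndividualHet]:
    """O_hom, E_hom, H_o and method-of-moments F per sample.

    Allele frequencies come from all called genotypes of the analysed set;
    only sites polymorphic within the set contribute.  E_hom for a sample
    sums the per-site expectation over the sites at which that sample is
    called.
    """
    if gm.n_samples < 2:
        raise ValueError("individual heterozygosity needs at least 2 samples")
    n_alt, n_called = allele_counts(gm)
    poly = (n_alt > 0) & (n_alt < n_called) & (n_called >= 2)
    e_site = _expected_hom_per_site(n_alt, n_called)
    calls = gm.calls
    called = calls != MISSING
    use = called & poly[None, :]
    o_hom = (use & (calls != 1)).sum(axis=1).astype(float)
    s = use.sum(axis=1)
    e_hom = np.where(use, e_site[None, :], 0.0).sum(axis=1)
    out = []
    for i, name in enumerate(gm.samples):
        si = int(s[i])
        h_o = 1.0 - o_hom[i] / si if si else np.nan
        denom = si - e_hom[i]
        f = (o_hom[i] - e_hom[i]) / denom if denom != 0 and si else np.nan
        out.append(IndividualHet(sample=name, o_hom=float(o_hom[i]),
                                 e_hom=float(e_hom[i]), s=si, h_o=h_o, f=f))
    return out


def population_He(
    gm: GenotypeMatrix, pop_map: PopulationMap, population: str
) -> float:
    """Mean unbiased expected heterozygosity over within-population
    polymorphic sites; NaN when the population is monomorphic."""
    idx = pop_map.indices(gm, population)
    sub = gm.take_samples(idx)
    n_alt, n_called = allele_counts(sub)
    poly = (n_alt > 0) & (n_alt < n_called) & (n_called >= 2)
    if not poly.any():
        return float("nan")
    e_het = 1.0 - _expected_hom_per_site(n_alt[poly], n_called[poly])
    return float(np.mean(e_het))


def n_polymorphic(gm: GenotypeMatrix, pop_map: PopulationMap,
                  population: str) -> int:
    """Sites carrying both alleles within the population."""
    n_alt, n_called = allele_counts(gm, pop_map, population)
    return int(((n_alt > 0) & (n_alt < n_called)).sum())


def shared_private_partition(
    gm: GenotypeMatrix, pop_map: PopulationMap
) -> pd.DataFrame:
    """Assign every SNP to the exact subset of populations where it segregates.

    Returns one row per non-empty subset with columns ``populations``
    (frozenset as a sorted '+'-joined label) and ``n_snps``; 'private to X'
    is the singleton subset of X.  Subset counts sum to the number of SNPs
    polymorphic in at least one population.
    """
    pops = pop_map.populations()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    poly = np.zeros((len(pops), gm.n_variants), dtype=bool)
    for k, p in enumerate(pops):
        n_alt, n_called = allele_counts(gm, pop_map, p)
        poly[k] = (n_alt > 0) & (n_alt < n_called)
    weights = 1 << np.arange(len(pops), dtype=np.int64)
    code = (poly.astype(np.int64) * weights[:, None]).sum(axis=0)
    rows = []
    for c in np.unique(code):
        if c == 0:
            continue
        members = [pops[k] for k in range(len(pops)) if c >> k & 1]
        rows.append(("+".join(sorted(members)), int((code == c).sum())))
    return pd.DataFrame(rows, columns=["populations", "n_snps"])
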