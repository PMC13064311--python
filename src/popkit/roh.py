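"""Runs of homozygosity via a two-state HMM, plus binning and F_ROH.

The HMM has states NORMAL and AUTOZYGOUS.  At a site with within-population
alt frequency p the probability of observing a heterozygote is
2p(1-p)(1-e) + e(1-2p(1-p)) under NORMAL and e under AUTOZYGOUS, where e is
a small genotyping-error rate; homozygous emissions are the complements.
Transitions between adjacent informative markers d bp apart occur with
probability 1 - exp(-t·d) with separate in/out rates.  Viterbi decoding
yields maximal AUTOZYGOUS runs; segment coordinates are the first and last
SNP positions of the run.

Defaults (e_het = 1e-3, t_in = 1e-8 /bp, t_out = 1e-7 /bp) put expected
segment lengths in the Mb range; all three are exposed.

F_ROH divides an individual's total ROH length by the autosomal genome
size (default 960.8 Mb, the chicken autosomal assembly span).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import viterbi2_kernel
from .gio import MISSING, GenotypeMatrix, PopulationMap

DEFAULT_GENOME_SIZE = 960_800_000

#: Table-style length classes in Mb: [0.3,1), [1,2), [2,4), [4,8), [8,10),
#: [10,16), [16,inf)
LENGTH_CLASSES_MB = [(0.3, 1.0), (1.0, 2.0), (2.0, 4.0), (4.0, 8.0),
                     (8.0, 10.0), (10.0, 16.0), (16.0, math.inf)]


@dataclass
class HMMParams:
    e_het: float = 1e-3
    t_in: float = 1e-8   # per bp, NORMAL -> AUTOZYGOUS
    t_out: float = 1e-7  # per bp, AUTOZYGOUS -> NORMAL


@dataclass
class ROHSegment:
    """One autozygous run; coordinates are 1-based inclusive SNP positions."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FrohRecord:
    sample: str
    total_length: int
    genome_size: int = DEFAULT_GENOME_SIZE

    @property
    def f_roh(self) -> float:
        return self.total_length / self.genome_size


def detect_roh(
    gm: GenotypeMatrix,
    sample: str,
    site_freqs: np.ndarray,
    params: HMMParams | None = None,
) -> list[ROHSegment]:
    """Viterbi-decode autozygous runs for one sample.

    ``site_freqs`` are per-variant alt-allele frequencies from the sample's
    own population.  Sites monomorphic in the population (p = 0 or 1) carry
    no evidence and are excluded before decoding; missing calls are skipped
    with the inter-marker distance accumulating across them.
    """
    params = params or HMMParams()
    i = gm.samples.index(sample)
    segments: list[ROHSegment] = []
    chrom_all = gm.variants["chrom"].astype(str).to_numpy()
    pos_all = gm.variants["pos"].to_numpy()
    calls_all = gm.calls[i]
    freqs = np.asarray(site_freqs, dtype=float)
    e = params.e_het
    for c in pd.unique(chrom_all):
        sel = chrom_all == c
        pos = pos_all[sel]
        calls = calls_all[sel]
        p = freqs[sel]
        ok = (calls != MISSING) & (p > 0.0) & (p < 1.0)
        pos, calls, p = pos[ok], calls[ok], p[ok]
        if len(pos) == 0:
            continue
        obs_het = (calls == 1).astype(np.uint8)
        # per-site emissions under NORMAL depend on p; fold them into
        # per-site log emissions rather than a single matrix
        het_n = 2.0 * p * (1.0 - p) * (1.0 - e) + e * (1.0 - 2.0 * p * (1.0 - p))
        path = _viterbi(obs_het, pos, het_n, e, params)
        for s_idx, e_idx in _runs(path):
            segments.append(ROHSegment(
                sample=sample, chrom=str(c), start=int(pos[s_idx]),
                end=int(pos[e_idx]), n_snps=int(e_idx - s_idx + 1)))
    return segments


def _viterbi(obs_het, pos, het_normal, e_het, params):
    """Log-space Viterbi with per-site emissions (wrapper over the kernel).

    The kernel takes a constant emission matrix, so the per-site NORMAL
    emission is folded into the distance terms: we run the kernel with unit
    emissions for NORMAL and add per-site corrections through the stay /
    switch arrays.
    """
    T = len(obs_het)
    d = np.diff(pos, prepend=pos[0]).astype(float)
    p_in = -np.expm1(-params.t_in * d)    # NORMAL -> AUTOZYGOUS
    p_out = -np.expm1(-params.t_out * d)  # AUTOZYGOUS -> NORMAL
    with np.errstate(divide="ignore"):
        log_stay = np.vstack([np.log1p(-p_in), np.log1p(-p_out)])
        log_switch = np.vstack([np.log(p_in), np.log(p_out)])
        # emission corrections, added to every incoming transition:
        # state 0 (NORMAL) emits het with per-site prob het_normal
        em0 = np.where(obs_het == 1, np.log(het_normal), np.log1p(-het_normal))
        em1 = np.where(obs_het == 1, math.log(e_het), math.log1p(-e_het))
    log_stay = log_stay.copy()
    log_switch = log_switch.copy()
    # fold per-site emissions into the transition terms feeding each state
    log_stay[0] += em0
    log_stay[1] += em1
    sw = np.vstack([log_switch[0] + em1, log_switch[1] + em0])
    # stationary initial distribution of the two-rate switch process
    pi_az = params.t_in / (params.t_in + params.t_out)
    init = np.array([math.log1p(-pi_az) + em0[0], math.log(pi_az) + em1[0]])
    emit = np.zeros((2, 2))
    path = viterbi2_kernel(obs_het.astype(np.uint8),
                           np.ascontiguousarray(log_stay),
                           np.ascontiguousarray(sw), emit, init)
    return path


def _runs(path: np.ndarray):
    """(start_idx, end_idx) of maximal state-1 runs."""
    out = []
    in_run = False
    start = 0
    for t, s in enumerate(path):
        if s == 1 and not in_run:
            in_run, start = True, t
        elif s != 1 and in_run:
            out.append((start, t - 1))
            in_run = False
    if in_run:
        out.append((start, len(path) - 1))
    return out


def detect_roh_population(
    gm: GenotypeMatrix,
    pop_map: PopulationMap,
    params: HMMParams | None = None,
    min_called: int = 10,
) -> list[ROHSegment]:
    """Run ROH detection for every sample, with emission frequencies from
    each sample's own population."""
    from .gio import allele_counts

    segments: list[ROHSegment] = []
    for pop in pop_map.populations():
        idx = pop_map.indices(gm, pop)
        if len(idx) == 0:
            continue
        n_alt, n_called = allele_counts(gm, pop_map, pop)
        with np.errstate(invalid="ignore"):
            freqs = np.where(n_called > 0, n_alt / np.maximum(n_called, 1), 0.0)
        for i in idx:
            sample = gm.samples[i]
            if int((gm.calls[i] != MISSING).sum()) < min_called:
                continue
            segments.extend(detect_roh(gm, sample, freqs, params))
    return segments


def filter_roh(
    segments: list[ROHSegment],
    min_len: int = 300_000,
    min_snps: int = 10,
) -> list[ROHSegment]:
    """Keep segments with length >= min_len AND n_snps >= min_snps
    (both bounds inclusive)."""
    return [s for s in segments if s.length >= min_len and s.n_snps >= min_snps]


def f_roh(
    segments: list[ROHSegment],
    sample: str,
    genome_size: int = DEFAULT_GENOME_SIZE,
) -> FrohRecord:
    """Total ROH length of one sample divided by the autosomal genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    total = sum(s.length for s in segments if s.sample == sample)
    return FrohRecord(sample=sample, total_length=total, genome_size=genome_size)


@dataclass
class ROHClassTable:
    """Per-population ROH summary mirroring the usual length-class table."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)


def classify_and_summarize(
    segments: list[ROHSegment],
    pop_map: PopulationMap,
    sample_lists: dict[str, list[str]] | None = None,
) -> ROHClassTable:
    """Length-class means and totals per population.

    Per-individual segment counts are averaged over *all* individuals of a
    population, zero-carriers included; pass ``sample_lists`` to name the
    full membership explicitly (defaults to the popmap).
    """
    if sample_lists is None:
        sample_lists = {p: pop_map.samples_of(p) for p in pop_map.populations()}
    per_sample: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        per_sample.setdefault(seg.sample, []).append(seg)
    rows = []
    for pop, members in sample_lists.items():
        n_ind = len(members)
        if n_ind == 0:
            continue
        lens_mb = []
        class_counts = np.zeros(len(LENGTH_CLASSES_MB))
        totals = []
        n_segs = 0
        for s in members:
            segs = per_sample.get(s, [])
            tot = 0
            for seg in segs:
                mb = seg.length / 1e6
                lens_mb.append(mb)
                tot += seg.length
                for k, (lo, hi) in enumerate(LENGTH_CLASSES_MB):
                    if lo <= mb < hi:
                        class_counts[k] += 1
                        break
            totals.append(tot / 1e6)
            n_segs += len(segs)
        row = {"population": pop, "n_individuals": n_ind}
        for (lo, hi), cnt in zip(LENGTH_CLASSES_MB, class_counts):
            label = f"{lo:g}-{hi:g}Mb" if math.isfinite(hi) else f">{lo:g}Mb"
            row[f"mean_n_{label}"] = cnt / n_ind
        row["min_len_mb"] = min(lens_mb) if lens_mb else 0.0
        row["max_len_mb"] = max(lens_mb) if lens_mb else 0.0
        row["mean_len_mb"] = float(np.mean(lens_mb)) if lens_mb else 0.0
        row["total_len_mb"] = float(np.sum(totals))
        row["mean_total_len_mb"] = float(np.mean(totals))
        row["sd_total_len_mb"] = float(np.std(totals, ddof=1)) if n_ind > 1 else 0.0
        row["mean_n_segments"] = n_segs / n_ind
        rows.append(row)
    return ROHClassTable(data=pd.DataFrame(rows))


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample, s.chrom, s.start, s.end, s.length, s.n_snps) for s in segments],
        columns=["sample", "chrom", "start", "end", "length_bp", "n_snps"],
    )
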