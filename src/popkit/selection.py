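"""Haplotype-based selection scans: EHH, iHS, XP-EHH, outlier regions.

EHH at marker distance x from a core SNP partitions the carriers of the
focal allele by their allele string over [core..x]; EHH(x) is the fraction
of carrier pairs still identical, sum_g C(s_g, 2) / C(n, 2).  iHH is the
trapezoidal integral of EHH against physical position over both flanks,
each truncated where EHH drops below a floor (default 0.05).

iHS = ln(iHH_ancestral / iHH_derived), standardised within derived-allele
frequency bins; XP-EHH = ln(iHH_popA / iHH_popB) with allele-agnostic EHH,
standardised genome-wide.  A positive XP-EHH marks longer haplotypes in the
first-named (reference) population.  Absolute standardised scores are
averaged in 40 kb / 20 kb windows requiring at least 10 scored SNPs, the
top 0.1 % of windows are flagged by a nearest-rank empirical quantile, and
adjacent flagged windows merge into candidate sweep regions that are then
annotated against gene / QTL intervals.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import ihh_kernel
from .gio import GenotypeMatrix, PopulationMap
from .windows import DEFAULT_STEP, DEFAULT_WIDTH, WindowTrack, windowed_statistic

EHH_FLOOR = 0.05
MAF_MIN = 0.05
FREQ_BIN_WIDTH = 0.025


@dataclass
class HaplotypeSet:
    """Phased haplotypes with ancestral/derived orientation.

    ``haps`` is (2*n_samples, n_variants) with 0 = ancestral, 1 = derived
    at sites where the ancestral allele is known (``ancestral_known``);
    elsewhere the coding is REF = 0.  Haplotypes 2i, 2i+1 belong to
    sample i.
    """

    haps: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    populations: list[str]
    ancestral_known: np.ndarray
    chrom_lengths: dict[str, int] | None = None

    @classmethod
    def from_genotypes(cls, gm: GenotypeMatrix, pop_map: PopulationMap
                       ) -> "HaplotypeSet":
        if not gm.phased or gm.haplotypes is None:
            raise ValueError(
                "selection scans need phased, fully called haplotypes")
        pop_map.validate(gm)
        anc = gm.variants["ancestral"].to_numpy()
        known = anc != "unknown"
        haps = gm.haplotypes.copy()
        flip = anc == "alt"   # derived is REF there; recode 0 = ancestral
        haps[:, flip] = 1 - haps[:, flip]
        return cls(
            haps=haps,
            variants=gm.variants[["chrom", "pos"]].copy(),
            samples=list(gm.samples),
            populations=[pop_map.assignments[s] for s in gm.samples],
            ancestral_known=known,
            chrom_lengths=gm.chrom_lengths,
        )

    def rows_of(self, population: str) -> np.ndarray:
        idx = [i for i, p in enumerate(self.populations) if p == population]
        if not idx:
            raise KeyError(f"no samples in population {population!r}")
        return np.ravel(np.column_stack((2 * np.array(idx),
                                         2 * np.array(idx) + 1)))


@dataclass
class EHHCurve:
    core_index: int
    focal_allele: str           # 'ancestral', 'derived' or 'all'
    positions: np.ndarray       # includes the core, EHH 1.0 there
    values: np.ndarray

    def __post_init__(self) -> None:
        assert np.all((self.values >= 0) & (self.values <= 1.0 + 1e-12))


@dataclass
class ScoreTrack:
    """Per-SNP raw and standardised scores for one statistic."""

    statistic: str
    data: pd.DataFrame  # chrom, pos, raw, std
    skipped: int = 0


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    windows: list[tuple[int, int]]
    max_score: float
    mean_score: float
    frac_positive: float = float("nan")
    features: list[str] = field(default_factory=list)
    nearest_feature: str | None = None
    nearest_distance: int | None = None


def _carriers(haps: np.ndarray, rows: np.ndarray, core: int,
              focal_allele: str) -> np.ndarray:
    if focal_allele == "all":
        return rows
    want = 1 if focal_allele == "derived" else 0
    return rows[haps[rows, core] == want]


def ehh(
    hap_set: HaplotypeSet,
    core_index: int,
    focal_allele: str,
    population: str | None = None,
    ehh_floor: float = EHH_FLOOR,
) -> dict[str, EHHCurve]:
    """EHH curves on both flanks of a core SNP.

    Returns {'left': curve, 'right': curve}; each curve starts at the core
    with EHH = 1 and is truncated before the first marker where EHH drops
    below ``ehh_floor``.  Fewer than 2 carriers raises.
    """
    rows = (hap_set.rows_of(population) if population is not None
            else np.arange(hap_set.haps.shape[0]))
    carriers = _carriers(hap_set.haps, rows, core_index, focal_allele)
    if len(carriers) < 2:
        raise ValueError("EHH undefined: fewer than 2 carriers of the focal allele")
    chrom = hap_set.variants["chrom"].astype(str).to_numpy()
    pos = hap_set.variants["pos"].to_numpy(dtype=float)
    on_chr = chrom == chrom[core_index]
    out = {}
    for name, direction in (("right", 1), ("left", -1)):
        ps = [pos[core_index]]
        vs = [1.0]
        grp = np.zeros(len(carriers), dtype=np.int64)
        j = core_index
        n = len(carriers)
        npairs = n * (n - 1) / 2
        while True:
            j += direction
            if j < 0 or j >= len(pos) or not on_chr[j]:
                break
            key = 2 * grp + hap_set.haps[carriers, j]
            _, grp = np.unique(key, return_inverse=True)
            sizes = np.bincount(grp)
            val = float((sizes * (sizes - 1) / 2).sum() / npairs)
            if val < ehh_floor:
                break
            ps.append(pos[j])
            vs.append(val)
            if val == 0.0:
                break
        out[name] = EHHCurve(core_index=core_index, focal_allele=focal_allele,
                             positions=np.array(ps), values=np.array(vs))
    return out


def ihh(curves: dict[str, EHHCurve]) -> float:
    """Trapezoidal integral of EHH against bp, summed over both flanks."""
    total = 0.0
    for curve in curves.values():
        p = curve.positions
        v = curve.values
        if len(p) >= 2:
            total += float(np.abs(np.trapezoid(v, p)))
    return total


def _chrom_blocks(hap_set: HaplotypeSet):
    chrom = hap_set.variants["chrom"].astype(str).to_numpy()
    pos = hap_set.variants["pos"].to_numpy(dtype=np.float64)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        yield c, idx, pos[idx]


def ihs_scan(
    hap_set: HaplotypeSet,
    population: str,
    maf_min: float = MAF_MIN,
    freq_bin_width: float = FREQ_BIN_WIDTH,
    ehh_floor: float = EHH_FLOOR,
) -> ScoreTrack:
    """Integrated haplotype score within one population.

    Eligible cores have known ancestral orientation and minor-allele
    frequency >= ``maf_min``; raw iHS = ln(iHH_ancestral / iHH_derived),
    standardised within derived-allele-frequency bins of width
    ``freq_bin_width``.  Cores whose iHH vanishes on either allele are
    skipped; bins with fewer than 2 scores leave the standardised value
    undefined (NaN).
    """
    rows = hap_set.rows_of(population)
    sub = np.ascontiguousarray(hap_set.haps[rows])
    records = []
    skipped = 0
    for c, idx, pos in _chrom_blocks(hap_set):
        block = np.ascontiguousarray(sub[:, idx])
        daf = block.mean(axis=0)
        known = hap_set.ancestral_known[idx]
        eligible = known & (np.minimum(daf, 1 - daf) >= maf_min)
        for local in np.flatnonzero(eligible):
            anc = np.flatnonzero(block[:, local] == 0).astype(np.int64)
            der = np.flatnonzero(block[:, local] == 1).astype(np.int64)
            if len(anc) < 2 or len(der) < 2:
                skipped += 1
                continue
            ihh_a = ihh_kernel(block, pos, local, anc, ehh_floor)
            ihh_d = ihh_kernel(block, pos, local, der, ehh_floor)
            if ihh_a <= 0.0 or ihh_d <= 0.0:
                skipped += 1
                continue
            records.append((c, int(pos[local]), math.log(ihh_a / ihh_d),
                            daf[local]))
    df = pd.DataFrame(records, columns=["chrom", "pos", "raw", "daf"])
    df["std"] = _standardize_binned(df["raw"].to_numpy(),
                                    df["daf"].to_numpy(), freq_bin_width)
    return ScoreTrack(statistic="iHS",
                      data=df[["chrom", "pos", "raw", "std", "daf"]],
                      skipped=skipped)


def _standardize_binned(raw: np.ndarray, daf: np.ndarray,
                        width: float) -> np.ndarray:
    std = np.full(len(raw), np.nan)
    if len(raw) == 0:
        return std
    bins = np.minimum((daf / width).astype(int),
                      int(round(1.0 / width)) - 1)
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() < 2:
            continue
        mu = raw[sel].mean()
        sd = raw[sel].std(ddof=1)
        if sd > 0:
            std[sel] = (raw[sel] - mu) / sd
    return std


def xpehh_scan(
    hap_set: HaplotypeSet,
    pop_a: str,
    pop_b: str,
    ehh_floor: float = EHH_FLOOR,
) -> ScoreTrack:
    """Cross-population EHH score between two populations.

    Per core SNP the allele-agnostic EHH (all haplotypes of a population,
    partitioned from the core outward) is integrated in each population;
    raw = ln(iHH_A / iHH_B), standardised genome-wide.  Positive scores
    mean longer haplotypes in ``pop_a`` (the reference population).
    """
    rows_a = hap_set.rows_of(pop_a)
    rows_b = hap_set.rows_of(pop_b)
    if len(rows_a) < 4 or len(rows_b) < 4:
        raise ValueError("both populations need at least 2 diploids")
    sub_a = np.ascontiguousarray(hap_set.haps[rows_a])
    sub_b = np.ascontiguousarray(hap_set.haps[rows_b])
    records = []
    skipped = 0
    for c, idx, pos in _chrom_blocks(hap_set):
        block_a = np.ascontiguousarray(sub_a[:, idx])
        block_b = np.ascontiguousarray(sub_b[:, idx])
        all_a = np.arange(block_a.shape[0], dtype=np.int64)
        all_b = np.arange(block_b.shape[0], dtype=np.int64)
        for local in range(len(idx)):
            ihh_a = ihh_kernel(block_a, pos, local, all_a, ehh_floor)
            ihh_b = ihh_kernel(block_b, pos, local, all_b, ehh_floor)
            if ihh_a <= 0.0 or ihh_b <= 0.0:
                skipped += 1
                continue
            records.append((c, int(pos[local]), math.log(ihh_a / ihh_b)))
    df = pd.DataFrame(records, columns=["chrom", "pos", "raw"])
    raw = df["raw"].to_numpy()
    if len(raw) >= 2 and raw.std(ddof=1) > 0:
        df["std"] = (raw - raw.mean()) / raw.std(ddof=1)
    else:
        df["std"] = np.nan
    return ScoreTrack(statistic=f"XPEHH[{pop_a},{pop_b}]", data=df,
                      skipped=skipped)


def window_scores(
    track: ScoreTrack,
    chrom_lengths: dict[str, int] | None = None,
    width: int = DEFAULT_WIDTH,
    step: int = DEFAULT_STEP,
    min_snps: int = 10,
) -> WindowTrack:
    """Mean absolute standardised score per window.

    Windows with fewer than ``min_snps`` scored SNPs are dropped, not
    zeroed.
    """
    if track.data.empty:
        raise ValueError("empty score track")
    df = track.data.dropna(subset=["std"])
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy()
    vals = np.abs(df["std"].to_numpy())
    if chrom_lengths is None:
        chrom_lengths = {c: int(pos[chrom == c].max())
                         for c in pd.unique(chrom)}
    sizes = {str(c): int(v) for c, v in chrom_lengths.items()}
    data = windowed_statistic(chrom, pos, vals, sizes, width, step,
                              reducer="mean", min_snps=min_snps)
    return WindowTrack(data=data, statistic=f"|{track.statistic}|_w")


def call_candidates(
    windows: WindowTrack, top_fraction: float = 0.001
) -> tuple[float, pd.DataFrame]:
    """Empirical top-fraction outlier windows by nearest-rank quantile.

    threshold = value at rank ceil((1 - f)·W); flagged windows have value
    strictly above it, so ~ceil(f·W) windows are flagged up to ties.
    """
    vals = windows.data["value"].to_numpy()
    W = len(vals)
    if W == 0:
        raise ValueError("no windows")
    if W < 1.0 / top_fraction:
        warnings.warn(
            f"only {W} windows for a top fraction of {top_fraction}; "
            "the empirical quantile is coarse", stacklevel=2)
    rank = max(1, math.ceil((1.0 - top_fraction) * W))
    threshold = float(np.sort(vals)[rank - 1])
    flagged = windows.data[windows.data["value"] > threshold].copy()
    if flagged.empty:
        warnings.warn("no window exceeds the outlier threshold", stacklevel=2)
    return threshold, flagged


def merge_regions(flagged: pd.DataFrame,
                  scores: pd.DataFrame | None = None) -> list[SweepRegion]:
    """Union overlapping or abutting flagged windows into sweep regions.

    Windows separated by any gap (>= 1 bp) stay separate regions.  With a
    per-SNP score frame (chrom, pos, raw) the direction summary (fraction
    of positive raw scores) is filled in.
    """
    regions: list[SweepRegion] = []
    if flagged.empty:
        return regions
    df = flagged.sort_values(["chrom", "start"])
    for c, grp in df.groupby("chrom", sort=False):
        cur: list[tuple[int, int, float]] = []
        for _, row in grp.iterrows():
            s, e, v = int(row["start"]), int(row["end"]), float(row["value"])
            if cur and s <= cur[-1][1] + 1:
                cur.append((s, e, v))
            else:
                if cur:
                    regions.append(_make_region(str(c), cur, scores))
                cur = [(s, e, v)]
        if cur:
            regions.append(_make_region(str(c), cur, scores))
    return regions


def _make_region(chrom, members, scores):
    start = min(m[0] for m in members)
    end = max(m[1] for m in members)
    vals = [m[2] for m in members]
    frac = float("nan")
    if scores is not None:
        sel = scores[(scores["chrom"].astype(str) == chrom)
                     & (scores["pos"] >= start) & (scores["pos"] <= end)]
        if len(sel):
            frac = float((sel["raw"] > 0).mean())
    return SweepRegion(chrom=chrom, start=start, end=end,
                       windows=[(m[0], m[1]) for m in members],
                       max_score=max(vals), mean_score=float(np.mean(vals)),
                       frac_positive=frac)


# ---------------------------------------------------------------------------
# feature annotation


def read_features(path: str) -> pd.DataFrame:
    """Read gene/QTL intervals from BED (0-based half-open) or GFF3
    (1-based inclusive) into internal 0-based half-open coordinates."""
    if str(path).endswith((".gff", ".gff3")):
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", merge_strategy="merge",
                                keep_order=True)
        rows = []
        for feat in db.all_features():
            name = (feat.attributes.get("Name") or feat.attributes.get("ID")
                    or [feat.featuretype])[0]
            rows.append((str(feat.seqid), feat.start - 1, feat.end, name))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(label="feature")
    df.columns = ["chrom", "start", "end", "label"][: df.shape[1]]
    if "label" not in df.columns:
        df["label"] = [f"feature_{i}" for i in range(len(df))]
    df["chrom"] = df["chrom"].astype(str)
    return df[["chrom", "start", "end", "label"]]


def annotate_regions(
    regions: list[SweepRegion], features: pd.DataFrame
) -> list[SweepRegion]:
    """Attach overlapping features to each region; gene-void regions get the
    nearest feature by edge distance (ties report all, '/'-joined)."""
    feats = features.copy()
    feats["chrom"] = feats["chrom"].astype(str)
    known_chroms = set(feats["chrom"])
    for region in regions:
        if region.chrom not in known_chroms:
            warnings.warn(f"no features on chromosome {region.chrom}",
                          stacklevel=2)
            region.features = []
            continue
        sub = feats[feats["chrom"] == region.chrom]
        r0, r1 = region.start - 1, region.end  # to 0-based half-open
        hit = sub[(sub["start"] < r1) & (sub["end"] > r0)]
        if len(hit):
            region.features = hit["label"].tolist()
            region.nearest_feature = None
            region.nearest_distance = None
        else:
            # gap length in bp between region and feature edges
            dist = np.where(sub["end"].to_numpy() <= r0,
                            r0 - sub["end"].to_numpy(),
                            sub["start"].to_numpy() - r1)
            d_min = dist.min()
            nearest = sub["label"].to_numpy()[dist == d_min]
            region.features = []
            region.nearest_feature = "/".join(map(str, nearest))
            region.nearest_distance = int(d_min)
    return regions


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "n_windows": len(r.windows), "max_score": r.max_score,
            "mean_score": r.mean_score, "frac_positive": r.frac_positive,
            "features": ",".join(r.features) if r.features else
            (f"gene void: nearest {r.nearest_feature} "
             f"({r.nearest_distance} bp)" if r.nearest_feature else ""),
        })
    return pd.DataFrame(rows)
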