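"""Genotype data model, VCF I/O, and the SNP filter cascade.

The in-memory model is a samples x variants alt-dosage matrix
(:class:`GenotypeMatrix`) with per-variant metadata held in a pandas
DataFrame.  Coordinates are 1-based inclusive in all user-facing I/O;
internal interval arithmetic is 0-based half-open and confined to the
modules that need it.

The filter cascade mirrors standard short-read practice: GATK-style hard
filters on INFO annotations, then restriction to bi-allelic autosomal SNPs,
then a joint genotyping-rate and minor-allele-count screen.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: GATK-recommended hard-filter thresholds for SNPs.  A variant fails when
#: the annotation is present and violates the (strict) inequality.
DEFAULT_HARD_FILTERS = {
    "QD": ("<", 2.0),
    "QUAL": ("<", 30.0),
    "SOR": (">", 3.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}

INFO_KEYS = ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

_VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "ancestral", "multiallelic"]


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix.

    calls
        (n_samples, n_variants) int8; 0/1/2 alt-allele dosage, -1 missing.
    variants
        DataFrame with columns chrom, pos (1-based), ref, alt, ancestral
        ('ref', 'alt' or 'unknown'), multiallelic (bool) and any INFO/QUAL
        annotation columns.
    phased
        True only if every genotype separator in the source was phased.
    haplotypes
        (2*n_samples, n_variants) uint8 alt coding, present when phased and
        fully called; haplotypes 2i, 2i+1 belong to sample i.
    chrom_lengths
        Optional chromosome sizes (bp); window grids fall back to the last
        SNP position when absent.
    """

    calls: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    phased: bool = False
    haplotypes: np.ndarray | None = None
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x variants)")
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be in {0,1,2,-1}")
        pos = self.variants["pos"].to_numpy()
        chrom = self.variants["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (np.diff(pos) <= 0)):
            raise ValueError("positions must be strictly increasing within chromosomes")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given variant indices (order preserved)."""
        return GenotypeMatrix(
            calls=self.calls[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            phased=self.phased,
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, index],
            chrom_lengths=self.chrom_lengths,
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        hap = None
        if self.haplotypes is not None:
            hap_idx = np.ravel(np.column_stack((2 * index, 2 * index + 1)))
            hap = self.haplotypes[hap_idx]
        return GenotypeMatrix(
            calls=self.calls[index],
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in index],
            phased=self.phased,
            haplotypes=hap,
            chrom_lengths=self.chrom_lengths,
        )


@dataclass
class PopulationMap:
    """Assignment of every sample to exactly one population label."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for s, p in self.assignments.items():
            if not p:
                raise ValueError(f"empty population label for sample {s!r}")

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def indices(self, gm: GenotypeMatrix, population: str) -> np.ndarray:
        """Row indices of a population's samples in the matrix."""
        if population not in self.populations():
            raise KeyError(f"unknown population {population!r}")
        return np.array(
            [i for i, s in enumerate(gm.samples) if self.assignments.get(s) == population],
            dtype=np.intp,
        )

    def validate(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.samples if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without population assignment: {missing[:5]}")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                         dtype=str, comment="#")
        return cls(dict(zip(df["sample"], df["population"])))

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for s, p in self.assignments.items():
                fh.write(f"{s}\t{p}\n")


@dataclass
class FilterReport:
    """Per-criterion removal counts, in application order."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    notes: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def __str__(self) -> str:
        lines = [f"input variants: {self.n_input}"]
        for k, v in self.removed.items():
            lines.append(f"  removed ({k}): {v}")
        for k, v in self.notes.items():
            lines.append(f"  note ({k}): {v}")
        lines.append(f"retained: {self.n_retained}")
        return "\n".join(lines)


def read_vcf(path: str | os.PathLike, want_info: bool = True) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Calls are coded as alt-allele dosage; ``./.`` becomes missing.  The
    phased flag is set only if every genotype separator is ``|``.
    Multi-allelic records are retained but flagged so the site filter can
    count them.  The AA INFO key, when present and matching REF or ALT,
    sets the ancestral-allele orientation.
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns (GT required)")
    rows: list[dict] = []
    call_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True
    any_missing = False
    for rec_no, v in enumerate(vcf, start=1):
        gts = v.genotypes  # per sample: [allele0, allele1, phased]
        if gts is None or len(gts) != len(samples):
            raise ValueError(f"{path}: record {rec_no} ({v.CHROM}:{v.POS}) lacks GT")
        arr = np.asarray([g[:3] if len(g) >= 3 else [g[0], g[0], g[-1]] for g in gts])
        a0 = arr[:, 0].astype(np.int16)
        a1 = arr[:, 1].astype(np.int16)
        phased_flags = arr[:, 2].astype(bool)
        miss = (a0 < 0) | (a1 < 0)
        dosage = ((a0 == 1).astype(np.int8) + (a1 == 1).astype(np.int8))
        dosage[miss] = MISSING
        call_cols.append(dosage)
        hap = np.empty(2 * len(samples), dtype=np.uint8)
        hap[0::2] = np.where(a0 == 1, 1, 0)
        hap[1::2] = np.where(a1 == 1, 1, 0)
        hap_cols.append(hap)
        if miss.any():
            any_missing = True
        if not phased_flags.all():
            all_phased = False
        alts = v.ALT or []
        multi = len(alts) > 1
        ancestral = "unknown"
        aa = v.INFO.get("AA")
        if aa is not None:
            aa = str(aa).upper()
            if aa == v.REF.upper():
                ancestral = "ref"
            elif alts and aa == str(alts[0]).upper():
                ancestral = "alt"
        row = {
            "chrom": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": alts[0] if alts else ".",
            "ancestral": ancestral,
            "multiallelic": multi,
        }
        if want_info:
            row["QUAL"] = np.nan if v.QUAL is None else float(v.QUAL)
            for key in INFO_KEYS:
                val = v.INFO.get(key)
                if val is not None:
                    try:
                        row[key] = float(val)
                    except (TypeError, ValueError) as exc:
                        raise ValueError(
                            f"{path}: record {rec_no} ({v.CHROM}:{v.POS}): "
                            f"non-numeric INFO {key}={val!r}"
                        ) from exc
                else:
                    row[key] = np.nan
        rows.append(row)
    vcf.close()
    variants = pd.DataFrame(rows, columns=None)
    if not rows:
        variants = pd.DataFrame(columns=_VARIANT_COLUMNS)
    calls = (
        np.stack(call_cols, axis=1)
        if call_cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    phased = all_phased and len(rows) > 0
    haps = None
    if phased and not any_missing:
        haps = np.stack(hap_cols, axis=1)
    return GenotypeMatrix(calls=calls, variants=variants, samples=samples,
                          phased=phased, haplotypes=haps)


def apply_hard_filters(
    gm: GenotypeMatrix,
    thresholds: dict[str, tuple[str, float]] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove variants violating GATK-style hard-filter thresholds.

    A variant is removed iff any *available* annotation violates its
    threshold; absent annotations never trigger removal but are counted in
    the report notes.
    """
    thresholds = DEFAULT_HARD_FILTERS if thresholds is None else thresholds
    report = FilterReport(n_input=gm.n_variants)
    fail = np.zeros(gm.n_variants, dtype=bool)
    for key, (op, cut) in thresholds.items():
        if key not in gm.variants.columns:
            report.notes[f"{key} absent"] = gm.n_variants
            continue
        vals = pd.to_numeric(gm.variants[key], errors="raise").to_numpy(dtype=float)
        absent = np.isnan(vals)
        if absent.any():
            report.notes[f"{key} missing"] = int(absent.sum())
        if op == "<":
            viol = vals < cut
        elif op == ">":
            viol = vals > cut
        else:
            raise ValueError(f"unknown comparison {op!r} for {key}")
        viol &= ~absent
        newly = viol & ~fail
        report.removed[f"{key}{op}{cut}"] = int(newly.sum())
        fail |= viol
    out = gm.take_variants(np.flatnonzero(~fail))
    return out, report


_SNP_ALLELES = frozenset("ACGT")


def filter_sites(
    gm: GenotypeMatrix,
    autosomes: list[str],
    min_call_rate: float = 0.5,
    min_mac: int = 2,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep bi-allelic autosomal SNPs with adequate call rate and MAC.

    Call rate and minor-allele count are computed jointly over all samples.
    Applying the filter twice is a no-op (idempotence).
    """
    if not autosomes:
        raise ValueError("autosome list must be non-empty")
    autosomes = [str(a) for a in autosomes]
    report = FilterReport(n_input=gm.n_variants)
    keep = np.ones(gm.n_variants, dtype=bool)

    multi = gm.variants["multiallelic"].to_numpy(dtype=bool)
    report.removed["multiallelic"] = int(multi.sum())
    keep &= ~multi

    is_snp = np.array(
        [r in _SNP_ALLELES and a in _SNP_ALLELES
         for r, a in zip(gm.variants["ref"], gm.variants["alt"])]
    )
    newly = keep & ~is_snp
    report.removed["not a SNP"] = int(newly.sum())
    keep &= is_snp

    on_auto = gm.variants["chrom"].astype(str).isin(autosomes).to_numpy()
    newly = keep & ~on_auto
    report.removed["not autosomal"] = int(newly.sum())
    keep &= on_auto

    called = gm.calls != MISSING
    call_rate = called.mean(axis=0) if gm.n_samples else np.zeros(gm.n_variants)
    ok_rate = call_rate >= min_call_rate
    newly = keep & ~ok_rate
    report.removed[f"call rate < {min_call_rate}"] = int(newly.sum())
    keep &= ok_rate

    alt_copies = np.where(called, gm.calls, 0).sum(axis=0)
    total_copies = 2 * called.sum(axis=0)
    mac = np.minimum(alt_copies, total_copies - alt_copies)
    ok_mac = mac >= min_mac
    newly = keep & ~ok_mac
    report.removed[f"MAC < {min_mac}"] = int(newly.sum())
    keep &= ok_mac

    if not keep.any():
        warnings.warn("filter_sites removed every variant", stacklevel=2)
    return gm.take_variants(np.flatnonzero(keep)), report


def allele_counts(
    gm: GenotypeMatrix,
    pop_map: PopulationMap | None = None,
    population: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt allele copies, called allele copies) over a population.

    With no population the counts run over all samples.  Counts consider
    called genotypes only.
    """
    if population is None:
        sub = gm.calls
    else:
        if pop_map is None:
            raise ValueError("pop_map required when a population is named")
        sub = gm.calls[pop_map.indices(gm, population)]
    called = sub != MISSING
    n_alt = np.where(called, sub, 0).sum(axis=0).astype(np.int64)
    n_called = 2 * called.sum(axis=0).astype(np.int64)
    return n_alt, n_called


def write_dataset(
    gm: GenotypeMatrix,
    pop_map: PopulationMap | None,
    out_prefix: str | os.PathLike,
) -> dict[str, str]:
    """Write the matrix as an uncompressed VCF plus a popmap TSV.

    Phase is preserved; the ancestral allele is emitted as the AA INFO key
    when known.  ``read_vcf(write_dataset(...))`` is the identity on calls.
    """
    if gm.n_variants == 0:
        raise ValueError("refusing to write an empty dataset")
    prefix = str(out_prefix)
    vcf_path = prefix + ".vcf"
    paths = {"vcf": vcf_path}
    sep = "|" if gm.phased else "/"
    info_cols = [c for c in gm.variants.columns if c in INFO_KEYS]
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if gm.chrom_lengths:
            for c, ln in gm.chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        for key in info_cols:
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        variants = gm.variants
        quals = variants["QUAL"].to_numpy() if "QUAL" in variants.columns else None
        for j in range(gm.n_variants):
            row = variants.iloc[j]
            info_parts = []
            if row["ancestral"] == "ref":
                info_parts.append(f"AA={row['ref']}")
            elif row["ancestral"] == "alt":
                info_parts.append(f"AA={row['alt']}")
            for key in info_cols:
                val = row[key]
                if pd.notna(val):
                    info_parts.append(f"{key}={val:g}")
            info = ";".join(info_parts) if info_parts else "."
            qual = "."
            if quals is not None and pd.notna(quals[j]):
                qual = f"{quals[j]:g}"
            gts = []
            if gm.haplotypes is not None:
                col = gm.haplotypes[:, j]
                for i in range(gm.n_samples):
                    gts.append(f"{col[2 * i]}{sep}{col[2 * i + 1]}")
            else:
                for i in range(gm.n_samples):
                    c = gm.calls[i, j]
                    if c == MISSING:
                        gts.append(f".{sep}.")
                    elif c == 0:
                        gts.append(f"0{sep}0")
                    elif c == 2:
                        gts.append(f"1{sep}1")
                    else:
                        gts.append(f"0{sep}1")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual}\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )
    if pop_map is not None:
        pm_path = prefix + ".popmap.tsv"
        pop_map.write(pm_path)
        paths["popmap"] = pm_path
    return paths
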