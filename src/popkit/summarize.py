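"""Table-level summaries and internal arithmetic-consistency checks.

Per-population summary rows combine within-population SNP counts,
individual heterozygosity and inbreeding, F_ROH and windowed pi.  The ROH
class table carries the identities that tie its columns together:

* sum of per-class mean counts  = mean segment count per individual
* total length / n individuals  = mean per-individual total length
* total length / (n x mean count) = mean segment length

`consistency_report` evaluates these identities on any table (including a
transcription of a published one) and returns machine-readable verdicts.
Standard deviations use the n-1 (sample) denominator.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diversity, roh
from .gio import GenotypeMatrix, PopulationMap


def _nanmean(x) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0 or np.isnan(x).all():
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(x))


@dataclass
class PopulationSummary:
    population: str
    n_snp: int
    h_o_mean: float
    h_o_sd: float
    h_e: float
    f_mean: float
    f_sd: float
    f_roh_mean: float
    f_roh_sd: float
    pi_mean: float
    pi_sd: float


def population_summary(
    gm: GenotypeMatrix,
    pop_map: PopulationMap,
    roh_segments: list[roh.ROHSegment] | None = None,
    genome_size: int = roh.DEFAULT_GENOME_SIZE,
) -> pd.DataFrame:
    """Per-population summary with means/SDs over individuals (H_o, F,
    F_ROH) and over windows (pi)."""
    pop_map.validate(gm)
    rows = []
    for pop in pop_map.populations():
        idx = pop_map.indices(gm, pop)
        sub = gm.take_samples(idx)
        n_snp = diversity.n_polymorphic(gm, pop_map, pop)
        het = diversity.individual_het(sub) if sub.n_samples >= 2 else []
        h_o = np.array([h.h_o for h in het])
        f = np.array([h.f for h in het])
        h_e = diversity.population_He(gm, pop_map, pop)
        pi_track = diversity.windowed_pi(gm, pop_map, pop)
        pi = pi_track.data["value"].to_numpy()
        if roh_segments is not None:
            froh = np.array([
                roh.f_roh(roh_segments, s, genome_size).f_roh
                for s in sub.samples
            ])
        else:
            froh = np.array([np.nan])
        def sd(x):
            x = np.asarray(x, dtype=float)
            ok = x[~np.isnan(x)]
            return float(np.std(ok, ddof=1)) if len(ok) > 1 else 0.0
        rows.append(PopulationSummary(
            population=pop, n_snp=n_snp,
            h_o_mean=_nanmean(h_o),
            h_o_sd=sd(h_o),
            h_e=h_e,
            f_mean=_nanmean(f),
            f_sd=sd(f),
            f_roh_mean=_nanmean(froh),
            f_roh_sd=sd(froh),
            pi_mean=_nanmean(pi),
            pi_sd=sd(pi),
        ).__dict__)
    return pd.DataFrame(rows)


def roh_table(
    segments: list[roh.ROHSegment],
    pop_map: PopulationMap,
    sample_lists: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """ROH length-class table plus its internal identity checks."""
    table = roh.classify_and_summarize(segments, pop_map, sample_lists).data
    if table.empty:
        return table
    checks = consistency_report(table)
    bad = [c for c in checks["checks"] if c["status"] == "fail"]
    if bad:
        raise AssertionError(f"ROH table failed internal checks: {bad}")
    return table


_CLASS_COLS_PREFIX = "mean_n_"


def _class_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns
            if c.startswith(_CLASS_COLS_PREFIX) and c != "mean_n_segments"]


def consistency_report(
    roh_class_table: pd.DataFrame | None = None,
    froh: pd.DataFrame | None = None,
    genome_size_mb: float = roh.DEFAULT_GENOME_SIZE / 1e6,
    decimals: int = 2,
) -> dict:
    """Arithmetic identities across summary tables, as JSON-ready verdicts.

    Tolerances allow for the rounding of printed inputs: each check passes
    within half a unit in the last printed decimal place per rounded term.
    ``froh``, when given, has columns population, mean_total_len_mb,
    f_roh (the printed per-population mean) and is checked against
    mean_total_len_mb / genome_size_mb at the printed precision.
    """
    checks = []
    unit = 0.5 * 10.0 ** (-decimals)

    def add(name, lhs, rhs, tol):
        status = "pass" if abs(lhs - rhs) <= tol else "fail"
        checks.append({"check": name, "lhs": lhs, "rhs": rhs,
                       "tol": tol, "status": status})

    if roh_class_table is None or roh_class_table.empty:
        checks.append({"check": "roh_class_table", "status": "skipped"})
    else:
        class_cols = _class_columns(roh_class_table)
        for _, row in roh_class_table.iterrows():
            pop = row["population"]
            class_sum = float(sum(row[c] for c in class_cols))
            add(f"{pop}: sum of class means = mean segment count",
                class_sum, float(row["mean_n_segments"]),
                unit * (len(class_cols) + 1))
            if "n_individuals" in row and row.get("n_individuals", 0):
                n = float(row["n_individuals"])
                add(f"{pop}: total length / n = mean per-individual total",
                    float(row["total_len_mb"]) / n,
                    float(row["mean_total_len_mb"]), unit * 2)
                denom = n * float(row["mean_n_segments"])
                if denom > 0:
                    add(f"{pop}: total length / (n x mean count) = mean length",
                        float(row["total_len_mb"]) / denom,
                        float(row["mean_len_mb"]),
                        unit * 2 + float(row["mean_len_mb"]) * unit
                        / max(float(row["mean_n_segments"]), 1.0))
    if froh is None:
        checks.append({"check": "froh_table", "status": "skipped"})
    else:
        for _, row in froh.iterrows():
            add(f"{row['population']}: mean total ROH / genome size = F_ROH",
                round(float(row["mean_total_len_mb"]) / genome_size_mb,
                      decimals),
                float(row["f_roh"]), unit)
    n_fail = sum(1 for c in checks if c.get("status") == "fail")
    return {"checks": checks, "n_fail": n_fail,
            "ok": n_fail == 0}


def report_to_json(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
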