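import functools
import textwrap

import numpy as np
import pandas as pd
import pytest

from popkit import gio, simulate


def make_gm(calls, chrom=None, pos=None, samples=None, phased=False,
            haplotypes=None, ancestral="ref", chrom_lengths=None, **info):
    """Small GenotypeMatrix builder for fixtures."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    variants = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
        "ref": ["A"] * m,
        "alt": ["G"] * m,
        "ancestral": ancestral,
        "multiallelic": False,
    })
    for key, vals in info.items():
        variants[key] = vals
    return gio.GenotypeMatrix(
        calls=calls,
        variants=variants,
        samples=samples or [f"s{i}" for i in range(n)],
        phased=phased,
        haplotypes=haplotypes,
        chrom_lengths=chrom_lengths,
    )


def write_vcf(path, body, samples=("s0", "s1")):
    """Write a hand-crafted VCF with the standard header."""
    header = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
        ##INFO=<ID=QD,Number=1,Type=Float,Description="x">
        ##INFO=<ID=SOR,Number=1,Type=Float,Description="x">
        ##INFO=<ID=FS,Number=1,Type=Float,Description="x">
        ##INFO=<ID=MQ,Number=1,Type=Float,Description="x">
        ##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="x">
        ##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="x">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        """)
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    with open(path, "w") as fh:
        fh.write(header + cols + "\n" + textwrap.dedent(body))
    return path


@functools.lru_cache(maxsize=None)
def study_bundle(seed):
    """Session-cached six-population study fixture."""
    return simulate.emulate_study(seed)


@pytest.fixture(scope="session")
def study1():
    return study_bundle(1)
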