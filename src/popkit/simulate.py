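"""Forward-in-time Wright–Fisher simulator with known truth.

Discrete non-overlapping generations, binomial resampling of parents,
Poisson crossovers and mutations (infinite-sites on a continuous coordinate),
optional additive viability selection at a single sweep site, optional
sib-mating bias for autozygosity enrichment, and optional two-deme symmetric
migration.  Haplotypes are phased by construction and the ancestral allele is
known everywhere (simulation starts from the ancestral state), so derived /
ancestral orientation in the output is exact.

Pedigree inbreeding is tracked exactly through the kinship matrix of each
deme, so every sampled individual carries its true pedigree F.

`emulate_study` wires the simulator into a six-population design mirroring a
dual-purpose-breed resequencing panel: one high-diversity outgroup, two
bottlenecked and sib-mated lines with long ROH and slow LD decay, two
intermediate commercial lines, and one focal population carrying a hard
selective sweep at a recorded locus.
"""
from __future__ import annotations

import copy
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gio
from ._kernels import gametes_kernel

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SweepConfig:
    """A single selected site on a branch.

    position is a genome-linear coordinate in bp (chromosomes concatenated).
    start_gen is in generations before present.  With ``initial_frequency``
    unset the sweep starts from a single new copy.  When ``min_final_freq``
    is set, branches on which the derived allele fails to reach it are
    re-run from the introduction point, up to ``max_retries`` attempts.
    """

    position: float
    s: float
    h: float = 0.5
    start_gen: int = 100
    initial_frequency: float | None = None
    min_final_freq: float | None = None
    max_retries: int = 100


@dataclass
class DemographyNode:
    """One branch of the rooted population tree.

    children are (split_time_generations_before_present, node) pairs.  The
    parent lineage persists through splits (daughters are founded by one
    round of reproduction from the parent).  ``p_sib`` is the per-offspring
    probability of drawing a full-sib parent pair.  ``bottleneck`` is
    (start_gen_before_present, size, duration_generations).
    """

    name: str
    N: int
    p_sib: float = 0.0
    children: list[tuple[int, "DemographyNode"]] = field(default_factory=list)
    sweep: SweepConfig | None = None
    bottleneck: tuple[int, int, int] | None = None
    reset_kinship_at_found: bool = True
    #: generations before present at which pedigree bookkeeping restarts, so
    #: Truth.pedigree_f measures inbreeding accumulated since that epoch
    kinship_reference_gen: int | None = None
    #: monogamous breeding-pair structure: offspring are multinomially
    #: assigned to this many pairs, giving large full-sib families (as in
    #: closed lines with few sires/dams); with a bottleneck configured the
    #: pair structure applies only while the bottleneck is active.  p_sib
    #: then biases pair formation toward full sibs.
    n_breeding_pairs: int | None = None

    def pairs_at(self, t: int) -> int | None:
        if self.n_breeding_pairs is None:
            return None
        if self.bottleneck is not None:
            t0, _, dur = self.bottleneck
            return self.n_breeding_pairs if t0 >= t > t0 - dur else None
        return self.n_breeding_pairs

    def size_at(self, t: int) -> int:
        if self.bottleneck is not None:
            t0, size, dur = self.bottleneck
            if t0 >= t > t0 - dur:
                return size
        return self.N


@dataclass
class SimulationConfig:
    seed: int
    sequence_length: int = 1_000_000  # per chromosome, bp
    n_chromosomes: int = 1
    mutation_rate: float = 1e-8  # per bp per generation
    recombination_rate: float = 1e-8  # per bp per generation
    demography: DemographyNode | None = None
    burn_in: int | None = None  # generations before the first event; default 10N
    #: per-chromosome multipliers on the recombination rate (chickens span
    #: several-fold between macro- and microchromosomes); default uniform
    recombination_multipliers: list[float] | None = None
    init: str = "monomorphic"  # or 'sfs' (neutral equilibrium spectrum)
    sample_sizes: dict[str, int] = field(default_factory=dict)
    missing_rate: float = 0.0
    geno_error_rate: float = 0.0
    track_kinship: bool = True
    run_generations: int = 0  # post-burn-in generations when the root is a leaf

    def __post_init__(self) -> None:
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.demography is None:
            self.demography = DemographyNode("pop", 100)

    @property
    def total_length(self) -> int:
        return self.sequence_length * self.n_chromosomes


@dataclass
class Truth:
    """Ground truth recorded by the simulator for downstream validation."""

    sweep_interval: tuple[str, int, int] | None
    sweep_position: tuple[str, int] | None
    sweep_final_freq: float | None
    pedigree_f: dict[str, float]
    ancestral: str = "ref"  # ancestral allele equals REF at every site
    seed: int | None = None

    def to_json(self, path: str | os.PathLike) -> None:
        d = {
            "sweep_interval": list(self.sweep_interval) if self.sweep_interval else None,
            "sweep_position": list(self.sweep_position) if self.sweep_position else None,
            "sweep_final_freq": self.sweep_final_freq,
            "pedigree_f": self.pedigree_f,
            "ancestral": self.ancestral,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


# ---------------------------------------------------------------------------
# internal population state


class _Deme:
    __slots__ = ("H", "phi", "F", "parent_pair")

    def __init__(self, H, phi, F, parent_pair):
        self.H = H            # (2N, S) uint8
        self.phi = phi        # (N, N) kinship incl. self on the diagonal
        self.F = F            # (N,) pedigree inbreeding of current individuals
        self.parent_pair = parent_pair  # (N, 2) parents in previous generation

    @property
    def n(self) -> int:
        return self.H.shape[0] // 2


class _World:
    """One or more demes sharing a common segregating-site frame."""

    def __init__(self, positions, demes, fixed, track_kinship):
        self.positions = positions  # (S,) float64 genome-linear, sorted
        self.demes: list[_Deme] = demes
        self.fixed: list[float] = fixed  # positions fixed for derived (all demes)
        self.track_kinship = track_kinship

    def fork_deme(self, idx: int) -> "_World":
        d = self.demes[idx]
        return _World(
            self.positions.copy(),
            [_Deme(d.H.copy(), None if d.phi is None else d.phi.copy(),
                   d.F.copy(), d.parent_pair.copy())],
            list(self.fixed),
            self.track_kinship,
        )


class _Engine:
    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.L = float(cfg.total_length)
        self.boundaries = np.array(
            [cfg.sequence_length * k for k in range(1, cfg.n_chromosomes)],
            dtype=np.float64,
        )
        mult = cfg.recombination_multipliers
        if mult is None:
            mult = [1.0] * cfg.n_chromosomes
        if len(mult) != cfg.n_chromosomes:
            raise ValueError("need one recombination multiplier per chromosome")
        self.chrom_rates = (cfg.recombination_rate * cfg.sequence_length
                            * np.asarray(mult, dtype=float))
        self.total_map = float(self.chrom_rates.sum())
        self.chrom_weights = (self.chrom_rates / self.total_map
                              if self.total_map > 0
                              else np.full(cfg.n_chromosomes,
                                           1.0 / cfg.n_chromosomes))
        self._gen_count = 0

    # -- initialisation ----------------------------------------------------

    def make_world(self, N: int) -> _World:
        cfg = self.cfg
        if cfg.init == "sfs":
            positions, H = self._init_sfs(N)
        else:
            positions = np.zeros(0, dtype=np.float64)
            H = np.zeros((2 * N, 0), dtype=np.uint8)
        phi = 0.5 * np.eye(N) if cfg.track_kinship else None
        deme = _Deme(H, phi, np.zeros(N), np.full((N, 2), -1, dtype=np.int64))
        return _World(positions, [deme], [], cfg.track_kinship)

    def _init_sfs(self, N: int):
        """Seed the founder deme at the neutral equilibrium frequency spectrum.

        Expected count of sites at derived copy number i is theta_L / i
        (theta_L = 4 N mu L); derived alleles land on random haplotypes, so
        the initial state is at mutation-drift equilibrium for heterozygosity
        but at linkage equilibrium -- a burn-in builds short-range LD.
        """
        two_n = 2 * N
        theta_l = 4 * N * self.cfg.mutation_rate * self.L
        counts = self.rng.poisson(theta_l / np.arange(1, two_n), size=two_n - 1)
        S = int(counts.sum())
        positions = np.sort(self.rng.uniform(0, self.L, size=S))
        H = np.zeros((two_n, S), dtype=np.uint8)
        col = 0
        for i, c in enumerate(counts, start=1):
            for _ in range(c):
                rows = self.rng.choice(two_n, size=i, replace=False)
                H[rows, col] = 1
                col += 1
        # column order must follow sorted positions: columns were filled in
        # SFS-class order, so shuffle the position assignment instead
        perm = self.rng.permutation(S)
        return positions, H[:, perm]

    # -- one generation ----------------------------------------------------

    def step(self, world: _World, new_sizes: list[int], p_sib: list[float],
             sweeps: list[SweepConfig | None], migration: float = 0.0,
             pairs: list[int | None] | None = None) -> None:
        rng = self.rng
        n_demes = len(world.demes)
        if migration > 0 and world.track_kinship:
            raise ValueError("kinship tracking is not defined with migration")
        if pairs is None:
            pairs = [None] * n_demes
        new_demes = []
        for d in range(n_demes):
            N_next = new_sizes[d]
            deme = world.demes[d]
            sweep = sweeps[d]
            sweep_col = -1
            if sweep is not None:
                sweep_col = self._locate(world.positions, sweep.position)
            mothers, fathers, src_m, src_f = self._choose_parents(
                world, d, N_next, p_sib[d], migration, pairs[d])
            n_g = 2 * N_next
            # crossovers + independent assortment at chromosome starts
            n_co = rng.poisson(self.total_map, size=n_g)
            start_src = rng.integers(0, 2, size=n_g).astype(np.int64)
            bp_pos, bp_off = self._breakpoints(n_co)
            if sweep is not None and sweep_col >= 0:
                mothers, fathers, src_m, src_f, start_src, bp_pos, bp_off = \
                    self._viability_select(world, d, deme, sweep, sweep_col,
                                           N_next, p_sib[d], migration,
                                           mothers, fathers, src_m, src_f,
                                           start_src, bp_pos, bp_off)
            bp_sites = np.searchsorted(world.positions, bp_pos).astype(np.int64)
            hap0, hap1 = self._parent_hap_rows(world, d, mothers, fathers,
                                               src_m, src_f)
            H_src = self._stacked_H(world, d, migration)
            out = np.empty((n_g, world.positions.shape[0]), dtype=np.uint8)
            gametes_kernel(H_src, bp_sites, bp_off, start_src, hap0, hap1, out)
            phi, F = self._update_kinship(deme, mothers, fathers, src_m, src_f)
            new_demes.append(_Deme(out, phi, F,
                                   np.column_stack((mothers, fathers))))
        world.demes = new_demes
        self._mutate(world)
        self._gen_count += 1
        if self._gen_count % 8 == 0:
            self.cleanup(world)

    def _locate(self, positions: np.ndarray, pos: float) -> int:
        i = int(np.searchsorted(positions, pos))
        if i < len(positions) and positions[i] == pos:
            return i
        return -1

    def _choose_parents(self, world, d, N_next, p_sib, migration,
                        n_pairs=None):
        rng = self.rng
        deme = world.demes[d]
        N_prev = deme.n
        other = 1 - d if len(world.demes) == 2 else d
        N_other = world.demes[other].n
        if n_pairs is not None:
            pair_m, pair_f = self._breeding_pairs(deme, n_pairs, p_sib)
            assign = rng.integers(0, len(pair_m), size=N_next)
            mothers, fathers = pair_m[assign], pair_f[assign]
            return (mothers, fathers,
                    np.full(N_next, d, dtype=np.int64),
                    np.full(N_next, d, dtype=np.int64))
        mothers = rng.integers(0, N_prev, size=N_next)
        fathers = rng.integers(0, N_prev, size=N_next)
        # no selfing
        clash = mothers == fathers
        while clash.any() and N_prev > 1:
            fathers[clash] = rng.integers(0, N_prev, size=int(clash.sum()))
            clash = mothers == fathers
        src_m = np.full(N_next, d, dtype=np.int64)
        src_f = np.full(N_next, d, dtype=np.int64)
        if migration > 0 and len(world.demes) == 2:
            mig_m = rng.random(N_next) < migration
            mig_f = rng.random(N_next) < migration
            src_m[mig_m] = other
            src_f[mig_f] = other
            mothers[mig_m] = rng.integers(0, N_other, size=int(mig_m.sum()))
            fathers[mig_f] = rng.integers(0, N_other, size=int(mig_f.sum()))
        if p_sib > 0:
            fam = self._families(deme)
            if fam:
                take = np.flatnonzero(rng.random(N_next) < p_sib)
                keys = list(fam)
                for k in take:
                    members = fam[keys[rng.integers(0, len(keys))]]
                    pair = rng.choice(members, size=2, replace=False)
                    mothers[k], fathers[k] = int(pair[0]), int(pair[1])
                    src_m[k] = src_f[k] = d
        return mothers, fathers, src_m, src_f

    def _breeding_pairs(self, deme: _Deme, n_pairs: int, p_sib: float):
        """Form monogamous breeding pairs, biased toward full sibs."""
        rng = self.rng
        N_prev = deme.n
        fam = self._families(deme) if p_sib > 0 else {}
        keys = list(fam)
        pm = np.empty(n_pairs, dtype=np.int64)
        pf = np.empty(n_pairs, dtype=np.int64)
        for k in range(n_pairs):
            if keys and rng.random() < p_sib:
                members = fam[keys[rng.integers(0, len(keys))]]
                pair = rng.choice(members, size=2, replace=False)
                pm[k], pf[k] = int(pair[0]), int(pair[1])
            else:
                a = rng.integers(0, N_prev)
                b = rng.integers(0, N_prev)
                while b == a and N_prev > 1:
                    b = rng.integers(0, N_prev)
                pm[k], pf[k] = a, b
        return pm, pf

    @staticmethod
    def _families(deme: _Deme) -> dict[tuple[int, int], list[int]]:
        if deme.parent_pair[0, 0] < 0:
            return {}
        fam: dict[tuple[int, int], list[int]] = {}
        for i, (a, b) in enumerate(deme.parent_pair):
            key = (int(min(a, b)), int(max(a, b)))
            fam.setdefault(key, []).append(i)
        return {k: v for k, v in fam.items() if len(v) >= 2}

    def _breakpoints(self, n_co: np.ndarray):
        """Per-gamete sorted breakpoint positions (ragged, flat + offsets)."""
        rng = self.rng
        n_g = n_co.shape[0]
        n_tot = int(n_co.sum())
        chrom = rng.choice(self.cfg.n_chromosomes, size=n_tot,
                           p=self.chrom_weights)
        co_flat = (chrom * float(self.cfg.sequence_length)
                   + rng.uniform(0, self.cfg.sequence_length, size=n_tot))
        co_gid = np.repeat(np.arange(n_g), n_co)
        nb = len(self.boundaries)
        if nb:
            coin = rng.random((n_g, nb)) < 0.5
            b_gid, b_idx = np.nonzero(coin)
            b_pos = self.boundaries[b_idx]
            pos = np.concatenate([co_flat, b_pos])
            gid = np.concatenate([co_gid, b_gid])
        else:
            pos, gid = co_flat, co_gid
        order = np.lexsort((pos, gid))
        pos, gid = pos[order], gid[order]
        counts = np.bincount(gid, minlength=n_g)
        off = np.zeros(n_g + 1, dtype=np.int64)
        np.cumsum(counts, out=off[1:])
        return pos, off

    def _parent_hap_rows(self, world, d, mothers, fathers, src_m, src_f):
        """Global haplotype row indices in the (possibly stacked) H source."""
        offs = np.zeros(len(world.demes), dtype=np.int64)
        for i in range(1, len(world.demes)):
            offs[i] = offs[i - 1] + world.demes[i - 1].H.shape[0]
        n = len(mothers)
        hap0 = np.empty(2 * n, dtype=np.int64)
        hap1 = np.empty(2 * n, dtype=np.int64)
        hap0[0::2] = offs[src_m] + 2 * mothers
        hap1[0::2] = offs[src_m] + 2 * mothers + 1
        hap0[1::2] = offs[src_f] + 2 * fathers
        hap1[1::2] = offs[src_f] + 2 * fathers + 1
        return hap0, hap1

    def _stacked_H(self, world, d, migration):
        if len(world.demes) == 1:
            return world.demes[0].H
        return np.vstack([dm.H for dm in world.demes])

    def _gamete_allele_at(self, world, hap0, hap1, start_src, bp_pos, bp_off,
                          sweep_col, H_src):
        """Allele each gamete carries at the sweep column (crossover parity)."""
        pos = world.positions[sweep_col]
        n_g = len(start_src)
        allele = np.empty(n_g, dtype=np.int64)
        for g in range(n_g):
            k = np.searchsorted(bp_pos[bp_off[g]:bp_off[g + 1]], pos,
                                side="right")
            src = (start_src[g] + k) % 2
            row = hap0[g] if src == 0 else hap1[g]
            allele[g] = H_src[row, sweep_col]
        return allele

    def _viability_select(self, world, d, deme, sweep, sweep_col, N_next,
                          p_sib, migration, mothers, fathers, src_m, src_f,
                          start_src, bp_pos, bp_off):
        """Rejection-sample offspring by fitness at the sweep site."""
        rng = self.rng
        s, h = sweep.s, sweep.h
        w = np.array([1.0, 1.0 + h * s, 1.0 + s]) / (1.0 + s)
        for _ in range(200):
            hap0, hap1 = self._parent_hap_rows(world, d, mothers, fathers,
                                               src_m, src_f)
            H_src = self._stacked_H(world, d, migration)
            allele = self._gamete_allele_at(world, hap0, hap1, start_src,
                                            bp_pos, bp_off, sweep_col, H_src)
            dosage = allele[0::2] + allele[1::2]
            accept = rng.random(N_next) < w[dosage]
            if accept.all():
                return (mothers, fathers, src_m, src_f, start_src,
                        bp_pos, bp_off)
            # redraw the rejected slots entirely
            bad = np.flatnonzero(~accept)
            m2, f2, sm2, sf2 = self._choose_parents(world, d, len(bad),
                                                    p_sib, migration)
            mothers[bad], fathers[bad] = m2, f2
            src_m[bad], src_f[bad] = sm2, sf2
            n_co = rng.poisson(self.total_map, size=2 * len(bad))
            new_pos, new_off = self._breakpoints(n_co)
            gam_bad = np.ravel(np.column_stack((2 * bad, 2 * bad + 1)))
            start_src[gam_bad] = rng.integers(0, 2, size=len(gam_bad))
            bp_pos, bp_off = _splice_ragged(bp_pos, bp_off, gam_bad,
                                            new_pos, new_off)
        return mothers, fathers, src_m, src_f, start_src, bp_pos, bp_off

    def _update_kinship(self, deme, mothers, fathers, src_m, src_f):
        if deme.phi is None:
            return None, np.zeros(len(mothers))
        phi = deme.phi
        a, b = mothers, fathers
        F = phi[a, b].copy()
        new = 0.25 * (phi[np.ix_(a, a)] + phi[np.ix_(a, b)]
                      + phi[np.ix_(b, a)] + phi[np.ix_(b, b)])
        np.fill_diagonal(new, 0.5 * (1.0 + F))
        return new, F

    def _mutate(self, world: _World) -> None:
        rng = self.rng
        mu_l = self.cfg.mutation_rate * self.L
        per_deme = [rng.poisson(d.H.shape[0] * mu_l) for d in world.demes]
        n_new = int(sum(per_deme))
        if n_new == 0:
            return
        newpos = rng.uniform(0, self.L, size=n_new)
        blocks = []
        k = 0
        for d, cnt in zip(world.demes, per_deme):
            block = np.zeros((d.H.shape[0], n_new), dtype=np.uint8)
            rows = rng.integers(0, d.H.shape[0], size=cnt)
            block[rows, np.arange(k, k + cnt)] = 1
            blocks.append(block)
            k += cnt
        positions = np.concatenate([world.positions, newpos])
        order = np.argsort(positions, kind="stable")
        world.positions = positions[order]
        for d, block in zip(world.demes, blocks):
            d.H = np.concatenate([d.H, block], axis=1)[:, order]

    def cleanup(self, world: _World) -> None:
        """Drop lost columns; promote globally fixed columns to the fixed list."""
        if world.positions.shape[0] == 0:
            return
        colsum = sum(d.H.sum(axis=0, dtype=np.int64) for d in world.demes)
        total = sum(d.H.shape[0] for d in world.demes)
        lost = colsum == 0
        fixed = colsum == total
        if fixed.any():
            world.fixed.extend(world.positions[fixed].tolist())
        keep = ~(lost | fixed)
        if not keep.all():
            world.positions = world.positions[keep]
            for d in world.demes:
                d.H = d.H[:, keep]

    # -- sweeps ------------------------------------------------------------

    def introduce_sweep(self, world: _World, sweep: SweepConfig) -> None:
        rng = self.rng
        deme = world.demes[0]
        two_n = deme.H.shape[0]
        col = np.zeros((two_n, 1), dtype=np.uint8)
        if sweep.initial_frequency is None:
            col[rng.integers(0, two_n), 0] = 1
        else:
            k = max(1, int(round(sweep.initial_frequency * two_n)))
            rows = rng.choice(two_n, size=min(k, two_n), replace=False)
            col[rows, 0] = 1
        i = int(np.searchsorted(world.positions, sweep.position))
        world.positions = np.insert(world.positions, i, sweep.position)
        deme.H = np.concatenate(
            [deme.H[:, :i], col, deme.H[:, i:]], axis=1)

    def sweep_frequency(self, world: _World, sweep: SweepConfig) -> float:
        if sweep.position in world.fixed:
            return 1.0
        i = self._locate(world.positions, sweep.position)
        if i < 0:
            return 0.0
        d = world.demes[0]
        return float(d.H[:, i].mean())


def _splice_ragged(pos, off, which, new_pos, new_off):
    """Replace the ragged slices `which` of (pos, off) with new slices."""
    n = len(off) - 1
    parts = []
    lens = np.empty(n, dtype=np.int64)
    repl = {int(g): k for k, g in enumerate(which)}
    for g in range(n):
        if g in repl:
            k = repl[g]
            seg = new_pos[new_off[k]:new_off[k + 1]]
        else:
            seg = pos[off[g]:off[g + 1]]
        parts.append(seg)
        lens[g] = len(seg)
    out_off = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(lens, out=out_off[1:])
    return (np.concatenate(parts) if parts else pos[:0]), out_off


# ---------------------------------------------------------------------------
# tree execution


def _run_branch(engine: _Engine, node: DemographyNode, world: _World,
                t_from: int, results: dict[str, _World],
                needed: set[str]) -> None:
    events = sorted(node.children, key=lambda e: -e[0])
    for t_split, child in events:
        if node.sweep is not None and node.sweep.start_gen > t_split:
            raise ValueError("sweeps must start after the branch's last split")
        _evolve_segment(engine, node, world, t_from, t_split, sweep=None)
        child_world = world.fork_deme(0)
        _found(engine, child_world, child.N, child.reset_kinship_at_found)
        _run_branch(engine, child, child_world, t_split, results, needed)
        t_from = t_split
    if node.name in needed or not needed:
        _evolve_segment(engine, node, world, t_from, 0, sweep=node.sweep)
        results[node.name] = world


def _evolve_segment(engine, node, world, t_from, t_to, sweep):
    t = t_from
    if sweep is not None and sweep.start_gen > t_from:
        raise ValueError("sweep start predates the branch segment")
    snapshot = None
    attempts = 0
    while t > t_to:
        if (node.kinship_reference_gen is not None
                and t == node.kinship_reference_gen
                and world.track_kinship):
            d = world.demes[0]
            d.phi = 0.5 * np.eye(d.n)
            d.F = np.zeros(d.n)
        if sweep is not None and t == sweep.start_gen:
            engine.cleanup(world)
            if snapshot is None:
                snapshot = (copy.deepcopy(world.__dict__), t)
            engine.introduce_sweep(world, sweep)
        active_sweep = (
            sweep if sweep is not None and t <= sweep.start_gen else None
        )
        pairs_now = node.pairs_at(t - 1)
        p_sib_now = (node.p_sib
                     if node.n_breeding_pairs is None or pairs_now is not None
                     else 0.0)
        engine.step(world, [node.size_at(t - 1)], [p_sib_now], [active_sweep],
                    pairs=[pairs_now])
        t -= 1
        if (sweep is not None and sweep.min_final_freq is not None
                and t == t_to):
            freq = engine.sweep_frequency(world, sweep)
            if freq < sweep.min_final_freq:
                attempts += 1
                if attempts > sweep.max_retries:
                    raise RuntimeError(
                        f"sweep failed to reach {sweep.min_final_freq} in "
                        f"{sweep.max_retries} attempts")
                state, t = snapshot
                world.__dict__.update(copy.deepcopy(state))
                # the loop re-introduces the sweep when t == start_gen


def _found(engine, world, N_new, reset_kinship):
    """Found a daughter deme by one round of reproduction from the parent."""
    engine.step(world, [N_new], [0.0], [None])
    if reset_kinship and world.track_kinship:
        d = world.demes[0]
        d.phi = 0.5 * np.eye(N_new)
        d.F = np.zeros(N_new)
        d.parent_pair = np.full((N_new, 2), -1, dtype=np.int64)


# ---------------------------------------------------------------------------
# public API


def simulate(config: SimulationConfig):
    """Run the configured simulation.

    Returns (GenotypeMatrix, PopulationMap, Truth).  The matrix carries the
    phased haplotypes (when genotyping noise is off); a
    :class:`popkit.selection.HaplotypeSet` can be built from it with
    ``HaplotypeSet.from_genotypes``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    engine = _Engine(config, rng)
    root = config.demography
    world = engine.make_world(root.N)
    burn = config.burn_in if config.burn_in is not None else 10 * root.N
    for _ in range(burn):
        engine.step(world, [root.N], [root.p_sib], [None])
    oldest = max((t for t, _ in root.children), default=config.run_generations)
    results: dict[str, _World] = {}
    needed = set(config.sample_sizes)
    sweep_node = _find_sweep_node(root)
    if sweep_node is not None:
        needed = needed | {sweep_node.name} if needed else needed
    _run_branch(engine, root, world, oldest, results, needed)

    sample_sizes = dict(config.sample_sizes)
    if not sample_sizes:
        leaf_names = [n for n, w in results.items()]
        sample_sizes = {leaf_names[-1]: min(results[leaf_names[-1]].demes[0].n, 20)}
    for name, n in sample_sizes.items():
        if name not in results:
            raise KeyError(f"no population named {name!r} in the demography")
        if n > results[name].demes[0].n:
            raise ValueError(f"sample size {n} exceeds deme size for {name!r}")

    gm, pop_map, pedigree_f = _assemble_output(engine, config, results,
                                               sample_sizes, rng)
    sweep_interval = sweep_pos_out = final_freq = None
    if sweep_node is not None:
        sw = sweep_node.sweep
        final_freq = engine.sweep_frequency(results[sweep_node.name], sw)
        L = config.sequence_length
        chrom = str(int(sw.position // L) + 1)
        p = int(sw.position % L) + 1
        sweep_pos_out = (chrom, p)
        # hitchhiking radius: distance over which recombination during the
        # sweep's fixation time T ~ 2 ln(2N)/s is unlikely, capped at 1 Mb
        # hitchhiking radius: haplotype homogenisation is set during the
        # establishment phase (~ln(2N)/s generations), so the footprint
        # extends to where recombination over that time becomes likely,
        # d ~ s/(r ln 2N); report twice that, capped at 1 Mb
        radius = 100_000
        r_local = engine.chrom_rates[int(sw.position // L)] / L
        if sw.s > 0 and r_local > 0:
            t_est = math.log(2 * sweep_node.N) / sw.s
            radius = int(min(1_000_000,
                             max(100_000, 2.0 / (r_local * t_est))))
        sweep_interval = (chrom, max(1, p - radius), min(L, p + radius))
    truth = Truth(sweep_interval=sweep_interval, sweep_position=sweep_pos_out,
                  sweep_final_freq=final_freq, pedigree_f=pedigree_f,
                  seed=config.seed)
    return gm, pop_map, truth


def _find_sweep_node(node: DemographyNode) -> DemographyNode | None:
    if node.sweep is not None:
        return node
    for _, child in node.children:
        found = _find_sweep_node(child)
        if found is not None:
            return found
    return None


def _assemble_output(engine, config, results, sample_sizes, rng):
    L = config.sequence_length
    # union of segregating positions, plus derived-fixed positions that are
    # not fixed in every sampled population
    for name in sample_sizes:
        engine.cleanup(results[name])
    seg_union: set[float] = set()
    fixed_sets = {}
    for name in sample_sizes:
        w = results[name]
        seg_union.update(w.positions.tolist())
        fixed_sets[name] = set(w.fixed)
    common_fixed = (set.intersection(*fixed_sets.values())
                    if fixed_sets else set())
    informative_fixed = set().union(*fixed_sets.values()) - common_fixed
    pos_union = np.array(sorted(seg_union | informative_fixed))

    hap_blocks = []
    samples: list[str] = []
    assignments: dict[str, str] = {}
    pedigree_f: dict[str, float] = {}
    for name, n_samp in sample_sizes.items():
        w = results[name]
        deme = w.demes[0]
        idx = rng.choice(deme.n, size=n_samp, replace=False)
        idx.sort()
        rows = np.ravel(np.column_stack((2 * idx, 2 * idx + 1)))
        block = np.zeros((2 * n_samp, pos_union.shape[0]), dtype=np.uint8)
        col_of = np.searchsorted(pos_union, w.positions)
        block[:, col_of] = deme.H[rows]
        if fixed_sets[name] & informative_fixed:
            fixed_cols = np.searchsorted(
                pos_union, np.array(sorted(fixed_sets[name] & informative_fixed)))
            block[:, fixed_cols] = 1
        hap_blocks.append(block)
        for k, i in enumerate(idx):
            s = f"{name}_{k}"
            samples.append(s)
            assignments[s] = name
            pedigree_f[s] = float(deme.F[i])
    haps = (np.vstack(hap_blocks) if hap_blocks
            else np.zeros((0, pos_union.shape[0]), dtype=np.uint8))

    # integer coordinates; drop the rare post-rounding duplicates
    chrom_idx = (pos_union // L).astype(int)
    pos_bp = (pos_union % L).astype(int) + 1
    key = chrom_idx.astype(np.int64) * (L + 2) + pos_bp
    _, first = np.unique(key, return_index=True)
    first.sort()
    chrom_idx, pos_bp = chrom_idx[first], pos_bp[first]
    haps = haps[:, first]

    # drop sites monomorphic among the sampled haplotypes
    seg = (haps.sum(axis=0) > 0) & (haps.sum(axis=0) < haps.shape[0])
    haps = haps[:, seg]
    chrom_idx, pos_bp = chrom_idx[seg], pos_bp[seg]

    m = haps.shape[1]
    ref = _BASES[rng.integers(0, 4, size=m)]
    alt = np.array([_BASES[(np.flatnonzero(_BASES != r))[rng.integers(0, 3)]]
                    for r in ref]) if m else np.array([], dtype=str)
    variants = pd.DataFrame({
        "chrom": np.array([str(c + 1) for c in chrom_idx], dtype=object),
        "pos": pos_bp.astype(np.int64),
        "ref": ref,
        "alt": alt,
        "ancestral": "ref",
        "multiallelic": False,
    })
    calls = (haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8))
    out_haps = haps
    if config.geno_error_rate > 0:
        err = rng.random(calls.shape) < config.geno_error_rate
        calls = np.where(err, rng.integers(0, 3, size=calls.shape,
                                           dtype=np.int8), calls)
        out_haps = None
    if config.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < config.missing_rate,
                         np.int8(gio.MISSING), calls)
        out_haps = None
    chrom_lengths = {str(k + 1): L for k in range(config.n_chromosomes)}
    gm = gio.GenotypeMatrix(calls=calls, variants=variants, samples=samples,
                            phased=out_haps is not None, haplotypes=out_haps,
                            chrom_lengths=chrom_lengths)
    return gm, gio.PopulationMap(assignments), pedigree_f


# ---------------------------------------------------------------------------
# the six-population study design

STUDY_SAMPLE_SIZES = {
    "focal": 49,
    "outgroup": 25,
    "commercialA": 20,
    "commercialB": 20,
    "inbredA": 23,
    "inbredB": 24,
}

STUDY_N_CHROMOSOMES = 5
STUDY_CHROM_LENGTH = 5_000_000


def study_config(seed: int) -> SimulationConfig:
    """The six-population design used throughout testing.

    One outgroup at the ancestral size (highest diversity), two lines
    through a strong recent bottleneck with sib-mating (long ROH, slow LD
    decay), two intermediate commercial lines, and a focal population
    carrying a hard sweep at the centre of chromosome 3.  Pedigree
    bookkeeping restarts 25 generations before sampling so Truth.pedigree_f
    reflects recent inbreeding.
    """
    sweep_pos = 2 * STUDY_CHROM_LENGTH + STUDY_CHROM_LENGTH / 2 + 0.5
    focal = DemographyNode("focal", 100, kinship_reference_gen=25,
                           sweep=SweepConfig(
                               position=sweep_pos, s=0.5, h=0.5, start_gen=30,
                               min_final_freq=0.9, max_retries=100))
    inbred = lambda name: DemographyNode(  # noqa: E731
        name, 50, p_sib=0.3, bottleneck=(15, 40, 15), n_breeding_pairs=8,
        kinship_reference_gen=25)
    domestic = DemographyNode("domestic_ancestor", 150, children=[
        (150, focal),
        (150, DemographyNode("commercialA", 100, kinship_reference_gen=25)),
        (150, DemographyNode("commercialB", 100, kinship_reference_gen=25)),
        (150, inbred("inbredA")),
        (150, inbred("inbredB")),
    ])
    root = DemographyNode("ancestral", 200, children=[
        (250, DemographyNode("outgroup", 200, kinship_reference_gen=25)),
        (250, domestic),
    ])
    return SimulationConfig(
        seed=seed,
        sequence_length=STUDY_CHROM_LENGTH,
        n_chromosomes=STUDY_N_CHROMOSOMES,
        mutation_rate=8e-8,
        recombination_rate=8e-8,
        # the sweep chromosome recombines like a microchromosome, keeping
        # the hitchhiking footprint well inside the chromosome
        recombination_multipliers=[1.0, 1.0, 4.0, 1.0, 1.0],
        demography=root,
        burn_in=150,
        init="sfs",
        sample_sizes=dict(STUDY_SAMPLE_SIZES),
    )


def load_config(path: str | os.PathLike) -> SimulationConfig:
    """Read a SimulationConfig from a YAML file.

    The demography is a nested mapping: each node has name, N and
    optionally p_sib, bottleneck [start_gen, size, duration],
    n_breeding_pairs, kinship_reference_gen, sweep (mapping of SweepConfig
    fields) and children (list of nodes with an extra split_time key).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def _node_from_dict(d: dict) -> DemographyNode:
    d = dict(d)
    d.pop("split_time", None)
    children = []
    for child in d.pop("children", []) or []:
        t = int(child["split_time"])
        children.append((t, _node_from_dict(child)))
    sweep = d.pop("sweep", None)
    if sweep is not None:
        sweep = SweepConfig(**sweep)
    if "bottleneck" in d and d["bottleneck"] is not None:
        d["bottleneck"] = tuple(int(x) for x in d["bottleneck"])
    return DemographyNode(children=children, sweep=sweep, **d)


def config_from_dict(raw: dict) -> SimulationConfig:
    raw = dict(raw)
    demography = raw.pop("demography", None)
    if demography is not None:
        demography = _node_from_dict(demography)
    for key in ("mutation_rate", "recombination_rate"):
        if key in raw:
            raw[key] = float(raw[key])
    return SimulationConfig(demography=demography, **raw)


def island_model(
    seed: int,
    N: int = 200,
    m: float = 1.0 / 800.0,
    sequence_length: int = 500_000,
    mutation_rate: float = 2.5e-7,
    recombination_rate: float = 1e-8,
    generations: int = 3000,
    n_sample: int = 20,
):
    """Two-deme symmetric-migration equilibrium simulation.

    Each parental gene lineage is drawn from the other deme with
    probability ``m``, so the allele migration rate is ``m``.  The
    Weir-Cockerham-type estimate between the two demes converges to
    1 - T_within / T_between = 1/(1 + 8 N m) (structured-coalescent
    pairwise times: T_within = 4N, T_between = 4N + 1/(2m)).
    Returns (GenotypeMatrix, PopulationMap).
    """
    cfg = SimulationConfig(seed=seed, sequence_length=sequence_length,
                           n_chromosomes=1, mutation_rate=mutation_rate,
                           recombination_rate=recombination_rate,
                           init="sfs", track_kinship=False)
    rng = np.random.default_rng(seed)
    engine = _Engine(cfg, rng)
    world = engine.make_world(N)
    d0 = world.demes[0]
    world.demes.append(_Deme(d0.H.copy(), None, d0.F.copy(),
                             d0.parent_pair.copy()))
    for _ in range(generations):
        engine.step(world, [N, N], [0.0, 0.0], [None, None], migration=m)
    engine.cleanup(world)

    blocks = []
    samples: list[str] = []
    assignments: dict[str, str] = {}
    for d, name in enumerate(("deme1", "deme2")):
        idx = rng.choice(N, size=n_sample, replace=False)
        idx.sort()
        rows = np.ravel(np.column_stack((2 * idx, 2 * idx + 1)))
        blocks.append(world.demes[d].H[rows])
        for k in range(n_sample):
            s = f"{name}_{k}"
            samples.append(s)
            assignments[s] = name
    haps = np.vstack(blocks)
    pos_bp = world.positions.astype(int) + 1
    keep = np.ones(len(pos_bp), dtype=bool)
    keep[1:] = np.diff(pos_bp) > 0
    seg = (haps.sum(axis=0) > 0) & (haps.sum(axis=0) < haps.shape[0])
    keep &= seg
    haps = haps[:, keep]
    pos_bp = pos_bp[keep]
    m_sites = haps.shape[1]
    ref = _BASES[rng.integers(0, 4, size=m_sites)]
    alt = np.array(
        [_BASES[(np.flatnonzero(_BASES != rb))[rng.integers(0, 3)]] for rb in ref]
    ) if m_sites else np.array([], dtype=str)
    variants = pd.DataFrame({
        "chrom": "1", "pos": pos_bp.astype(np.int64), "ref": ref, "alt": alt,
        "ancestral": "ref", "multiallelic": False,
    })
    gm = gio.GenotypeMatrix(
        calls=haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8),
        variants=variants, samples=samples, phased=True, haplotypes=haps,
        chrom_lengths={"1": sequence_length},
    )
    return gm, gio.PopulationMap(assignments)


def emulate_study(seed: int, out_prefix: str | os.PathLike | None = None):
    """Simulate the six-population study design; optionally write the bundle.

    Returns (GenotypeMatrix, PopulationMap, Truth).  With ``out_prefix`` the
    bundle is written as VCF + popmap TSV + truth JSON.
    """
    gm, pop_map, truth = simulate(study_config(seed))
    if out_prefix is not None:
        gio.write_dataset(gm, pop_map, out_prefix)
        truth.to_json(str(out_prefix) + ".truth.json")
    return gm, pop_map, truth
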