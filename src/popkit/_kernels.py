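"""Numba inner loops.

Everything here is deterministic given its inputs: all randomness is drawn
with numpy Generators on the Python side and passed in as arrays, so seeding
stays in one place. Pure-Python oracles for these kernels live in the test
suite.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def gametes_kernel(H, bp_sites, bp_off, start_src, hap0, hap1, out):
    """Build gametes by copying stretches from two parental haplotype rows.

    H          : (n_hap, S) uint8 parental haplotypes
    bp_sites   : flat array of column indices where the source haplotype flips
    bp_off     : (n_gametes+1,) offsets into bp_sites
    start_src  : (n_gametes,) 0/1, which parental haplotype starts the gamete
    hap0, hap1 : (n_gametes,) row indices of the two parental haplotypes
    out        : (n_gametes, S) uint8, filled in place
    """
    n_g, S = out.shape
    for g in range(n_g):
        src = start_src[g]
        prev = 0
        for b in range(bp_off[g], bp_off[g + 1]):
            e = bp_sites[b]
            row = hap0[g] if src == 0 else hap1[g]
            for j in range(prev, e):
                out[g, j] = H[row, j]
            src = 1 - src
            prev = e
        row = hap0[g] if src == 0 else hap1[g]
        for j in range(prev, S):
            out[g, j] = H[row, j]


@njit(cache=False)
def viterbi2_kernel(obs_het, log_dist_stay, log_dist_switch, emit_log, init_log):
    """Two-state Viterbi over a het/hom observation sequence.

    obs_het        : (T,) uint8, 1 if the genotype is heterozygous
    log_dist_stay  : (2, T) log P(stay in state s) for the gap before site t
    log_dist_switch: (2, T) log P(leave state s) for the gap before site t
    emit_log       : (2, 2) log emission, [state, obs]
    init_log       : (2,) log initial state probabilities

    Returns the Viterbi state path (0 = NORMAL, 1 = AUTOZYGOUS).
    """
    T = obs_het.shape[0]
    path = np.empty(T, dtype=np.uint8)
    back = np.empty((T, 2), dtype=np.uint8)
    v0 = init_log[0] + emit_log[0, obs_het[0]]
    v1 = init_log[1] + emit_log[1, obs_het[0]]
    for t in range(1, T):
        o = obs_het[t]
        # into state 0
        a = v0 + log_dist_stay[0, t]
        b = v1 + log_dist_switch[1, t]
        if a >= b:
            n0 = a + emit_log[0, o]
            back[t, 0] = 0
        else:
            n0 = b + emit_log[0, o]
            back[t, 0] = 1
        # into state 1
        a = v0 + log_dist_switch[0, t]
        b = v1 + log_dist_stay[1, t]
        if a >= b:
            n1 = a + emit_log[1, o]
            back[t, 1] = 0
        else:
            n1 = b + emit_log[1, o]
            back[t, 1] = 1
        v0, v1 = n0, n1
    s = 0 if v0 >= v1 else 1
    path[T - 1] = s
    for t in range(T - 1, 0, -1):
        s = back[t, s]
        path[t - 1] = s
    return path


@njit(cache=False)
def ihh_kernel(haps, pos, core, carriers, floor):
    """Integrated EHH over both flanks for one core SNP.

    haps     : (n_hap, m) uint8
    pos      : (m,) float64 physical positions (bp)
    core     : core SNP column
    carriers : row indices of the haplotypes carrying the focal allele
               (or all rows for the allele-agnostic variant)
    floor    : EHH truncation threshold

    Returns the trapezoidal integral of EHH against bp, summed over the two
    flanks, each truncated at the first marker where EHH < floor.
    """
    n = carriers.shape[0]
    m = pos.shape[0]
    if n < 2:
        return -1.0
    npairs = 0.5 * n * (n - 1)
    total = 0.0
    grp = np.empty(n, dtype=np.int64)
    newgrp = np.empty(n, dtype=np.int64)
    relab = np.empty(2 * n, dtype=np.int64)
    sizes = np.empty(n, dtype=np.int64)
    for direction in range(2):
        for i in range(n):
            grp[i] = 0
        n_grp = 1
        prev_ehh = 1.0
        prev_pos = pos[core]
        j = core
        while True:
            j = j + 1 if direction == 0 else j - 1
            if j < 0 or j >= m:
                break
            # refine partition by the allele at marker j
            for i in range(2 * n_grp):
                relab[i] = -1
            nxt = 0
            for i in range(n):
                key = 2 * grp[i] + haps[carriers[i], j]
                if relab[key] < 0:
                    relab[key] = nxt
                    nxt += 1
                newgrp[i] = relab[key]
            n_grp = nxt
            for i in range(n_grp):
                sizes[i] = 0
            for i in range(n):
                grp[i] = newgrp[i]
                sizes[grp[i]] += 1
            acc = 0.0
            for i in range(n_grp):
                s = sizes[i]
                acc += 0.5 * s * (s - 1)
            ehh = acc / npairs
            if ehh < floor:
                break
            d = pos[j] - prev_pos
            if d < 0:
                d = -d
            total += 0.5 * (prev_ehh + ehh) * d
            prev_ehh = ehh
            prev_pos = pos[j]
            if ehh == 0.0:
                break
    return total


@njit(cache=False)
def ld_decay_kernel(G, pos, max_dist, sums, counts, keep_prob, rng_state):
    """Accumulate genotype r-squared into distance bins.

    G        : (n, m) int8 alt-dosage matrix, -1 = missing, sites sorted by pos
    pos      : (m,) int64 positions on ONE chromosome
    max_dist : maximum pair distance in bp
    sums, counts : bin accumulators; bins are per-bp up to 1 kb then 1 kb wide
    keep_prob    : pair subsampling probability (1.0 = keep all)
    rng_state    : (1,) uint64 xorshift state for subsampling
    """
    n, m = G.shape
    state = rng_state[0]
    for i in range(m):
        for j in range(i + 1, m):
            d = pos[j] - pos[i]
            if d > max_dist:
                break
            if d <= 0:
                continue
            if keep_prob < 1.0:
                state ^= state << 13
                state ^= state >> 7
                state ^= state << 17
                if (state >> 11) * (1.0 / 9007199254740992.0) >= keep_prob:
                    continue
            sx = 0.0
            sy = 0.0
            sxx = 0.0
            syy = 0.0
            sxy = 0.0
            cnt = 0
            for k in range(n):
                a = G[k, i]
                b = G[k, j]
                if a < 0 or b < 0:
                    continue
                sx += a
                sy += b
                sxx += a * a
                syy += b * b
                sxy += a * b
                cnt += 1
            if cnt < 2:
                continue
            vx = sxx - sx * sx / cnt
            vy = syy - sy * sy / cnt
            if vx <= 0.0 or vy <= 0.0:
                continue
            cov = sxy - sx * sy / cnt
            r2 = cov * cov / (vx * vy)
            if d <= 1000:
                b_id = d - 1
            else:
                b_id = 1000 + (d - 1001) // 1000
            sums[b_id] += r2
            counts[b_id] += 1
    rng_state[0] = state


@njit(cache=False)
def ld_prune_kernel(G, kept, window, step, r2_max):
    """PLINK-style greedy LD pruning over one chromosome.

    For every pair inside a sliding window of `window` SNPs whose genotype
    r-squared exceeds r2_max, the later SNP (larger position) is dropped;
    the window then advances by `step` SNPs. `kept` is modified in place.
    """
    n, m = G.shape
    w = 0
    while w < m:
        hi = min(w + window, m)
        for i in range(w, hi):
            if not kept[i]:
                continue
            for j in range(i + 1, hi):
                if not kept[j]:
                    continue
                sx = 0.0
                sy = 0.0
                sxx = 0.0
                syy = 0.0
                sxy = 0.0
                cnt = 0
                for k in range(n):
                    a = G[k, i]
                    b = G[k, j]
                    if a < 0 or b < 0:
                        continue
                    sx += a
                    sy += b
                    sxx += a * a
                    syy += b * b
                    sxy += a * b
                    cnt += 1
                if cnt < 2:
                    continue
                vx = sxx - sx * sx / cnt
                vy = syy - sy * sy / cnt
                if vx <= 0.0 or vy <= 0.0:
                    continue
                cov = sxy - sx * sy / cnt
                if cov * cov / (vx * vy) > r2_max:
                    kept[j] = False
        if hi >= m:
            break
        w += step
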