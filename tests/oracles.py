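"""Independent brute-force oracles, kept deliberately naive.

These re-derive the statistics by direct enumeration, separately from the
vectorised/JIT implementation paths they check.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def ehh_pairs(haps, core, carrier_rows, marker):
    """EHH at `marker` by enumerating all carrier pairs: the fraction of
    pairs identical over every site between the core and the marker
    (inclusive of the marker, exclusive of the core)."""
    lo, hi = (core + 1, marker) if marker > core else (marker, core - 1)
    span = list(range(lo, hi + 1))
    n = len(carrier_rows)
    if n < 2:
        return math.nan
    same = 0
    total = 0
    for a, b in itertools.combinations(carrier_rows, 2):
        total += 1
        if all(haps[a, j] == haps[b, j] for j in span):
            same += 1
    return same / total


def ihh_quadrature(haps, pos, core, carrier_rows, floor, n_grid=20001):
    """iHH by computing the full EHH step curve per flank and integrating
    with trapezoids over the recorded markers (independent transcription of
    the definition, used against the JIT kernel)."""
    m = len(pos)
    total = 0.0
    for direction in (1, -1):
        xs = [pos[core]]
        ys = [1.0]
        j = core
        while True:
            j += direction
            if j < 0 or j >= m:
                break
            e = ehh_pairs(haps, core, carrier_rows, j)
            if e < floor:
                break
            xs.append(pos[j])
            ys.append(e)
            if e == 0.0:
                break
        for k in range(1, len(xs)):
            total += 0.5 * (ys[k - 1] + ys[k]) * abs(xs[k] - xs[k - 1])
    return total


def viterbi_bruteforce(obs_het, pos, het_normal, e_het, t_in, t_out):
    """Most probable 2-state path by enumerating all 2^T paths."""
    T = len(obs_het)
    pi_az = t_in / (t_in + t_out)
    best_lp, best_path = -math.inf, None
    d = np.diff(pos, prepend=pos[0]).astype(float)
    p_in = 1.0 - np.exp(-t_in * d)
    p_out = 1.0 - np.exp(-t_out * d)

    def emit(state, t):
        p_het = e_het if state == 1 else het_normal[t]
        return math.log(p_het if obs_het[t] else 1.0 - p_het)

    for bits in itertools.product((0, 1), repeat=T):
        lp = math.log(pi_az if bits[0] else 1.0 - pi_az) + emit(bits[0], 0)
        for t in range(1, T):
            if bits[t - 1] == 0:
                pr = p_in[t] if bits[t] == 1 else 1.0 - p_in[t]
            else:
                pr = 1.0 - p_out[t] if bits[t] == 1 else p_out[t]
            lp += math.log(pr) + emit(bits[t], t)
        if lp > best_lp:
            best_lp, best_path = lp, bits
    return np.array(best_path), best_lp


def wc_scalar(n1, p1, h1, n2, p2, h2):
    """Step-by-step transcription of the two-population variance
    components, written independently of the vectorised path."""
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - 1.0 / (n_bar - 1) * (p_bar * (1 - p_bar)
                                  - (r - 1) / r * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def individual_het_loops(calls):
    """Per-sample O_hom, E_hom, S by explicit per-site loops (-1 missing)."""
    n, m = calls.shape
    out = []
    for i in range(n):
        o_hom = e_hom = 0.0
        s = 0
        for j in range(m):
            col = [calls[k, j] for k in range(n) if calls[k, j] >= 0]
            n_al = 2 * len(col)
            if n_al < 2:
                continue
            p = sum(col) / n_al
            if p in (0.0, 1.0):
                continue
            if calls[i, j] < 0:
                continue
            s += 1
            e_hom += 1.0 - 2.0 * p * (1 - p) * n_al / (n_al - 1)
            if calls[i, j] != 1:
                o_hom += 1
        out.append((o_hom, e_hom, s))
    return out
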