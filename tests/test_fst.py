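import numpy as np
import pytest

from popkit import fst, gio
from conftest import make_gm
from oracles import wc_scalar


def _two_pop_gm(calls_a, calls_b, **kw):
    calls = np.vstack([calls_a, calls_b]).astype(np.int8)
    na = len(calls_a)
    gm = make_gm(calls, **kw)
    pm = gio.PopulationMap({s: ("A" if i < na else "B")
                            for i, s in enumerate(gm.samples)})
    return gm, pm


class TestComponents:
    def test_complete_fixation(self):
        c = fst.wc_components((10, 1.0, 0.0), (10, 0.0, 0.0))
        assert c.a == pytest.approx(0.5)
        assert c.b == pytest.approx(0.0)
        assert c.c == pytest.approx(0.0)
        assert c.theta == pytest.approx(1.0)

    def test_identical_populations_nonpositive_a(self):
        c = fst.wc_components((12, 0.4, 0.3), (12, 0.4, 0.3))
        assert c.a <= 0

    def test_matches_scalar_transcription(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(2, 16, size=2)
            p1, p2 = rng.uniform(0.05, 0.95, size=2)
            h1 = min(rng.uniform(0, 1), 1.0)
            h2 = min(rng.uniform(0, 1), 1.0)
            c = fst.wc_components((n1, p1, h1), (n2, p2, h2))
            a, b, cc = wc_scalar(n1, p1, h1, n2, p2, h2)
            assert c.a == pytest.approx(a, rel=1e-12)
            assert c.b == pytest.approx(b, rel=1e-12)
            assert c.c == pytest.approx(cc, rel=1e-12)

    def test_monomorphic_flagged_zero(self):
        c = fst.wc_components((8, 0.0, 0.0), (8, 0.0, 0.0))
        assert (c.a, c.b, c.c) == (0.0, 0.0, 0.0)

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            fst.wc_components((1, 0.5, 0.5), (10, 0.5, 0.5))


class TestWindowed:
    def test_fixed_differences_every_window_one(self):
        gm, pm = _two_pop_gm(np.full((4, 6), 2), np.zeros((4, 6)),
                             pos=[1_000, 5_000, 25_000, 45_000, 65_000, 70_000],
                             chrom_lengths={"1": 80_000})
        track, gw = fst.windowed_fst(gm, pm, "A", "B")
        vals = track.data.dropna(subset=["value"])
        np.testing.assert_allclose(vals["value"].to_numpy(), 1.0)
        assert gw == pytest.approx(1.0)

    def test_duplicated_population_near_zero(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 3, size=(10, 400)).astype(np.int8)
        gm, pm = _two_pop_gm(base, base.copy(),
                             pos=np.arange(1, 401) * 100)
        _, gw = fst.windowed_fst(gm, pm, "A", "B")
        # theta is slightly negative for duplicated panels (no true
        # among-population variance); it must not exceed 0.01
        assert gw <= 0.01

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(6)
        gm, pm = _two_pop_gm(rng.integers(0, 3, size=(6, 50)),
                             rng.integers(0, 3, size=(8, 50)))
        t1, g1 = fst.windowed_fst(gm, pm, "A", "B")
        t2, g2 = fst.windowed_fst(gm, pm, "B", "A")
        assert g1 == pytest.approx(g2, rel=1e-12)
        np.testing.assert_allclose(t1.data["value"], t2.data["value"])

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 3, size=(6, 40))
        b = rng.integers(0, 3, size=(6, 40))
        gm, pm = _two_pop_gm(a, b)
        _, g1 = fst.windowed_fst(gm, pm, "A", "B")
        a2, b2 = a.copy(), b.copy()
        a2[:, 7] = 2 - a2[:, 7]
        b2[:, 7] = 2 - b2[:, 7]
        gm2, _ = _two_pop_gm(a2, b2)
        _, g2 = fst.windowed_fst(gm2, pm, "A", "B")
        assert g1 == pytest.approx(g2, rel=1e-12)

    def test_genome_wide_is_ratio_of_sums_not_mean_of_windows(self):
        # strongly unbalanced windows: window means differ from the
        # component-sum ratio
        rng = np.random.default_rng(8)
        pos = np.concatenate([np.arange(1, 31) * 1000,
                              40_001 + np.arange(1, 4) * 1000])
        a = np.zeros((6, 33), dtype=np.int8)
        b = np.full((6, 33), 2, dtype=np.int8)      # fixed differences
        b[:, 30:] = rng.integers(0, 2, size=(6, 3))  # weak signal windows
        a[:, 30:] = rng.integers(0, 2, size=(6, 3))
        gm, pm = _two_pop_gm(a, b, pos=pos, chrom_lengths={"1": 45_000})
        track, gw = fst.windowed_fst(gm, pm, "A", "B")
        window_mean = np.nanmean(track.data["value"])
        assert abs(gw - window_mean) > 0.01

    def test_uninformative_window_missing(self):
        gm, pm = _two_pop_gm(np.zeros((3, 1)), np.zeros((3, 1)),
                             pos=[500], chrom_lengths={"1": 100_000})
        track, gw = fst.windowed_fst(gm, pm, "A", "B")
        assert track.data["value"].isna().all()
        assert np.isnan(gw)


class TestPairwiseMatrix:
    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(9, 80)).astype(np.int8)
        gm = make_gm(calls)
        pm = gio.PopulationMap({s: "ABC"[i // 3] for i, s in enumerate(gm.samples)})
        mat = fst.pairwise_matrix(gm, pm)
        np.testing.assert_allclose(mat.values, mat.values.T)
        assert (np.diag(mat.values) == 0).all()

    def test_per_chromosome_restriction(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(0, 3, size=(8, 60)).astype(np.int8)
        gm = make_gm(calls, chrom=["1"] * 30 + ["2"] * 30,
                     pos=list(range(1, 31)) * 2)
        pm = gio.PopulationMap({s: ("A" if i < 4 else "B")
                                for i, s in enumerate(gm.samples)})
        full = fst.pairwise_matrix(gm, pm)
        c1 = fst.pairwise_matrix(gm, pm, chrom="1")
        c2 = fst.pairwise_matrix(gm, pm, chrom="2")
        assert c1.loc["A", "B"] != c2.loc["A", "B"]
        lo, hi = sorted([c1.loc["A", "B"], c2.loc["A", "B"]])
        assert lo <= full.loc["A", "B"] <= hi

    def test_single_sample_population_is_nan(self):
        calls = np.random.default_rng(1).integers(0, 3, (5, 30)).astype(np.int8)
        gm = make_gm(calls)
        pm = gio.PopulationMap({s: ("A" if i < 4 else "B")
                                for i, s in enumerate(gm.samples)})
        mat = fst.pairwise_matrix(gm, pm)
        assert np.isnan(mat.loc["A", "B"])

    def test_star_fixture_most_diverged_pair_largest(self):
        """Three populations drifted for different times from one ancestor:
        the pair separated longest has the largest FST."""
        rng = np.random.default_rng(10)
        m = 600
        p_anc = rng.uniform(0.2, 0.8, size=m)

        def drift(p, gens, n=40):
            p = p.copy()
            for _ in range(gens):
                p = rng.binomial(2 * n, p) / (2 * n)
            return p

        freqs = {"A": drift(p_anc, 2), "B": drift(p_anc, 2),
                 "C": drift(p_anc, 60)}
        calls = []
        labels = {}
        samples = []
        for pop, p in freqs.items():
            g = rng.binomial(2, p[None, :].repeat(8, axis=0))
            calls.append(g)
            for k in range(8):
                name = f"{pop}{k}"
                samples.append(name)
                labels[name] = pop
        gm = make_gm(np.vstack(calls).astype(np.int8), samples=samples)
        mat = fst.pairwise_matrix(gm, gio.PopulationMap(labels))
        assert mat.loc["A", "C"] > mat.loc["A", "B"]
        assert mat.loc["B", "C"] > mat.loc["A", "B"]
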