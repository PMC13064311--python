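import numpy as np
import pandas as pd
import pytest

from popkit import gio, selection
from popkit.selection import HaplotypeSet
from popkit.windows import WindowTrack
from conftest import make_gm
from oracles import ehh_pairs, ihh_quadrature


def hapset(haps, pos=None, pops=None, ancestral_known=True, chrom=None):
    haps = np.asarray(haps, dtype=np.uint8)
    n2, m = haps.shape
    assert n2 % 2 == 0
    n = n2 // 2
    variants = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000.0,
    })
    pops = pops or ["p"] * n
    return HaplotypeSet(
        haps=haps, variants=variants,
        samples=[f"s{i}" for i in range(n)], populations=pops,
        ancestral_known=np.full(m, ancestral_known),
    )


class TestEHH:
    def test_identical_carriers_stay_at_one(self):
        haps = np.tile(np.array([1, 0, 1, 1, 0, 1], dtype=np.uint8), (6, 1))
        hs = hapset(haps)
        curves = selection.ehh(hs, core_index=2, focal_allele="derived")
        assert np.allclose(curves["right"].values, 1.0)
        assert np.allclose(curves["left"].values, 1.0)

    def test_split_into_two_groups_of_two(self):
        # 4 derived carriers split 2/2 at the next marker: EHH = 2/C(4,2) = 1/3
        haps = np.array([
            [1, 0], [1, 0], [1, 1], [1, 1],
        ], dtype=np.uint8)
        hs = hapset(haps)
        curves = selection.ehh(hs, 0, "derived", ehh_floor=0.0)
        assert curves["right"].values[1] == pytest.approx(1 / 3)

    def test_core_value_is_one(self):
        rng = np.random.default_rng(0)
        hs = hapset(rng.integers(0, 2, size=(8, 10)))
        curves = selection.ehh(hs, 5, "all")
        assert curves["left"].values[0] == 1.0
        assert curves["right"].values[0] == 1.0

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(1)
        hs = hapset(rng.integers(0, 2, size=(12, 40)))
        for allele in ("ancestral", "derived", "all"):
            curves = selection.ehh(hs, 20, allele, ehh_floor=0.0)
            for c in curves.values():
                assert (np.diff(c.values) <= 1e-12).all()

    def test_single_carrier_rejected(self):
        haps = np.zeros((6, 3), dtype=np.uint8)
        haps[0, 1] = 1
        with pytest.raises(ValueError):
            selection.ehh(hapset(haps), 1, "derived")

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(2)
        haps = rng.integers(0, 2, size=(10, 15)).astype(np.uint8)
        hs = hapset(haps)
        core = 7
        carriers = np.flatnonzero(haps[:, core] == 1)
        curves = selection.ehh(hs, core, "derived", ehh_floor=0.0)
        for j, (p, v) in enumerate(zip(curves["right"].positions[1:],
                                       curves["right"].values[1:])):
            marker = core + 1 + j
            assert v == pytest.approx(ehh_pairs(haps, core, carriers, marker),
                                      abs=1e-12)


class TestIHH:
    def test_rectangle_area(self):
        # EHH constant at 1 over a 10 kb flank on each side
        haps = np.tile(np.array([1] * 11, dtype=np.uint8), (4, 1))
        pos = np.arange(0, 11) * 1000.0 + 1
        hs = hapset(haps, pos=pos)
        curves = selection.ehh(hs, 5, "derived")
        assert selection.ihh(curves) == pytest.approx(10_000.0)

    def test_matches_quadrature_oracle(self):
        from popkit._kernels import ihh_kernel
        rng = np.random.default_rng(3)
        for _ in range(10):
            n, m = 12, 25
            haps = rng.integers(0, 2, size=(n, m)).astype(np.uint8)
            pos = np.sort(rng.choice(100_000, m, replace=False)).astype(float)
            core = int(rng.integers(2, m - 2))
            carriers = np.arange(n, dtype=np.int64)
            got = ihh_kernel(haps, pos, core, carriers, 0.05)
            ref = ihh_quadrature(haps, pos, core, carriers, 0.05)
            assert got == pytest.approx(ref, abs=1e-9)


class TestIhsScan:
    def _mirror_hapset(self):
        """Ancestral and derived carriers with mirror-image structure."""
        rng = np.random.default_rng(4)
        m = 21
        half = rng.integers(0, 2, size=(6, m)).astype(np.uint8)
        mirror = half.copy()
        haps = np.vstack([half, mirror])
        core = 10
        haps[:6, core] = 0
        haps[6:, core] = 1
        return hapset(haps)

    def test_symmetric_fixture_raw_zero(self):
        hs = self._mirror_hapset()
        track = selection.ihs_scan(hs, "p", maf_min=0.0)
        core_row = track.data[track.data.pos == 11 * 1000]
        assert core_row["raw"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_standardized_bins_mean_zero_sd_one(self):
        rng = np.random.default_rng(5)
        haps = rng.integers(0, 2, size=(40, 400)).astype(np.uint8)
        hs = hapset(haps)
        track = selection.ihs_scan(hs, "p", maf_min=0.05)
        df = track.data.dropna(subset=["std"])
        assert len(df) > 50
        bins = (df["daf"] / 0.025).astype(int).clip(upper=39)
        for _, grp in df.groupby(bins):
            if len(grp) >= 2:
                assert grp["std"].mean() == pytest.approx(0.0, abs=1e-9)
                assert grp["std"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_antisymmetric_under_allele_relabel(self):
        rng = np.random.default_rng(6)
        haps = rng.integers(0, 2, size=(16, 31)).astype(np.uint8)
        hs = hapset(haps)
        t1 = selection.ihs_scan(hs, "p", maf_min=0.05)
        hs2 = hapset(1 - haps)  # relabel ancestral/derived everywhere
        t2 = selection.ihs_scan(hs2, "p", maf_min=0.05)
        merged = t1.data.merge(t2.data, on="pos", suffixes=("_a", "_b"))
        assert len(merged) > 5
        np.testing.assert_allclose(merged["raw_a"], -merged["raw_b"],
                                   atol=1e-12)

    def test_maf_filter_applied(self):
        haps = np.zeros((20, 5), dtype=np.uint8)
        haps[0, 2] = 1  # daf = 0.05 > maf at exactly 0.05? 1/20 = 0.05
        hs = hapset(haps)
        track = selection.ihs_scan(hs, "p", maf_min=0.10)
        assert len(track.data) == 0


class TestXpehhScan:
    def test_identical_populations_zero_raw(self):
        rng = np.random.default_rng(7)
        block = rng.integers(0, 2, size=(10, 25)).astype(np.uint8)
        haps = np.vstack([block, block])
        hs = hapset(haps, pops=["a"] * 5 + ["b"] * 5)
        track = selection.xpehh_scan(hs, "a", "b")
        np.testing.assert_allclose(track.data["raw"], 0.0, atol=1e-12)

    def test_swap_negates_raw(self):
        rng = np.random.default_rng(8)
        haps = rng.integers(0, 2, size=(24, 31)).astype(np.uint8)
        hs = hapset(haps, pops=["a"] * 6 + ["b"] * 6)
        t1 = selection.xpehh_scan(hs, "a", "b")
        t2 = selection.xpehh_scan(hs, "b", "a")
        np.testing.assert_allclose(t1.data["raw"], -t2.data["raw"], atol=1e-12)


class TestWindowsAndCandidates:
    def _track(self, chrom, pos, std):
        df = pd.DataFrame({"chrom": chrom, "pos": pos,
                           "raw": std, "std": std})
        return selection.ScoreTrack(statistic="test", data=df)

    def test_absolute_mean(self):
        pos = np.arange(1, 21) * 1000
        std = np.where(np.arange(20) % 2, 2.0, -2.0)
        track = self._track(["1"] * 20, pos, std)
        wins = selection.window_scores(track, {"1": 40_000})
        assert wins.data["value"].iloc[0] == pytest.approx(2.0)

    def test_window_with_nine_snps_dropped(self):
        pos = np.arange(1, 10) * 1000  # 9 scored SNPs
        track = self._track(["1"] * 9, pos, np.ones(9))
        wins = selection.window_scores(track, {"1": 40_000})
        assert len(wins.data) == 0

    def test_grid_translation(self):
        pos = np.arange(1, 41) * 900 + 10
        std = np.sin(np.arange(40)) + 2
        t1 = self._track(["1"] * 40, pos, std)
        w1 = selection.window_scores(t1, {"1": 80_000})
        shift = 40_000  # two grid steps
        t2 = self._track(["1"] * 40, pos + shift, std)
        w2 = selection.window_scores(t2, {"1": 80_000 + shift})
        merged = w1.data.merge(w2.data.assign(start=w2.data.start - shift),
                               on="start", suffixes=("_1", "_2"))
        assert len(merged) >= len(w1.data) - 1
        np.testing.assert_allclose(merged["value_1"], merged["value_2"])

    def test_top_fraction_flagging(self):
        rng = np.random.default_rng(9)
        vals = rng.permutation(10_000).astype(float)
        wins = WindowTrack(data=pd.DataFrame({
            "chrom": "1", "start": np.arange(10_000) * 20_000 + 1,
            "end": np.arange(10_000) * 20_000 + 40_000,
            "n_snps": 50, "value": vals}))
        thr, flagged = selection.call_candidates(wins, 0.001)
        assert len(flagged) == 10
        # sort oracle: the flagged set is exactly the 10 largest values
        top10 = set(np.sort(vals)[-10:])
        assert set(flagged["value"]) == top10

    def test_all_equal_flags_nothing_and_warns(self):
        wins = WindowTrack(data=pd.DataFrame({
            "chrom": "1", "start": np.arange(2000) * 20_000 + 1,
            "end": np.arange(2000) * 20_000 + 40_000,
            "n_snps": 50, "value": 1.0}))
        with pytest.warns(UserWarning):
            thr, flagged = selection.call_candidates(wins, 0.001)
        assert len(flagged) == 0

    def test_few_windows_warns(self):
        wins = WindowTrack(data=pd.DataFrame({
            "chrom": "1", "start": [1, 20_001], "end": [40_000, 60_000],
            "n_snps": 50, "value": [1.0, 2.0]}))
        with pytest.warns(UserWarning):
            selection.call_candidates(wins, 0.001)


class TestMergeAndAnnotate:
    def _flagged(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    def test_overlapping_windows_merge(self):
        flagged = self._flagged([("1", 40_001, 80_000, 2.5),
                                 ("1", 60_001, 100_000, 3.0)])
        regions = selection.merge_regions(flagged)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (40_001, 100_000)
        assert regions[0].max_score == 3.0
        assert regions[0].mean_score == pytest.approx(2.75)

    def test_gap_keeps_regions_separate(self):
        flagged = self._flagged([("3", 60_220_001, 60_360_000, 2.5),
                                 ("3", 60_400_001, 60_460_000, 2.6)])
        regions = selection.merge_regions(flagged)
        assert len(regions) == 2

    def test_single_window_region(self):
        flagged = self._flagged([("2", 1, 40_000, 2.0)])
        regions = selection.merge_regions(flagged)
        assert (regions[0].start, regions[0].end) == (1, 40_000)

    def test_overlap_and_gene_void_and_tie(self):
        regions = selection.merge_regions(self._flagged([
            ("1", 100_001, 140_000, 2.0),   # inside geneA
            ("1", 500_001, 540_000, 2.0),   # void, nearest tie at 10 kb
            ("7", 1, 40_000, 2.0),          # chromosome without features
        ]))
        feats = pd.DataFrame({
            "chrom": ["1", "1", "1"],
            "start": [90_000, 480_000, 550_000],   # 0-based half-open
            "end": [150_000, 490_000, 560_000],
            "label": ["geneA", "leftTie", "rightTie"],
        })
        with pytest.warns(UserWarning):
            annotated = selection.annotate_regions(regions, feats)
        assert annotated[0].features == ["geneA"]
        assert annotated[1].features == []
        assert set(annotated[1].nearest_feature.split("/")) == {"leftTie",
                                                                "rightTie"}
        assert annotated[1].nearest_distance == 10_000
        assert annotated[2].features == []

    def test_read_bed_and_gff(self, tmp_path):
        bed = tmp_path / "f.bed"
        bed.write_text("1\t100\t200\tqtlA\n2\t0\t50\tqtlB\n")
        df = selection.read_features(str(bed))
        assert df.loc[0, "label"] == "qtlA"
        assert df.loc[0, "start"] == 100

        gff = tmp_path / "f.gff3"
        gff.write_text("##gff-version 3\n"
                       "1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;Name=GENE1\n")
        df = selection.read_features(str(gff))
        assert df.loc[0, "label"] == "GENE1"
        assert df.loc[0, "start"] == 100  # converted to 0-based
        assert df.loc[0, "end"] == 200
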