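import numpy as np
import pytest

from popkit import gio
from conftest import make_gm, write_vcf


class TestReadVcf:
    def test_basic_dosage_and_missing(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", """\
            1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/1\t./.
            1\t200\t.\tC\tT\t50\tPASS\t.\tGT\t1/1\t0/0
            1\t300\t.\tG\tA\t50\tPASS\t.\tGT\t0/0\t0/1
            """)
        gm = gio.read_vcf(path)
        assert gm.calls.tolist() == [[1, 2, 0], [-1, 0, 1]]
        assert (gm.calls == gio.MISSING).sum() == 1
        assert not gm.phased

    def test_phased_homalt(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", "1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t1|1\t0|1\n")
        gm = gio.read_vcf(path)
        assert gm.calls[0, 0] == 2
        assert gm.phased
        assert gm.haplotypes.tolist() == [[1], [1], [0], [1]]

    def test_multiallelic_retained_and_flagged(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", """\
            1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/1\t0/0
            1\t200\t.\tC\tA,T\t50\tPASS\t.\tGT\t1/2\t0/1
            """)
        gm = gio.read_vcf(path)
        assert gm.n_variants == 2
        assert gm.variants["multiallelic"].tolist() == [False, True]

    def test_ancestral_from_aa(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", """\
            1\t100\t.\tA\tG\t50\tPASS\tAA=G\tGT\t0/1\t0/0
            1\t200\t.\tC\tT\t50\tPASS\tAA=C\tGT\t0/1\t0/0
            1\t300\t.\tC\tT\t50\tPASS\t.\tGT\t0/1\t0/0
            """)
        gm = gio.read_vcf(path)
        assert gm.variants["ancestral"].tolist() == ["alt", "ref", "unknown"]

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            gio.read_vcf(tmp_path / "nope.vcf")


class TestRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = gio.MISSING
        gm = make_gm(calls, pos=np.sort(rng.choice(10_000, 30, replace=False)) + 1)
        pm = gio.PopulationMap({s: "pop" for s in gm.samples})
        paths = gio.write_dataset(gm, pm, tmp_path / "out")
        back = gio.read_vcf(paths["vcf"])
        np.testing.assert_array_equal(back.calls, gm.calls)
        np.testing.assert_array_equal(back.variants["pos"], gm.variants["pos"])
        assert back.phased == gm.phased

    def test_phase_and_aa_preserved(self, tmp_path):
        haps = np.array([[1, 0], [0, 1], [0, 0], [1, 1]], dtype=np.uint8)
        gm = make_gm(haps[0::2] + haps[1::2], phased=True, haplotypes=haps,
                     ancestral=["ref", "unknown"])
        paths = gio.write_dataset(gm, None, tmp_path / "out")
        text = open(paths["vcf"]).read()
        assert "AA=A" in text          # emitted only for the known site
        assert text.count("AA=") == 1
        back = gio.read_vcf(paths["vcf"])
        assert back.phased
        np.testing.assert_array_equal(back.haplotypes, haps)

    def test_popmap_row_count(self, tmp_path):
        gm = make_gm(np.zeros((3, 2)) + 1)
        pm = gio.PopulationMap({"s0": "a", "s1": "a", "s2": "b"})
        paths = gio.write_dataset(gm, pm, tmp_path / "out")
        lines = open(paths["popmap"]).read().splitlines()
        assert len(lines) == 3
        assert gio.PopulationMap.read(paths["popmap"]).assignments == pm.assignments


class TestHardFilters:
    def test_thresholds_and_boundaries(self):
        gm = make_gm(
            np.ones((2, 4)),
            QD=[1.5, 5.0, 5.0, 5.0],
            MQ=[50.0, 40.0, 39.9, 50.0],
            QUAL=[50.0, 50.0, 50.0, 29.0],
        )
        out, rep = gio.apply_hard_filters(gm)
        # QD=1.5 removed; MQ=40.0 exactly retained (strict <); MQ=39.9 and
        # QUAL=29 removed
        assert out.n_variants == 1
        assert out.variants["MQ"].tolist() == [40.0]
        assert rep.n_removed == 3
        assert rep.n_input - rep.n_removed == rep.n_retained == 1

    def test_missing_annotation_passes_and_is_logged(self):
        gm = make_gm(np.ones((2, 2)), QD=[5.0, 5.0], SOR=[np.nan, 1.0])
        out, rep = gio.apply_hard_filters(gm)
        assert out.n_variants == 2
        assert rep.notes.get("SOR missing") == 1

    def test_non_numeric_annotation_errors(self):
        gm = make_gm(np.ones((2, 1)), QD=["bad"])
        with pytest.raises((ValueError, TypeError)):
            gio.apply_hard_filters(gm)


class TestFilterSites:
    def test_mac_call_rate_autosome(self):
        # site 0: single het -> MAC 1, removed; site 1: MAC 2 kept;
        # site 2: on Z removed; site 3: called in <50% removed
        calls = np.array([
            [1, 1, 1, -1],
            [0, 1, 1, -1],
            [0, 0, 0, -1],
            [0, 0, 0, 1],
        ], dtype=np.int8)
        gm = make_gm(calls, chrom=["1", "1", "Z", "1"], pos=[10, 20, 10, 40])
        out, rep = gio.filter_sites(gm, autosomes=["1", "2"])
        assert out.variants["pos"].tolist() == [20]
        assert rep.removed["not autosomal"] == 1
        assert rep.removed["MAC < 2"] == 1
        assert rep.removed["call rate < 0.5"] == 1
        assert rep.n_removed + out.n_variants == gm.n_variants

    def test_half_call_rate_boundary_kept(self):
        calls = np.array([[1], [1], [-1], [-1]], dtype=np.int8)
        out, _ = gio.filter_sites(make_gm(calls), autosomes=["1"])
        assert out.n_variants == 1  # exactly 50% called, MAC=2

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(-1, 3, size=(6, 40)).astype(np.int8)
        gm = make_gm(calls)
        once, _ = gio.filter_sites(gm, autosomes=["1"])
        twice, rep = gio.filter_sites(once, autosomes=["1"])
        assert twice.n_variants == once.n_variants
        assert rep.n_removed == 0

    def test_empty_result_warns(self):
        gm = make_gm(np.zeros((2, 1)))
        with pytest.warns(UserWarning):
            out, _ = gio.filter_sites(gm, autosomes=["1"])
        assert out.n_variants == 0

    def test_empty_autosome_list_rejected(self):
        with pytest.raises(ValueError):
            gio.filter_sites(make_gm(np.ones((2, 1))), autosomes=[])


class TestAlleleCounts:
    def test_hand_tally(self):
        calls = np.array([
            [1, 2, -1, 0, 2, 1],
            [2, -1, -1, 0, 1, 1],
            [0, 0, -1, -1, 2, 0],
            [1, 1, -1, 0, 2, -1],
        ], dtype=np.int8)
        gm = make_gm(calls)
        pm = gio.PopulationMap({s: "p" for s in gm.samples})
        n_alt, n_called = gio.allele_counts(gm, pm, "p")
        assert n_alt.tolist() == [4, 3, 0, 0, 7, 2]
        assert n_called.tolist() == [8, 6, 0, 6, 8, 6]
        assert (n_alt <= n_called).all()

    def test_two_diploids_example(self):
        gm = make_gm(np.array([[1], [2]], dtype=np.int8))
        n_alt, n_called = gio.allele_counts(gm)
        assert (n_alt[0], n_called[0]) == (3, 4)

    def test_unknown_population_errors(self):
        gm = make_gm(np.ones((2, 1)))
        pm = gio.PopulationMap({s: "p" for s in gm.samples})
        with pytest.raises(KeyError):
            gio.allele_counts(gm, pm, "nope")
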