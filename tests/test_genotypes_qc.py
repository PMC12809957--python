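"""PLINK I/O, dataset merging, LD pruning, and the staged QC pipeline."""

import numpy as np
import pandas as pd
import pytest

import flockdiv as fd
from flockdiv.errors import GenotypeError, QcStageError
from flockdiv.qc import QcParams

from conftest import make_dataset, make_pedigree


class TestPlinkIO:
    def test_ped_map_roundtrip(self, tmp_path):
        # minor allele (dosage-counted) is the rarer one in this fixture
        gd = make_dataset([[0, 1, 0], [1, 0, 0]])
        gd.write_ped_map(tmp_path / "toy")
        back = fd.GenotypeDataset.read_ped_map(tmp_path / "toy")
        np.testing.assert_array_equal(back.geno, gd.geno)
        assert list(back.samples["id"]) == list(gd.samples["id"])
        back.write_ped_map(tmp_path / "toy2")
        assert (tmp_path / "toy.ped").read_text() == \
            (tmp_path / "toy2.ped").read_text()
        assert (tmp_path / "toy.map").read_text() == \
            (tmp_path / "toy2.map").read_text()

    def test_missing_genotype_convention(self, tmp_path):
        gd = make_dataset([[2, -1], [0, 1]])
        gd.write_ped_map(tmp_path / "m")
        text = (tmp_path / "m.ped").read_text()
        assert "0 0" in text
        back = fd.GenotypeDataset.read_ped_map(tmp_path / "m")
        assert back.geno[0, 1] == -1

    def test_bed_roundtrip_and_magic(self, tmp_path):
        rng = np.random.default_rng(0)
        geno = rng.integers(-1, 3, size=(7, 13)).astype(np.int8)
        gd = make_dataset(geno)
        gd.write_bed(tmp_path / "b")
        back = fd.GenotypeDataset.read_bed(tmp_path / "b")
        np.testing.assert_array_equal(back.geno, gd.geno)
        raw = bytearray((tmp_path / "b.bed").read_bytes())
        raw[0] = 0x00
        (tmp_path / "b.bed").write_bytes(bytes(raw))
        with pytest.raises(GenotypeError, match="magic"):
            fd.GenotypeDataset.read_bed(tmp_path / "b")

    def test_malformed_ped_line_reports_number(self, tmp_path):
        gd = make_dataset([[2, 1, 0]])
        gd.write_ped_map(tmp_path / "x")
        with open(tmp_path / "x.ped", "a") as fh:
            fh.write("1 s9 0 0 1 -9 A A\n")   # truncated genotype fields
        with pytest.raises(GenotypeError, match="line 2"):
            fd.GenotypeDataset.read_ped_map(tmp_path / "x")


class TestIntersect:
    def test_identical_markers_concatenates_samples(self):
        a = make_dataset([[2, 1], [0, 0]])
        b = make_dataset([[1, 1]])
        merged, dropped = fd.intersect_datasets([a, b])
        assert merged.n_samples == 3
        assert merged.n_markers == 2
        assert not dropped
        assert set(merged.samples["dataset"]) == {"ds0", "ds1"}

    def test_disjoint_markers_error(self):
        a = make_dataset([[2, 1]], bp=[100, 200])
        b = make_dataset([[1, 1]], bp=[300, 400])
        with pytest.raises(GenotypeError, match="empty"):
            fd.intersect_datasets([a, b])

    def test_swapped_alleles_flip_dosage(self):
        a = make_dataset([[2, 0]])
        b = make_dataset([[2, 0]])
        b.markers.loc[0, ["a1", "a2"]] = ["B", "A"]   # swapped labels
        merged, dropped = fd.intersect_datasets([a, b])
        assert not dropped
        assert merged.geno[1, 0] == 0      # flipped 2 -> 0
        assert merged.geno[1, 1] == 0      # unchanged

    def test_irreconcilable_allele_dropped_and_logged(self):
        a = make_dataset([[2, 0]])
        b = make_dataset([[2, 0]])
        b.markers.loc[0, ["a1", "a2"]] = ["C", "T"]
        merged, dropped = fd.intersect_datasets([a, b])
        assert merged.n_markers == 1
        assert len(dropped) == 1


class TestLdPrune:
    def test_independent_snps_untouched(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(60, 30)).astype(np.int8)
        gd = make_dataset(geno)
        pruned = fd.ld_prune(gd, r2_threshold=0.5, window_snps=10, step=5)
        assert pruned.n_markers == 30

    def test_duplicated_snp_column_one_removed(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, size=(40, 1)).astype(np.int8)
        other = rng.integers(0, 3, size=(40, 3)).astype(np.int8)
        geno = np.hstack([col, other[:, :1], col, other[:, 1:]])
        gd = make_dataset(geno)
        pruned = fd.ld_prune(gd, r2_threshold=0.5, window_snps=5, step=2)
        assert pruned.n_markers == gd.n_markers - 1

    def test_no_surviving_window_pair_exceeds_threshold(self):
        # post-hoc exhaustive window scan of the pruned output
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
        noisy = base.copy()
        flip = rng.random(base.shape) < 0.05
        noisy[flip] = rng.integers(0, 3, size=int(flip.sum()))
        geno = np.empty((50, 40), dtype=np.int8)
        geno[:, 0::2] = base
        geno[:, 1::2] = noisy   # adjacent highly correlated pairs
        gd = make_dataset(geno)
        w, thr = 8, 0.5
        pruned = fd.ld_prune(gd, r2_threshold=thr, window_snps=w, step=3)
        from flockdiv.qc import _r2_matrix
        for start in range(0, pruned.n_markers, 1):
            win = np.arange(start, min(start + w, pruned.n_markers))
            if len(win) < 2:
                continue
            r2 = _r2_matrix(pruned.geno[:, win])
            np.fill_diagonal(r2, 0.0)
            assert r2.max() <= thr + 1e-12


class TestQcPipeline:
    @pytest.fixture
    def fixture_data(self):
        rng = np.random.default_rng(4)
        n, L = 30, 40
        geno = rng.integers(0, 3, size=(n, L)).astype(np.int8)
        geno[0, : int(0.15 * L)] = -1          # low-call-rate animal
        geno[:, 5] = 0                          # monomorphic marker
        geno[1:, 7] = -1                        # low-call-rate marker
        geno[:, 11] = geno[:, 10]               # perfect LD pair
        chrom = np.ones(L, dtype=int)
        chrom[-2:] = 27                         # non-autosomal
        gd = make_dataset(geno, chrom=chrom)
        rows = [(f"s{i}", f"P{i}", f"Q{i}", "M", 2001, "1") for i in range(n)]
        rows[2] = ("s2", "0", "0", "M", 2001, "1")   # unknown parentage
        ped = make_pedigree(rows)
        return gd, ped

    def test_bookkeeping_closes(self, fixture_data):
        gd, ped = fixture_data
        res = fd.qc_pipeline(gd, ped, QcParams())
        rep = res.report
        assert rep.removed_samples["unknown_parentage"] == 1
        assert rep.removed_samples["low_call_rate"] == 1
        assert (rep.input_samples - sum(rep.removed_samples.values())
                == rep.retained["samples"])
        assert (rep.input_markers - rep.removed_markers["non_autosomal"]
                - rep.removed_markers["low_call_rate"]
                == rep.retained["markers_callrate"])
        assert (rep.retained["markers_callrate"]
                - rep.removed_markers["ld_pruned"] == rep.retained["full"])
        assert (rep.retained["full"]
                - rep.removed_markers["low_maf_from_full"]
                == rep.retained["reduced"])

    def test_variant_definitions(self, fixture_data):
        gd, ped = fixture_data
        res = fd.qc_pipeline(gd, ped, QcParams())
        # monomorphic marker kept in full, dropped from reduced
        assert "m5" in set(res.full.markers["snp_id"])
        assert "m5" not in set(res.reduced.markers["snp_id"])
        # the perfect-LD pair is split in full but intact in the ld set
        full_ids = set(res.full.markers["snp_id"])
        ld_ids = set(res.ld.markers["snp_id"])
        assert len({"m10", "m11"} & full_ids) == 1
        assert {"m10", "m11"} <= ld_ids
        # non-autosomal markers gone everywhere
        for ds in (res.full, res.reduced, res.ld):
            assert (ds.markers["chrom"] <= 26).all()

    def test_deterministic(self, fixture_data):
        gd, ped = fixture_data
        r1 = fd.qc_pipeline(gd, ped, QcParams())
        r2 = fd.qc_pipeline(gd, ped, QcParams())
        np.testing.assert_array_equal(r1.full.geno, r2.full.geno)
        assert r1.report.to_dict() == r2.report.to_dict()

    def test_empty_stage_names_stage(self):
        gd = make_dataset(np.full((4, 6), -1, dtype=np.int8))
        with pytest.raises(QcStageError, match="call-rate"):
            fd.qc_pipeline(gd)
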