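"""MAF spectrum, heterozygosity, ROH, HBD HMM, GRM, LD decay, correlations."""

import numpy as np
import pandas as pd
import pytest

import flockdiv as fd
from flockdiv.errors import AnalysisError
from flockdiv.genomic import RohParams

from _oracles import hmm_posterior_logspace, roh_bruteforce
from conftest import make_dataset


class TestMafSpectrum:
    def test_monomorphic_all_in_first_bin(self):
        gd = make_dataset(np.zeros((10, 5), dtype=np.int8))
        spect = fd.maf_spectrum(gd)
        assert spect["proportion"].iloc[0] == 1.0

    def test_half_frequency_in_last_bin(self):
        col = np.array([2] * 25 + [1] * 50 + [0] * 25, dtype=np.int8)
        gd = make_dataset(col[:, None])
        spect = fd.maf_spectrum(gd)
        assert spect["count"].iloc[-1] == 1

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        gd = make_dataset(rng.integers(0, 3, (40, 200)).astype(np.int8))
        assert fd.maf_spectrum(gd)["proportion"].sum() == pytest.approx(1.0)


class TestHeterozygosity:
    def test_all_het_animal_f_ind_minus_one(self):
        # p = 0.5 markers: H_E = 0.5; a fully heterozygous animal has
        # F_IND = (0.5 - 1)/0.5 = -1
        geno = np.array([[1, 1, 1, 1],
                         [2, 2, 0, 0],
                         [0, 0, 2, 2],
                         [1, 1, 1, 1]], dtype=np.int8)
        res = fd.heterozygosity(make_dataset(geno))
        assert res.h_e == pytest.approx(0.5)
        assert res.f_ind.iloc[0] == pytest.approx(-1.0)

    def test_f_ind_formula(self):
        res_he, ho_i = 0.4, 0.3
        assert (res_he - ho_i) / res_he == pytest.approx(0.25)
        # and through the implementation on constructed data:
        rng = np.random.default_rng(1)
        p = 0.5
        geno = (rng.random((200, 400)) < p).astype(np.int8) + \
               (rng.random((200, 400)) < p).astype(np.int8)
        res = fd.heterozygosity(make_dataset(geno))
        i = 0
        ho = float((geno[i] == 1).mean())
        assert res.f_ind.iloc[i] == pytest.approx((res.h_e - ho) / res.h_e)

    def test_hnb_and_fis_definitions(self):
        rng = np.random.default_rng(2)
        geno = rng.integers(0, 3, (25, 60)).astype(np.int8)
        res = fd.heterozygosity(make_dataset(geno))
        n = 25
        assert res.hnb == pytest.approx(res.h_e * 2 * n / (2 * n - 1))
        assert res.f_is == pytest.approx(1 - res.h_o / res.hnb)

    def test_monomorphic_flagged(self):
        res = fd.heterozygosity(make_dataset(np.zeros((5, 4), dtype=np.int8)))
        assert res.flag is not None

    def test_by_group_table(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, (30, 50)).astype(np.int8)
        gd = make_dataset(geno, flocks=["a"] * 15 + ["b"] * 15)
        res = fd.heterozygosity(gd, gd.samples["flock"])
        assert list(res.by_group.index) == ["a", "b"]
        assert (res.by_group["n"] == 15).all()


class TestRoh:
    def test_fully_heterozygous_no_segments(self):
        gd = make_dataset(np.ones((2, 300), dtype=np.int8))
        assert len(fd.detect_roh(gd)) == 0

    def test_planted_tract_recovered_once(self):
        # the tract must exceed the window length for any window to be
        # compliant against an all-heterozygous background
        geno = np.ones((1, 400), dtype=np.int8)
        geno[0, 150:210] = 0         # 60 SNPs x 40 kb spacing = ~2.4 Mb
        gd = make_dataset(geno, spacing=40_000)
        segs = fd.detect_roh(gd)
        assert len(segs) == 1
        seg = segs.iloc[0]
        assert seg["start_bp"] >= gd.markers["bp"].iloc[150]
        assert seg["end_bp"] <= gd.markers["bp"].iloc[209]
        assert seg["roh_class"] == "1-6Mb"

    def test_short_tract_below_min_snps_rejected(self):
        geno = np.ones((1, 400), dtype=np.int8)
        geno[0, 150:175] = 0         # 25 SNPs < min_snps=30
        segs = fd.detect_roh(make_dataset(geno))
        assert len(segs) == 0

    def test_gap_splits_run(self):
        geno = np.zeros((1, 100), dtype=np.int8)   # fully homozygous
        bp = (np.arange(100) + 1) * 100_000
        bp[50:] += 1_000_000                        # 1.1 Mb gap at midpoint
        segs = fd.detect_roh(make_dataset(geno, bp=bp))
        assert len(segs) == 2

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(4)
        params = RohParams()
        for rep in range(5):
            n, L = 4, 400
            geno = rng.integers(0, 3, (n, L)).astype(np.int8)
            # plant homozygous tracts of varying lengths
            for a in range(n):
                start = rng.integers(0, L - 80)
                geno[a, start:start + rng.integers(20, 80)] = 0
            miss = rng.random(geno.shape) < 0.01
            geno[miss] = -1
            bp = np.cumsum(rng.integers(20_000, 220_000, L))
            gd = make_dataset(geno, bp=bp)
            segs = fd.detect_roh(gd, params)
            for a in range(n):
                expect = roh_bruteforce(geno[a], bp, params)
                got = segs[segs["animal"] == f"s{a}"]
                assert len(got) == len(expect)
                for (_, row), (s0, e0, ns, ln) in zip(got.iterrows(), expect):
                    assert (row["start_bp"], row["end_bp"],
                            row["n_snps"], row["length_bp"]) == (s0, e0, ns, ln)

    def test_short_chromosome_skipped(self):
        gd = make_dataset(np.zeros((1, 20), dtype=np.int8))
        segs = fd.detect_roh(gd)
        assert segs.attrs["skipped_chromosomes"] == [1]


class TestFroh:
    def test_no_segments_zero(self):
        gd = make_dataset(np.ones((2, 100), dtype=np.int8))
        segs = fd.detect_roh(gd)
        out = fd.f_roh(segs, gd)
        assert (out["F_ROH"] == 0).all()

    def test_fraction_and_class_assignment(self):
        gd = make_dataset(np.ones((1, 100), dtype=np.int8),
                          bp=(np.arange(100) + 1) * 1_000_000)  # 99 Mb span
        segs = pd.DataFrame([("s0", 1, 1_000_000, 6_000_000, 40, 5_000_000,
                              "1-6Mb")],
                            columns=["animal", "chrom", "start_bp", "end_bp",
                                     "n_snps", "length_bp", "roh_class"])
        out = fd.f_roh(segs, gd)
        assert out.loc["s0", "F_ROH"] == pytest.approx(5 / 99)
        assert out.loc["s0", "F_ROH_1-6Mb"] == pytest.approx(5 / 99)

    def test_class_components_sum_to_total(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, (10, 500)).astype(np.int8)
        for a in range(10):
            geno[a, 100:100 + rng.integers(40, 300)] = 2
        gd = make_dataset(geno, spacing=120_000)
        segs = fd.detect_roh(gd)
        out = fd.f_roh(segs, gd)
        cls_cols = [c for c in out.columns if c.startswith("F_ROH_")]
        np.testing.assert_allclose(out[cls_cols].sum(axis=1),
                                   out["F_ROH"], atol=1e-12)


class TestHbd:
    def _dataset(self, geno, spacing=100_000):
        return make_dataset(geno, spacing=spacing)

    def test_forward_backward_likelihoods_agree(self):
        rng = np.random.default_rng(6)
        geno = rng.integers(0, 3, (8, 120)).astype(np.int8)
        res = fd.hbd_posterior(self._dataset(geno))
        np.testing.assert_allclose(res.loglik_forward, res.loglik_backward,
                                   atol=1e-8)
        assert res.posterior.min() >= 0 and res.posterior.max() <= 1

    def test_matches_logspace_oracle_on_50_snps(self):
        rng = np.random.default_rng(7)
        L = 50
        freqs = rng.uniform(0.05, 0.5, L)
        geno = np.zeros((1, L), dtype=np.int8)
        geno[0] = rng.integers(0, 3, L)
        geno[0, 10:35] = np.where(rng.random(25) < freqs[10:35], 2, 0)  # homozygous stretch
        gd = self._dataset(geno)
        params = fd.HbdModelParams()
        res = fd.hbd_posterior(gd, params, freqs=freqs)
        bp = gd.markers["bp"].to_numpy()
        d_m = np.diff(bp) / 1e6 / 100.0
        post, ll = hmm_posterior_logspace(geno[0], freqs, d_m, params.rate,
                                          params.mixing, params.error)
        np.testing.assert_allclose(res.posterior[0], post, atol=1e-8)
        assert res.loglik_forward[0] == pytest.approx(ll, abs=1e-8)

    def test_fully_homozygous_rare_alleles_high_fhbd(self):
        rng = np.random.default_rng(8)
        L = 200
        freqs = np.full(L, 0.2)
        geno = np.where(rng.random((1, L)) < 0.2, 2, 0).astype(np.int8)
        params = fd.HbdModelParams(rate=2.0)
        res = fd.hbd_posterior(self._dataset(geno), params, freqs=freqs)
        assert res.f_hbd.iloc[0] > 0.9

    def test_hardy_weinberg_low_fhbd(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 0.5, 500)
        geno = ((rng.random((50, 500)) < p).astype(np.int8) +
                (rng.random((50, 500)) < p).astype(np.int8))
        res = fd.hbd_posterior(self._dataset(geno))
        assert res.f_hbd.mean() < 0.05

    def test_larger_rate_weakly_decreases_fhbd(self):
        rng = np.random.default_rng(10)
        L = 300
        freqs = np.full(L, 0.3)
        geno = np.ones((1, L), dtype=np.int8)
        geno[0, 100:160] = 0        # one long homozygous tract, het elsewhere
        gd = self._dataset(geno)
        f_small = fd.hbd_posterior(gd, fd.HbdModelParams(rate=5.0),
                                   freqs=freqs).f_hbd.iloc[0]
        f_large = fd.hbd_posterior(gd, fd.HbdModelParams(rate=200.0),
                                   freqs=freqs).f_hbd.iloc[0]
        assert f_large <= f_small + 1e-9


class TestGrm:
    def test_single_marker_formulas(self):
        # p = 0.5: dosage-2 animal has G_ii = (2-1)^2/0.5 = 2 -> F = 1
        geno = np.array([[2], [0], [1], [1]], dtype=np.int8)
        G, f = fd.grm_vanraden1(make_dataset(geno))
        assert G[0, 0] == pytest.approx(2.0)
        assert f.iloc[0] == pytest.approx(1.0)

    def test_all_het_at_half_freq(self):
        geno = np.array([[1, 1], [1, 1], [2, 0], [0, 2]], dtype=np.int8)
        _, f = fd.grm_vanraden1(make_dataset(geno))
        assert f.iloc[0] == pytest.approx(-1.0)

    def test_monomorphic_error(self):
        with pytest.raises(AnalysisError):
            fd.grm_vanraden1(make_dataset(np.zeros((4, 3), dtype=np.int8)))

    def test_fullsib_mean_relationship(self):
        # litters of full sibs: expected genomic relationship 0.5
        ped = fd.simulate_pedigree(fd.SimConfig(
            n_founder_sires=20, n_founder_dams=20, n_generations=1,
            offspring_per_dam=10, sire_reuse_max=10**6, n_flocks=1,
            migration_rate=0.0, seed=11))
        gcfg = fd.GenomeConfig(n_chromosomes=10, snps_per_chrom=500, seed=11)
        gd, _ = fd.simulate_genotypes(ped, gcfg)
        founders = ped.is_founder
        freqs = gd.subset(sample_mask=founders).allele_freq()
        G, _ = fd.grm_vanraden1(gd, freqs=freqs)
        sibs = []
        key = [(ped.sire_idx[i], ped.dam_idx[i]) for i in range(ped.n_animals)]
        for i in range(ped.n_animals):
            for j in range(i + 1, ped.n_animals):
                if key[i] == key[j] and key[i][0] >= 0:
                    sibs.append(G[i, j])
        assert len(sibs) > 0
        assert np.mean(sibs) == pytest.approx(0.5, abs=0.05)


class TestLdDecay:
    def test_duplicated_marker_r2_one(self):
        rng = np.random.default_rng(12)
        col = rng.integers(0, 3, (40, 1)).astype(np.int8)
        geno = np.hstack([col, col])
        res = fd.ld_decay(make_dataset(geno, bp=[1000, 2000]),
                          bin_width_bp=10_000)
        assert res.adjacent_mean_r2 == pytest.approx(1.0)

    def test_independent_markers_near_bias_floor(self):
        rng = np.random.default_rng(13)
        n = 100
        geno = rng.integers(0, 3, (n, 300)).astype(np.int8)
        res = fd.ld_decay(make_dataset(geno), bin_width_bp=50_000_000)
        total = (res.bins["mean_r2"] * res.bins["n_pairs"]).sum() / \
            res.bins["n_pairs"].sum()
        assert total == pytest.approx(1.0 / (n - 1), rel=0.25)

    def test_decay_in_drifted_population(self):
        ped = fd.simulate_wright_fisher_pedigree(25, 25, 8, seed=14)
        gcfg = fd.GenomeConfig(n_chromosomes=4, snps_per_chrom=150,
                               chrom_length_bp=50_000_000, seed=14)
        gd, _ = fd.simulate_genotypes(ped, gcfg)
        last = gd.samples["birth_year"] == gd.samples["birth_year"].max()
        res = fd.ld_decay(gd.subset(sample_mask=last.to_numpy()),
                          max_dist_bp=50_000_000, bin_width_bp=5_000_000)
        m = res.bins.dropna()
        x = m["dist_low"].to_numpy(dtype=float)
        y = m["mean_r2"].to_numpy()
        from scipy import stats
        rho = stats.spearmanr(x, y).statistic
        assert rho < 0


class TestCorrelations:
    def test_self_and_identity_columns(self):
        rng = np.random.default_rng(15)
        a = rng.random(50)
        b = rng.random(50)
        tbl = pd.DataFrame({"F_A": a, "F_B": b, "F_SUM": a + b})
        res = fd.inbreeding_correlations(tbl)
        assert res.matrix.loc["F_A", "F_A"] == 1.0
        two = pd.DataFrame({"x": a, "total": 0.7 * a + 0.3 * a})
        assert fd.inbreeding_correlations(two).matrix.loc["x", "total"] == \
            pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        tbl = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.5, 0.5, 0.5]})
        res = fd.inbreeding_correlations(tbl)
        assert res.undefined == ["b"]
        assert np.isnan(res.matrix.loc["a", "b"])
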