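"""Pedigree inbreeding, relatedness, gene-origin and coancestry-FST."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import flockdiv as fd
from flockdiv.errors import AnalysisError

from _oracles import founder_contribution_paths, random_pedigree, tabular_A
from conftest import make_pedigree


class TestInbreedingAndRelatedness:
    def test_unrelated_parents_give_zero(self):
        ped = make_pedigree([("A", None, None, "M", 2000, "1"),
                             ("B", None, None, "F", 2000, "1"),
                             ("C", "A", "B", "M", 2001, "1")])
        assert fd.inbreeding_ml(ped)["C"] == 0.0

    def test_fullsib_line_sequence(self, fullsib_line):
        F = fd.inbreeding_ml(fullsib_line)
        assert [F[f"s{g}"] for g in range(2, 6)] == [0.25, 0.375, 0.5, 0.59375]

    def test_parent_offspring_mating(self):
        ped = make_pedigree([("S", None, None, "M", 2000, "1"),
                             ("D", None, None, "F", 2000, "1"),
                             ("A", "S", "D", "F", 2001, "1"),
                             ("X", "S", "A", "M", 2002, "1")])
        assert fd.inbreeding_ml(ped)["X"] == 0.25

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_tabular_relationship_matrix(self, seed):
        rng = np.random.default_rng(seed)
        ped = fd.PedigreeTable(random_pedigree(rng, 60))
        A = tabular_A(ped)
        F = fd.inbreeding_ml(ped).to_numpy()
        np.testing.assert_allclose(F, np.diag(A) - 1, atol=1e-10)
        AR = fd.average_relatedness(ped).to_numpy()
        np.testing.assert_allclose(AR, A.mean(axis=1), atol=1e-10)

    def test_ar_trio(self):
        ped = make_pedigree([("f1", None, None, "M", 2000, "1"),
                             ("f2", None, None, "F", 2000, "1"),
                             ("o", "f1", "f2", "M", 2001, "1")])
        AR = fd.average_relatedness(ped)
        assert AR["f1"] == pytest.approx(0.5)
        assert AR["o"] == pytest.approx(2.0 / 3.0)

    def test_single_animal_ar_is_one(self):
        ped = make_pedigree([("only", None, None, "M", 2000, "1")])
        assert fd.average_relatedness(ped)["only"] == 1.0


class TestDeltaFTrend:
    def test_constant_f_gives_zero_rate(self):
        F = pd.Series([0.1] * 30)
        years = pd.Series(np.repeat([2000, 2003, 2006], 10))
        res = fd.delta_f_trend(F, years, L=3.0)
        assert res.mean_delta_f == pytest.approx(0.0)
        assert res.slope == pytest.approx(0.0)

    def test_geometric_increase_constant_deltaF(self):
        # cohort means 0, 0.01, 0.0199 -> ΔF = 0.01 each step
        F = pd.Series(np.repeat([0.0, 0.01, 0.0199], 5))
        years = pd.Series(np.repeat([2000, 2002, 2004], 5))
        res = fd.delta_f_trend(F, years, L=2.0)
        assert res.mean_delta_f == pytest.approx(0.01, rel=1e-6)
        assert abs(res.slope) < 1e-8

    def test_two_cohorts_flagged(self):
        F = pd.Series([0.0, 0.1])
        years = pd.Series([2000, 2003])
        res = fd.delta_f_trend(F, years, L=3.0)
        assert res.flag is not None

    def test_wright_fisher_rate_matches_1_over_2N(self):
        # ΔF expectation 1/(2N) in an idealized population of N=20
        vals = []
        for rep in range(20):
            ped = fd.simulate_wright_fisher_pedigree(10, 10, 10, seed=100 + rep)
            F = fd.inbreeding_ml(ped)
            res = fd.delta_f_trend(
                F, pd.Series(ped.birth_year, index=ped.ids), L=1.0)
            vals.append(res.mean_delta_f)
        assert np.mean(vals) == pytest.approx(0.025, rel=0.4)


class TestGeneOrigin:
    def test_equal_founders_fe(self):
        rows = [(f"F{k}", None, None, "M" if k % 2 else "F", 2000, "1")
                for k in range(4)]
        rows += [("a", "F1", "F0", "M", 2001, "1"),
                 ("b", "F3", "F2", "F", 2001, "1"),
                 ("x", "a", "b", "M", 2002, "1")]
        ped = make_pedigree(rows)
        res = fd.founder_contributions(ped, ["x"])
        assert res.f_e == pytest.approx(4.0)
        assert res.q.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unequal_contributions_formula(self):
        # contributions 0.75 / 0.25 -> f_e = 1.6
        rows = [("A", None, None, "M", 2000, "1"),
                ("B", None, None, "F", 2000, "1"),
                ("c", "A", "B", "F", 2001, "1"),
                ("x", "A", "c", "M", 2002, "1")]
        ped = make_pedigree(rows)
        res = fd.founder_contributions(ped, ["x"])
        assert res.f_e == pytest.approx(1.6)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_contributions_match_path_counting(self, seed):
        rng = np.random.default_rng(seed)
        ped = fd.PedigreeTable(random_pedigree(rng, 30, p_known=1.0))
        C, slots = fd.founder_contribution_matrix(ped)
        i = ped.n_animals - 1
        expect = founder_contribution_paths(ped, i)
        for k, v in expect.items():
            assert C[i, slots.index(ped.ids[k])] == pytest.approx(v, abs=1e-12)
        assert C[i].sum() == pytest.approx(1.0, abs=1e-12)

    def test_dominant_sire_selected_first(self):
        rows = [("S", None, None, "M", 2000, "1")]
        rows += [(f"D{k}", None, None, "F", 2000, "1") for k in range(4)]
        rows += [(f"o{k}", "S", f"D{k}", "M", 2001, "1") for k in range(4)]
        ped = make_pedigree(rows)
        res = fd.marginal_ancestors(ped, [f"o{k}" for k in range(4)])
        assert res.table["id"].iloc[0] == "S"
        assert res.table["marginal"].iloc[0] >= 0.5

    def test_balanced_founders_fa_equals_fe(self):
        rows = [(f"F{k}", None, None, "M" if k % 2 else "F", 2000, "1")
                for k in range(4)]
        rows += [("a", "F1", "F0", "M", 2001, "1"),
                 ("b", "F3", "F2", "F", 2001, "1")]
        ped = make_pedigree(rows)
        anc = fd.marginal_ancestors(ped, ["a", "b"])
        fe = fd.founder_contributions(ped, ["a", "b"]).f_e
        assert fe == pytest.approx(4.0)
        assert anc.f_a == pytest.approx(fe)

    def test_bottleneck_ancestor_gives_ratio_above_one(self):
        rows = [("G1", None, None, "M", 1990, "1"),
                ("G2", None, None, "F", 1990, "1"),
                ("X", "G1", "G2", "M", 1995, "1")]
        rows += [(f"D{k}", None, None, "F", 1996, "1") for k in range(4)]
        refs = []
        for k in range(4):
            for j in range(2):
                rid = f"r{k}_{j}"
                rows.append((rid, "X", f"D{k}", "M", 2000, "1"))
                refs.append(rid)
        ped = make_pedigree(rows)
        anc = fd.marginal_ancestors(ped, refs)
        fe = fd.founder_contributions(ped, refs).f_e
        assert anc.table["id"].iloc[0] == "X"
        assert anc.f_a < fe
        assert anc.table["marginal"].sum() <= 1.0 + 1e-12
        assert np.all(np.diff(anc.table["marginal"]) <= 1e-12)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fa_never_exceeds_fe(self, seed):
        rng = np.random.default_rng(seed)
        ped = fd.PedigreeTable(random_pedigree(rng, 50, p_known=0.9))
        refs = ped.ids[-10:]
        fa = fd.marginal_ancestors(ped, refs).f_a
        fe = fd.founder_contributions(ped, refs).f_e
        assert fa <= fe + 1e-9

    def test_gci_examples(self):
        rows = [("S", None, None, "M", 2000, "1"),
                ("D1", None, None, "F", 2000, "1"),
                ("D2", None, None, "F", 2000, "1"),
                ("h1", "S", "D1", "M", 2001, "1"),
                ("h2", "S", "D2", "F", 2001, "1"),
                ("x", "h1", "h2", "M", 2002, "1")]
        g = fd.gci(make_pedigree(rows))
        assert g["S"] == 1.0                       # founder
        # x has founder shares 0.5, 0.25, 0.25 -> 1/0.375
        assert g["x"] == pytest.approx(1.0 / 0.375)


class TestPedigreeFstNei:
    def test_single_flock_fst_zero(self):
        rows = [("A", None, None, "M", 2000, "1"),
                ("B", None, None, "F", 2000, "1"),
                ("C", "A", "B", "M", 2001, "1")]
        res = fd.pedigree_fst_nei(make_pedigree(rows))
        assert res.fst == pytest.approx(0.0, abs=1e-12)

    def test_formula_values(self):
        # two unrelated families in different flocks: within-flock
        # coancestry exceeds the population mean -> positive FST and
        # symmetric positive Nei distance
        rows = []
        for f in ("1", "2"):
            rows += [(f"S{f}", None, None, "M", 2000, f),
                     (f"D{f}", None, None, "F", 2000, f),
                     (f"O{f}", f"S{f}", f"D{f}", "M", 2001, f)]
        res = fd.pedigree_fst_nei(make_pedigree(rows))
        assert res.fst > 0
        D = res.nei_distance
        assert np.allclose(D.values, D.values.T)
        assert np.all(np.diag(D.values) == 0)
        assert D.loc["1", "2"] > 0
        # Eq. check: FST = (f̄ − f̃)/(1 − f̃) with the computed means
        fbar = float(np.average(res.flock_mean_coancestry,
                                weights=res.flock_sizes))
        ft = res.population_mean_coancestry
        assert res.fst == pytest.approx((fbar - ft) / (1 - ft))

    def test_empty_flock_rejected(self):
        rows = [("A", None, None, "M", 2000, "1"),
                ("B", None, None, "F", 2000, None)]
        ped = make_pedigree(rows)
        flocks = pd.Series(["1", None], index=["A", "B"]).dropna()
        res = fd.pedigree_fst_nei(ped, pd.Series(["1"], index=["A"]))
        assert res.fst == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(AnalysisError):
            fd.pedigree_fst_nei(ped, pd.Series([], dtype=object))
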