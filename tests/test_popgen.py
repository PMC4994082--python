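"""Diversity indices, F-statistics, exact tests, allelic richness."""

import numpy as np
import pytest
from scipy.special import comb

import msatpipe as mp
from msatpipe import popgen

from conftest import toy_matrix


class TestMissingFilters:
    def test_locus_with_too_much_missing_dropped(self):
        geno = [[(0, 0), (0, 0)] for _ in range(10)]
        for i in range(2):  # 20% missing at locus 2
            geno[i][1] = None
        gm = toy_matrix(geno, ["P1"] * 5 + ["P2"] * 5)
        out = popgen.apply_missing_filters(gm, max_locus_missing=0.15)
        assert out.loci == ["L1"]

    def test_complete_matrix_unchanged(self):
        geno = [[(0, 1), (1, 1)] for _ in range(6)]
        gm = toy_matrix(geno, ["P1"] * 3 + ["P2"] * 3)
        out = popgen.apply_missing_filters(gm)
        assert out.loci == gm.loci and out.individuals == gm.individuals

    def test_matches_brute_force_order(self):
        rng = np.random.default_rng(4)
        n, L = 30, 8
        geno = [
            [
                None if rng.random() < 0.2 else (int(rng.integers(2)), int(rng.integers(2)))
                for _ in range(L)
            ]
            for _ in range(n)
        ]
        gm = toy_matrix(geno, ["P1"] * 15 + ["P2"] * 15)
        out = popgen.apply_missing_filters(gm, 0.15, 0.35)
        miss = gm.missing_mask
        keep_loci = [l for l in range(L) if miss[:, l].mean() < 0.15]
        keep_ind = [
            i for i in range(n) if miss[i, keep_loci].mean() < 0.35
        ]
        assert out.loci == [gm.loci[l] for l in keep_loci]
        assert out.individuals == [gm.individuals[i] for i in keep_ind]

    def test_all_loci_dropped_errors(self):
        geno = [[None] for _ in range(4)]
        geno[0][0] = (0, 0)
        gm = toy_matrix(geno, ["P1"] * 2 + ["P2"] * 2)
        with pytest.raises(ValueError, match="missing-data threshold"):
            popgen.apply_missing_filters(gm)


class TestDiversityIndices:
    def test_nei_chesser_hand_case(self):
        """One population of genotypes AA, AB, AB, BB (duplicated so the
        between-population machinery runs): HO = 0.5, HS = 0.5833."""
        geno = [[(0, 0)], [(0, 1)], [(0, 1)], [(1, 1)]] * 2
        gm = toy_matrix(geno, ["P1"] * 4 + ["P2"] * 4)
        res = popgen.diversity_indices(gm)
        assert res.per_locus.loc["L1", "HO"] == pytest.approx(0.5)
        assert res.per_locus.loc["L1", "HS"] == pytest.approx(0.5833, abs=5e-5)

    def test_identical_populations_no_differentiation(self):
        # duplicated population: differentiation estimates vanish as n grows
        rng = np.random.default_rng(0)
        block = [[(int(rng.integers(3)), int(rng.integers(3)))] for _ in range(100)]
        gm = toy_matrix(block + block, ["P1"] * 100 + ["P2"] * 100)
        res = popgen.diversity_indices(gm)
        for stat in ("GST", "G_ST_hedrick", "D_jost"):
            assert res.per_locus.loc["L1", stat] == pytest.approx(0.0, abs=0.01)

    def test_fixed_differences_maximal(self):
        geno = [[(0, 0)]] * 4 + [[(1, 1)]] * 4
        gm = toy_matrix(geno, ["P1"] * 4 + ["P2"] * 4)
        res = popgen.diversity_indices(gm)
        assert res.per_locus.loc["L1", "G_ST_hedrick"] == pytest.approx(1.0)
        assert res.per_locus.loc["L1", "D_jost"] == pytest.approx(1.0)

    def test_monomorphic_locus_flagged(self):
        geno = [[(0, 0), (0, 1)] for _ in range(8)]
        gm = toy_matrix(geno, ["P1"] * 4 + ["P2"] * 4, labels={"L1": [1], "L2": [1, 2]})
        res = popgen.diversity_indices(gm)
        assert res.monomorphic == ["L1"]
        assert np.isnan(res.per_locus.loc["L1", "GST"])

    def test_single_population_errors(self):
        gm = toy_matrix([[(0, 1)]] * 4, ["P1"] * 4)
        with pytest.raises(ValueError):
            popgen.diversity_indices(gm)


class TestAmova:
    def test_weir_cockerham_hand_oracle(self):
        """6 individuals, 2 populations, 1 locus: components match an exact
        rational-arithmetic evaluation of the estimator (a = 1/12,
        b = c = 1/3, FST = 1/9, FIS = 1/2)."""
        geno = [[(0, 0)], [(0, 1)], [(1, 1)], [(1, 1)], [(1, 2)], [(2, 2)]]
        gm = toy_matrix(geno, ["P1"] * 3 + ["P2"] * 3)
        comp = popgen._wc_locus_components(gm.alleles[:, 0, :], gm.pop_indices, 2, 3)
        assert comp == pytest.approx((1 / 12, 1 / 3, 1 / 3))
        res = popgen.amova_fstats(gm, permutations=0)
        assert res.fst == pytest.approx(1 / 9)
        assert res.fis == pytest.approx(1 / 2)

    def test_fixed_differences_fst_one(self):
        geno = [[(0, 0)]] * 5 + [[(1, 1)]] * 5
        gm = toy_matrix(geno, ["P1"] * 5 + ["P2"] * 5)
        res = popgen.amova_fstats(gm, permutations=199, rng=np.random.default_rng(0))
        assert res.fst == pytest.approx(1.0)
        # only permutations reproducing the exact split can reach FST = 1
        assert res.p_fst <= 0.05

    def test_identical_populations_null(self):
        rng = np.random.default_rng(8)
        block = [[(int(rng.integers(3)), int(rng.integers(3))) for _ in range(4)] for _ in range(20)]
        gm = toy_matrix(block + block, ["P1"] * 20 + ["P2"] * 20)
        res = popgen.amova_fstats(gm, permutations=199, rng=rng)
        assert res.fst <= 0.01
        assert res.p_fst > 0.2

    def test_tiny_population_errors(self):
        gm = toy_matrix([[(0, 1)]] * 3, ["P1"] * 2 + ["P2"])
        with pytest.raises(ValueError, match="P2"):
            popgen.amova_fstats(gm, permutations=0)


class TestStandardizedFst:
    def test_disjoint_allele_sets_give_one(self):
        geno = [[(0, 1)]] * 5 + [[(2, 3)]] * 5
        gm = toy_matrix(geno, ["P1"] * 5 + ["P2"] * 5)
        res = popgen.standardized_fst(gm, permutations=0)
        assert res.fprime_st == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(1)
        block = [[(int(rng.integers(4)), int(rng.integers(4)))] for _ in range(250)]
        gm = toy_matrix(block + block, ["P1"] * 250 + ["P2"] * 250)
        res = popgen.standardized_fst(gm, permutations=0)
        assert abs(res.fprime_st) < 0.02

    def test_fprime_at_least_fst_with_diversity(self):
        rng = np.random.default_rng(2)
        freqs = mp.draw_pop_freqs(np.full(6, 1 / 6), 0.10, 3, rng)
        geno = mp.simulate_genotypes(freqs, [40, 40, 40], rng)
        gm = toy_matrix(
            [[tuple(geno[i])] for i in range(120)],
            ["P1"] * 40 + ["P2"] * 40 + ["P3"] * 40,
            labels={"L1": list(range(1, 7))},
        )
        res = popgen.standardized_fst(gm, permutations=0)
        assert res.fprime_st >= res.fst

    def test_monomorphic_identical_pops_undefined(self):
        gm = toy_matrix([[(0, 0)]] * 6, ["P1"] * 3 + ["P2"] * 3, labels={"L1": [1]})
        with pytest.raises(ValueError, match="undefined|FST"):
            popgen.standardized_fst(gm, permutations=0)


class TestPairwise:
    def test_pairs_match_standalone_runs(self):
        rng = np.random.default_rng(3)
        freqs = mp.draw_pop_freqs(np.full(5, 0.2), 0.15, 3, rng)
        geno = mp.simulate_genotypes(freqs, [20, 20, 20], rng)
        gm = toy_matrix(
            [[tuple(geno[i])] for i in range(60)],
            ["P1"] * 20 + ["P2"] * 20 + ["P3"] * 20,
            labels={"L1": list(range(1, 6))},
        )
        pw = popgen.pairwise_differentiation(gm, permutations=0)
        for a, b in (("P1", "P2"), ("P1", "P3"), ("P2", "P3")):
            sub = gm.subset_pops([a, b])
            solo = popgen.standardized_fst(sub, permutations=0)
            assert pw.value(a, b) == pytest.approx(solo.fprime_st)

    def test_fixed_pair_significant(self):
        geno = [[(0, 0)]] * 6 + [[(1, 1)]] * 6 + [[(0, 1)]] * 6
        gm = toy_matrix(geno, ["P1"] * 6 + ["P2"] * 6 + ["P3"] * 6)
        pw = popgen.pairwise_differentiation(
            gm, permutations=199, rng=np.random.default_rng(0)
        )
        assert pw.value("P1", "P2") == pytest.approx(1.0)
        assert pw.p_value("P1", "P2") <= 0.01

    def test_island_level_grouping(self):
        geno = [[(0, 0)]] * 4 + [[(0, 1)]] * 4 + [[(1, 1)]] * 4
        gm = toy_matrix(geno, ["S1"] * 4 + ["S2"] * 4 + ["S3"] * 4)
        gm.islands = {"S1": "IA", "S2": "IA", "S3": "IB"}
        pw = popgen.pairwise_differentiation(gm, level="island", permutations=0)
        assert pw.labels == ["IA", "IB"]


class TestExactTest:
    def test_fixed_difference_tiny_p(self):
        geno = [[(0, 0)]] * 10 + [[(1, 1)]] * 10
        gm = toy_matrix(geno, ["P1"] * 10 + ["P2"] * 10)
        res = popgen.exact_test(gm, steps=5000, rng=np.random.default_rng(0))
        locus_p = res[res["locus"] == "L1"]["p"].iloc[0]
        assert locus_p < 0.001

    def test_matches_hypergeometric_enumeration(self):
        """2x2 table: Monte-Carlo p within 0.01 of the exact enumeration of
        the conditional (Fisher) distribution."""
        counts = np.array([[9, 3], [4, 8]])  # allele copies
        colors = counts.sum(axis=0)
        n1 = counts[0].sum()

        def log_prob(x):
            return (
                np.log(comb(colors[0], x))
                + np.log(comb(colors[1], n1 - x))
                - np.log(comb(colors.sum(), n1))
            )

        obs = log_prob(counts[0, 0])
        lo = max(0, n1 - colors[1])
        hi = min(n1, colors[0])
        exact_p = sum(
            np.exp(log_prob(x))
            for x in range(lo, hi + 1)
            if log_prob(x) <= obs + 1e-9
        )
        geno = (
            [[(0, 0)]] * 4 + [[(0, 1)]] * 1 + [[(1, 1)]] * 1
            + [[(0, 0)]] * 2 + [[(1, 1)]] * 4
        )
        gm = toy_matrix(geno, ["P1"] * 6 + ["P2"] * 6)
        np.testing.assert_array_equal(gm.allele_counts(0), counts)
        res = popgen.exact_test(gm, steps=40_000, rng=np.random.default_rng(1))
        mc_p = res[res["locus"] == "L1"]["p"].iloc[0]
        assert mc_p == pytest.approx(exact_p, abs=0.01)

    def test_identical_populations_combined_p_not_extreme(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(50):
            block = [
                [(int(rng.integers(3)), int(rng.integers(3))) for _ in range(3)]
                for _ in range(15)
            ]
            perm = rng.permutation(30)
            rows = (block + block)
            rows = [rows[i] for i in perm]
            gm = toy_matrix(rows, ["P1"] * 15 + ["P2"] * 15)
            res = popgen.exact_test(gm, steps=400, rng=rng)
            ps.append(res[res["locus"] == "combined"]["p"].iloc[0])
        ps = np.array(ps)
        # null combined p roughly uniform: mean near 0.5, few tiny values
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.01).mean() <= 0.06


class TestAllelicRichness:
    def test_full_sample_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            counts = rng.integers(0, 20, size=rng.integers(2, 8))
            if counts.sum() < 2:
                continue
            g = int(counts.sum())
            ar = popgen.rarefied_richness(counts, g)
            assert ar == pytest.approx((counts > 0).sum())

    def test_hand_case(self):
        assert popgen.rarefied_richness(np.array([9, 1]), 2) == pytest.approx(1.2)

    def test_monotone_in_g(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            counts = rng.integers(1, 25, size=5)
            n = int(counts.sum())
            values = [popgen.rarefied_richness(counts, g) for g in range(1, n + 1)]
            assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_small_samples_flagged_not_extrapolated(self):
        geno = [[(0, 1)]] * 4 + [[(0, 0)]] * 30
        gm = toy_matrix(geno, ["P1"] * 4 + ["P2"] * 30)
        table = popgen.allelic_richness(gm, rarefaction_colonies=10)
        assert np.isnan(table.loc["L1", "P1"])
        assert not np.isnan(table.loc["L1", "P2"])


class TestInvariants:
    def test_d_zero_iff_gst_zero(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            geno = [
                [(int(rng.integers(3)), int(rng.integers(3))) for _ in range(2)]
                for _ in range(24)
            ]
            gm = toy_matrix(geno, ["P1"] * 12 + ["P2"] * 12)
            res = popgen.diversity_indices(gm)
            for locus in res.per_locus.index:
                gst = res.per_locus.loc[locus, "GST"]
                d = res.per_locus.loc[locus, "D_jost"]
                if np.isnan(gst):
                    continue
                assert (abs(gst) < 1e-12) == (abs(d) < 1e-12)

    def test_permutation_p_reproducible_under_seed(self):
        geno = [[(0, 0)]] * 6 + [[(0, 1)]] * 6
        gm = toy_matrix(geno, ["P1"] * 6 + ["P2"] * 6)
        a = popgen.amova_fstats(gm, permutations=99, rng=np.random.default_rng(3))
        b = popgen.amova_fstats(gm, permutations=99, rng=np.random.default_rng(3))
        assert (a.p_fst, a.p_fis) == (b.p_fst, b.p_fis)
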