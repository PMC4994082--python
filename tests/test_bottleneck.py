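"""Heterozygosity-excess and mode-shift bottleneck tests."""

import numpy as np
import pytest
from scipy import stats

import msatpipe as mp
from msatpipe import bottleneck as bn

from conftest import toy_matrix


class TestMutationModel:
    def test_geometric_variance_parameterization(self):
        model = bn.MutationModel("TPM", multistep_var=30.0)
        p = model.geom_p
        assert (1 - p) / p**2 == pytest.approx(30.0)

    def test_invalid_kind_and_pstep(self):
        with pytest.raises(ValueError):
            bn.MutationModel("SMM")
        with pytest.raises(ValueError):
            bn.MutationModel("TPM", p_stepwise=1.5)


class TestIamSimulator:
    def test_ewens_expected_allele_count(self):
        """Mean allele count of the urn sampler matches the Ewens closed
        form sum theta/(theta+i) within 2% at n = 50."""
        rng = np.random.default_rng(0)
        theta = 3.0
        labels = bn._iam_batch(50, theta, 10_000, rng)
        k, _ = bn._summaries(labels)
        expected = bn.ewens_expected_alleles(theta, 50)
        assert abs(k.mean() - expected) / expected < 0.02

    def test_saturation_all_distinct(self):
        heq = bn.simulate_heq(20, 20, bn.IAM, n_iter=200, rng=np.random.default_rng(1))
        # every retained simulation has all-distinct alleles: with the
        # unbiased correction the heterozygosity is exactly 1
        np.testing.assert_allclose(heq, 1.0)

    def test_seed_determinism(self):
        a = bn.simulate_heq(60, 5, bn.IAM, n_iter=500, rng=np.random.default_rng(3))
        b = bn.simulate_heq(60, 5, bn.IAM, n_iter=500, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_heq_stochastically_increases_with_k(self):
        rng = np.random.default_rng(4)
        means = [
            bn.simulate_heq(60, k, bn.IAM, n_iter=800, rng=rng).mean() for k in (3, 6, 12)
        ]
        assert means[0] < means[1] < means[2]

    def test_invalid_k_errors(self):
        for k in (1, 61):
            with pytest.raises(ValueError):
                bn.simulate_heq(60, k, bn.IAM, n_iter=10, rng=np.random.default_rng(0))


class TestTpmSimulator:
    def test_coalescent_tree_height(self):
        rng = np.random.default_rng(5)
        heights = [bn._kingman_tree(40, rng)[1].max() for _ in range(2000)]
        assert np.mean(heights) == pytest.approx(2 * (1 - 1 / 40), rel=0.05)

    def test_tpm_yields_fewer_alleles_than_iam_at_same_theta(self):
        """Homoplasy: stepwise mutations can coincide, so the TPM allele
        count is below the Ewens (IAM) expectation."""
        rng = np.random.default_rng(6)
        theta = 5.0
        ks = [np.unique(bn._tpm_once(60, theta, bn.TPM, rng)).size for _ in range(800)]
        assert np.mean(ks) < bn.ewens_expected_alleles(theta, 60)

    def test_heq_distribution_reasonable(self):
        heq = bn.simulate_heq(60, 6, bn.TPM, n_iter=300, rng=np.random.default_rng(7))
        assert len(heq) == 300
        assert 0 < heq.mean() < 1
        assert heq.std() > 0


class TestHetExcess:
    def test_all_positive_differences_exact_p(self):
        """11 loci all in excess: the one-tailed exact signed-rank p is
        1 / 2^11."""
        diffs = np.linspace(0.01, 0.05, 11)
        p = stats.wilcoxon(diffs, alternative="greater", method="exact").pvalue
        assert p == pytest.approx(1 / 2**11)
        # and the full test reproduces it on a matrix engineered for excess:
        # even frequencies maximize He given k
        geno = [[(i % 4, (i + 1) % 4) for _ in range(11)] for i in range(40)]
        gm = toy_matrix(geno, ["pop"] * 40)
        res = bn.het_excess_test(gm, "pop", bn.IAM, n_iter=400, rng=np.random.default_rng(8))
        assert (res.per_locus["DH"] > 0).all()
        assert res.wilcoxon_p == pytest.approx(1 / 2**11)

    def test_equilibrium_population_mean_dh_near_zero(self):
        rng = np.random.default_rng(9)
        dh = []
        for _ in range(25):
            gm = bn.equilibrium_population(25, 8, theta=1.0, rng=rng)
            res = bn.het_excess_test(gm, "pop", bn.IAM, n_iter=300, rng=rng)
            dh.append(res.per_locus["DH"].mean())
        assert abs(np.mean(dh)) < 0.2

    def test_founder_reduction_shows_excess(self):
        rng = np.random.default_rng(10)
        dh = []
        for _ in range(8):
            gm = bn.equilibrium_population(48, 8, theta=2.0, rng=rng)
            gb = bn.founder_reduction(gm, survival=0.05, generations=3, rng=rng)
            res = bn.het_excess_test(gb, "pop", bn.IAM, n_iter=300, rng=rng)
            dh.append(res.per_locus["DH"].mean())
        assert np.mean(dh) > 0.5

    def test_few_polymorphic_loci_warns(self):
        geno = [[(0, 0), (0, 1)] for _ in range(20)]
        gm = toy_matrix(geno, ["pop"] * 20)
        with pytest.warns(UserWarning, match="polymorphic"):
            bn.het_excess_test(gm, "pop", bn.IAM, n_iter=100, rng=np.random.default_rng(0))


class TestModeShift:
    def test_direct_binning(self):
        # frequencies 0.05, 0.06, 0.39, 0.5 over two loci
        geno = []
        for i in range(50):
            a = 0 if i < 5 else 1  # allele 0 at freq 0.05 needs copies
            geno.append([(0, 0), (0, 0)])
        # build explicit allele counts instead: 100 copies per locus
        # locus 1: counts 5, 6, 39, 50  -> freqs 0.05, 0.06, 0.39, 0.5
        copies1 = [0] * 5 + [1] * 6 + [2] * 39 + [3] * 50
        copies2 = [0] * 50 + [1] * 50
        geno = [
            [(copies1[2 * i], copies1[2 * i + 1]), (copies2[2 * i], copies2[2 * i + 1])]
            for i in range(50)
        ]
        gm = toy_matrix(geno, ["pop"] * 50)
        counts, verdict = bn.mode_shift_test(gm, "pop")
        assert counts[0] == 2  # 0.05 and 0.06
        assert counts[3] == 1  # 0.39
        assert counts[4] == 3  # the three 0.5 alleles
        assert verdict == "mode-shifted"

    def test_l_shape_verdict(self):
        # many rare alleles, one common: L shape
        copies = [0] * 92 + [1, 2, 3, 4, 5, 6, 7, 8]
        geno = [[(copies[2 * i], copies[2 * i + 1])] for i in range(50)]
        gm = toy_matrix(geno, ["pop"] * 50)
        counts, verdict = bn.mode_shift_test(gm, "pop")
        assert counts[0] == 8
        assert verdict == "L-shaped"

    def test_all_intermediate_frequencies_mode_shifted(self):
        geno = [[(0, 1)]] * 30
        gm = toy_matrix(geno, ["pop"] * 30)
        _, verdict = bn.mode_shift_test(gm, "pop")
        assert verdict == "mode-shifted"

    def test_no_polymorphism_undefined(self):
        gm = toy_matrix([[(0, 0)]] * 10, ["pop"] * 10, labels={"L1": [1]})
        with pytest.raises(ValueError, match="undefined"):
            bn.mode_shift_test(gm, "pop")

    def test_equilibrium_populations_mostly_l_shaped(self):
        rng = np.random.default_rng(11)
        verdicts = []
        for _ in range(100):
            gm = bn.equilibrium_population(30, 11, theta=5.0, rng=rng)
            verdicts.append(bn.mode_shift_test(gm, "pop")[1])
        assert np.mean([v == "L-shaped" for v in verdicts]) >= 0.9
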