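"""EM allele frequencies, diversity, GST and genotype PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA

import chubclines as cc
from chubclines.popgen import em_loglik

from test_io_filter import certain, make_gl


class TestEMFrequency:
    def test_homozygous_reference_panel_goes_to_zero(self):
        gl = certain(np.zeros((10, 1), dtype=int))
        assert cc.em_allele_frequency(gl[:, 0]) == pytest.approx(0.0, abs=1e-6)

    def test_all_heterozygote_panel_is_half(self):
        gl = certain(np.ones((10, 1), dtype=int))
        assert cc.em_allele_frequency(gl[:, 0]) == pytest.approx(0.5)

    def test_opposite_homozygotes_balance_at_half(self):
        gl = certain(np.array([[0], [2]]))
        assert cc.em_allele_frequency(gl[:, 0]) == pytest.approx(0.5)

    def test_loglik_never_decreases_over_iterations(self):
        rng = np.random.default_rng(21)
        raw = rng.random((15, 8, 3))
        gl = raw / raw.sum(axis=2, keepdims=True)
        prev = em_loglik(gl, np.full(8, 0.5))
        for it in range(1, 21):
            p = cc.em_allele_frequencies(gl, n_iter=it)
            cur = em_loglik(gl, p)
            assert np.all(cur >= prev - 1e-9)
            prev = cur

    def test_all_missing_locus_warns_and_returns_half(self):
        gl = np.full((4, 1, 3), 1 / 3)
        with pytest.warns(UserWarning, match="no data"):
            p = cc.em_allele_frequencies(gl)
        assert p[0] == 0.5

    def test_recovers_parental_frequencies_from_reads(self):
        # 50 individuals at depth 10 recover the truth within 0.05 RMSE
        freqs = cc.simulate_parental_frequencies(200, 0.8, 0.1, seed=22)
        truth, geno = cc.simulate_cohort(freqs, {"P0": 50}, seed=23)
        reads = cc.simulate_reads(geno, mean_depth=10, seed=24)
        gl = cc.genotype_likelihoods(reads)
        p = cc.em_allele_frequencies(gl.gl)
        rmse = np.sqrt(np.mean((p - freqs.f0) ** 2))
        assert rmse <= 0.05


class TestDiversity:
    def test_monomorphic_panel_has_zero_pi(self):
        gl = make_gl(np.zeros((6, 5), dtype=int), depth=np.full((6, 5), 5))
        pi = cc.nucleotide_diversity(gl, {"pop": list(gl.individuals)})
        assert pi["pop"] == pytest.approx(0.0, abs=1e-9)

    def test_single_locus_half_frequency_value(self):
        # p = 0.5 with n = 10: pi = 0.5 * 20/19
        gl = make_gl(np.ones((10, 1), dtype=int), depth=np.full((10, 1), 5))
        pi = cc.nucleotide_diversity(gl, {"pop": list(gl.individuals)})
        assert pi["pop"] == pytest.approx(0.5 * 20 / 19)

    def test_wider_frequency_spread_gives_higher_pi(self):
        near_fixed = cc.simulate_parental_frequencies(300, 0.98, 0.5, seed=25)
        balanced = cc.ParentalFrequencies(
            f0=np.full(300, 0.5), f1=np.full(300, 0.5)
        )
        pis = {}
        for name, fr in [("fixed", near_fixed), ("balanced", balanced)]:
            truth, geno = cc.simulate_cohort(fr, {"P0": 20}, seed=26)
            gl = cc.genotype_likelihoods(
                cc.simulate_reads(geno, 10, seed=27)
            )
            pis[name] = cc.nucleotide_diversity(
                gl, {"pop": list(gl.individuals)}
            )["pop"]
        assert pis["balanced"] > pis["fixed"]


class TestGST:
    def test_identical_populations_zero(self):
        f = pd.DataFrame([[0.2, 0.7], [0.2, 0.7]], index=["a", "b"])
        assert cc.pairwise_gst(f).loc["a", "b"] == pytest.approx(0.0)

    def test_fixed_differences_one(self):
        f = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["a", "b"])
        assert cc.pairwise_gst(f).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_single_locus(self):
        # p=0.3 vs 0.7: HS=0.42, HT=0.5, GST=0.16
        f = pd.DataFrame([[0.3], [0.7]], index=["a", "b"])
        assert cc.pairwise_gst(f).loc["a", "b"] == pytest.approx(0.16)

    def test_matrix_symmetric_bounded_zero_diagonal(self):
        rng = np.random.default_rng(28)
        f = pd.DataFrame(rng.random((4, 50)), index=list("abcd"))
        g = cc.pairwise_gst(f)
        np.testing.assert_allclose(g.to_numpy(), g.to_numpy().T)
        assert np.all(np.diag(g.to_numpy()) == 0)
        off = g.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.all((off >= 0) & (off <= 1))

    def test_monomorphic_pair_undefined(self):
        f = pd.DataFrame([[0.0], [0.0]], index=["a", "b"])
        assert np.isnan(cc.pairwise_gst(f).loc["a", "b"])

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            cc.pairwise_gst(pd.DataFrame([[0.5]], index=["a"]))


class TestGenotypePCA:
    def test_two_blocks_separate_on_first_component(self, fixed_freqs):
        truth, geno = cc.simulate_cohort(
            fixed_freqs, {"P0": 10, "P1": 10}, seed=29
        )
        gl = cc.genotype_likelihoods(
            cc.simulate_reads(geno, 15, seed=30, individuals=truth.individuals)
        )
        pca = cc.genotype_pca(gl)
        assert pca.explained_variance_ratio_[0] > 0.9
        pc1 = pca.scores_[:, 0]
        assert set(np.sign(pc1[truth.classes == "P0"])) != set(
            np.sign(pc1[truth.classes == "P1"])
        )

    def test_matches_svd_based_pca(self, small_cohort):
        gl = small_cohort[3]
        ours = cc.genotype_pca(gl, n_components=3)
        ref = PCA(n_components=3).fit_transform(gl.mean_genotype())
        for j in range(3):
            r = np.corrcoef(ours.scores_[:, j], ref[:, j])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_duplicated_individual_same_scores(self, small_cohort):
        gl = small_cohort[3]
        dup = gl.subset(individual_mask=np.r_[0, np.arange(gl.n_individuals)])
        pca = cc.genotype_pca(dup, n_components=3)
        np.testing.assert_allclose(
            pca.scores_[0], pca.scores_[1], atol=1e-8
        )

    def test_variance_proportions_sorted_and_sum_to_one(self, small_cohort):
        pca = cc.genotype_pca(small_cohort[3])
        ratio = pca.explained_variance_ratio_
        assert np.all(np.diff(ratio) <= 1e-12)
        assert ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reordering_individuals_permutes_scores(self, small_cohort):
        gl = small_cohort[3]
        perm = np.random.default_rng(31).permutation(gl.n_individuals)
        a = cc.genotype_pca(gl, n_components=2).scores_
        b = cc.genotype_pca(gl.subset(individual_mask=perm), n_components=2).scores_
        for j in range(2):
            r = np.corrcoef(a[perm, j], b[:, j])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_constant_matrix_rejected(self):
        gl = make_gl(np.ones((4, 5), dtype=int))
        with pytest.raises(ValueError, match="constant"):
            cc.genotype_pca(gl)
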