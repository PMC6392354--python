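"""Synthetic hybrid-zone generator: truth bookkeeping and distributions."""

import numpy as np
import pandas as pd
import pytest

import chubclines as cc


class TestParentalFrequencies:
    def test_all_fixed_when_prop_fixed_one(self, fixed_freqs):
        assert np.all(fixed_freqs.f0 <= 0.001)
        assert np.all(fixed_freqs.f1 >= 0.999)

    def test_deterministic_under_seed(self):
        a = cc.simulate_parental_frequencies(50, 0.7, 0.1, seed=5)
        b = cc.simulate_parental_frequencies(50, 0.7, 0.1, seed=5)
        np.testing.assert_array_equal(a.f0, b.f0)
        np.testing.assert_array_equal(a.f1, b.f1)

    def test_divergence_increases_frequency_gap(self):
        lo = cc.simulate_parental_frequencies(2000, 0.2, 0.0, seed=6)
        hi = cc.simulate_parental_frequencies(2000, 0.9, 0.0, seed=6)
        assert np.mean(np.abs(hi.f1 - hi.f0)) > np.mean(np.abs(lo.f1 - lo.f0))

    def test_fixed_pools_are_fully_differentiated(self, fixed_freqs):
        # GST between p~0 and p~1 panels: HS~0, HT~0.5 at every locus
        freqs = pd.DataFrame(
            [fixed_freqs.f0, fixed_freqs.f1], index=["p0", "p1"]
        )
        gst = cc.pairwise_gst(freqs)
        assert gst.loc["p0", "p1"] == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("kwargs", [
        {"n_loci": 0},
        {"n_loci": 10, "divergence": 0.0},
        {"n_loci": 10, "divergence": 1.5},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cc.simulate_parental_frequencies(**kwargs)


class TestCohort:
    def test_f1_heterozygous_at_fixed_differences(self, fixed_freqs):
        truth, geno = cc.simulate_cohort(fixed_freqs, {"F1": 5}, seed=7)
        assert np.all(geno == 1)
        np.testing.assert_allclose(truth.true_q, 0.5)
        np.testing.assert_allclose(truth.true_q12, 1.0)

    def test_f2_interpopulation_ancestry_near_half(self):
        # each F2 locus is heterospecific with probability 1/2 (gamete cross)
        freqs = cc.simulate_parental_frequencies(10_000, 1.0, 1.0, seed=8)
        truth, _ = cc.simulate_cohort(freqs, {"F2": 4}, seed=9)
        np.testing.assert_allclose(truth.true_q12, 0.5, atol=0.02)
        np.testing.assert_allclose(truth.true_q, 0.5, atol=0.02)

    def test_backcross_truth_geometry(self, fixed_freqs):
        truth, _ = cc.simulate_cohort(fixed_freqs, {"BC1": 20}, seed=10)
        # one F1 gamete (50/50) + one pure pop-1 gamete
        assert truth.true_q12.mean() == pytest.approx(0.5, abs=0.05)
        assert truth.true_q.mean() == pytest.approx(0.75, abs=0.03)

    def test_truth_bookkeeping_reconstructs_scalars(self, small_cohort):
        truth = small_cohort[0]
        q, q12 = truth.recompute()
        np.testing.assert_array_equal(q, truth.true_q)
        np.testing.assert_array_equal(q12, truth.true_q12)

    def test_q12_envelope_holds_for_all_individuals(self, small_cohort):
        truth = small_cohort[0]
        envelope = cc.max_interpop_ancestry(truth.true_q)
        assert np.all(truth.true_q12 <= envelope + 1e-12)

    def test_empty_design_rejected(self, fixed_freqs):
        with pytest.raises(ValueError):
            cc.simulate_cohort(fixed_freqs, {}, seed=1)
        with pytest.raises(ValueError):
            cc.simulate_cohort(fixed_freqs, {"F1": 0}, seed=1)


class TestReads:
    def test_zero_depth_means_all_missing(self):
        geno = np.ones((3, 5), dtype=int)
        reads = cc.simulate_reads(geno, mean_depth=0.0, seed=11)
        assert np.all(reads.n_reads == 0)

    def test_homozygous_alt_with_no_error_reads_all_alt(self):
        geno = np.full((2, 50), 2)
        reads = cc.simulate_reads(geno, mean_depth=10, error_rate=0.0, seed=12)
        np.testing.assert_array_equal(reads.n_alt, reads.n_reads)

    def test_heterozygote_allele_balance_converges_to_half(self):
        geno = np.ones((1, 20), dtype=int)
        reads = cc.simulate_reads(geno, mean_depth=20_000, seed=13)
        ratio = reads.n_alt / reads.n_reads
        np.testing.assert_allclose(ratio, 0.5, atol=0.02)

    def test_invalid_parameters_rejected(self):
        geno = np.ones((1, 1), dtype=int)
        with pytest.raises(ValueError):
            cc.simulate_reads(geno, mean_depth=-1)
        with pytest.raises(ValueError):
            cc.simulate_reads(geno, mean_depth=1, error_rate=0.5)


class TestGenotypeLikelihoods:
    def test_missing_cell_is_uniform(self):
        reads = cc.ReadCountMatrix(
            individuals=np.array(["a"]),
            contigs=np.array(["c"]),
            n_reads=np.array([[0]]),
            n_alt=np.array([[0]]),
        )
        gl = cc.genotype_likelihoods(reads)
        np.testing.assert_allclose(gl.gl[0, 0], [1 / 3, 1 / 3, 1 / 3])

    def test_matches_binomial_formula(self):
        # 10 reads all alternate at error 0.01: unnormalized likelihoods are
        # 0.01^10, 0.5^10, 0.99^10
        reads = cc.ReadCountMatrix(
            individuals=np.array(["a"]),
            contigs=np.array(["c"]),
            n_reads=np.array([[10]]),
            n_alt=np.array([[10]]),
        )
        gl = cc.genotype_likelihoods(reads, error_rate=0.01)
        raw = np.array([0.01**10, 0.5**10, 0.99**10])
        np.testing.assert_allclose(gl.gl[0, 0], raw / raw.sum(), rtol=1e-9)

    def test_triples_normalized_everywhere(self, small_cohort):
        gl = small_cohort[3]
        np.testing.assert_allclose(gl.gl.sum(axis=2), 1.0, atol=1e-9)


class TestEnvironment:
    def test_noise_free_single_slope_is_collinear(self):
        q = np.linspace(0.05, 0.95, 40)
        env = cc.simulate_environment(
            q, slopes={"specific_conductance": 1.0}, noise_sd=0.0, seed=14
        )
        r = np.corrcoef(np.log(env["specific_conductance"]), q)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_table_is_strictly_positive(self):
        q = np.random.default_rng(15).uniform(0, 1, 50)
        env = cc.simulate_environment(q, noise_sd=2.0, seed=16)
        assert (env > 0).all().all()

    def test_all_noise_covariates_rarely_selected(self):
        # with zero slopes, AIC stepwise should keep a covariate only at its
        # false-inclusion rate; across seeds the average selected count must
        # stay well below one of six
        q_rng = np.random.default_rng(17)
        n_selected = []
        slopes = {name: 0.0 for name in cc.simulate.ENV_COVARIATES}
        for seed in range(12):
            q = q_rng.uniform(0, 1, 300)
            env = cc.simulate_environment(q, slopes=slopes, noise_sd=1.0, seed=seed)
            sel = cc.stepwise_select(q, env)
            n_selected.append(len(sel.selected_))
        assert np.mean(n_selected) <= 1.5

    def test_sign_pattern_recovered(self):
        # conductance, pH and velocity rise with prairie-like ancestry;
        # depth and dissolved oxygen fall; temperature is unassociated
        q = np.random.default_rng(18).uniform(0, 1, 300)
        env = cc.simulate_environment(q, noise_sd=1.0, seed=19)
        signal = {
            k: v for k, v in cc.simulate.DEFAULT_ENV_SLOPES.items() if v != 0
        }
        fit = cc.fit_ols(q, np.log(env[list(signal)]))
        for name, slope in signal.items():
            assert np.sign(fit.params[name]) == np.sign(slope), name

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            cc.simulate_environment(np.array([0.5]), noise_sd=-1)
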