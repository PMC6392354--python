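"""Genomic cline function, cline MCMC, exceptional flags, concordance."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chubclines as cc
from chubclines.clines import ConcordanceInput


class TestClineProbability:
    def test_neutral_cline_is_identity_on_grid(self):
        h = np.linspace(0, 1, 101)
        np.testing.assert_allclose(cc.cline_probability(h, 0.0, 0.0), h)

    @pytest.mark.parametrize("h", [0.0, 1.0])
    @pytest.mark.parametrize("alpha,beta", [(0, 0), (2, -3), (-1.5, 4)])
    def test_pure_individuals_fixed(self, h, alpha, beta):
        assert cc.cline_probability(h, alpha, beta) == h

    def test_hand_evaluated_value(self):
        # beta term vanishes at h = 0.5: 0.5 + 2*0.25*0.2 = 0.6
        assert cc.cline_probability(0.5, 0.2, 5.0) == pytest.approx(0.6)

    @given(
        st.floats(0, 1),
        st.floats(-3, 3),
        st.floats(-3, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_always_a_probability(self, h, alpha, beta):
        assert 0.0 <= cc.cline_probability(h, alpha, beta) <= 1.0

    def test_out_of_range_hybrid_index_rejected(self):
        with pytest.raises(ValueError):
            cc.cline_probability(1.3, 0.0, 0.0)


def enumerate_overlap_probability(l, s, m, n):
    """Exhaustive oracle: fraction of s-subsets sharing >= m of the l marked."""
    marked = set(range(l))
    hits = total = 0
    for subset in combinations(range(n), s):
        total += 1
        if len(marked.intersection(subset)) >= m:
            hits += 1
    return hits / total


class TestConcordanceProbability:
    def test_matches_exhaustive_enumeration_small_n(self):
        rng = np.random.default_rng(61)
        cases = [(2, 2, 2, 4)]
        for _ in range(20):
            n = int(rng.integers(2, 13))
            l = int(rng.integers(0, n + 1))
            s = int(rng.integers(0, n + 1))
            m = int(rng.integers(0, min(l, s) + 1))
            cases.append((l, s, m, n))
        for l, s, m, n in cases:
            expected = enumerate_overlap_probability(l, s, m, n)
            got = cc.concordance_probability(l=l, s=s, m=m, n=n)
            assert got == pytest.approx(expected, abs=1e-12), (l, s, m, n)

    def test_known_small_case(self):
        # all C(4,2)=6 subsets equally likely; only one shares both loci
        assert cc.concordance_probability(l=2, s=2, m=2, n=4) == pytest.approx(
            1 / 6
        )

    def test_zero_overlap_is_certain(self):
        assert cc.concordance_probability(l=100, s=10, m=0, n=1000) == 1.0

    def test_monotone_nonincreasing_in_m(self):
        probs = [
            cc.concordance_probability(l=50, s=20, m=m, n=500)
            for m in range(0, 21)
        ]
        assert np.all(np.diff(probs) <= 1e-15)

    def test_genome_scale_log_space_stability(self):
        p = cc.concordance_probability(l=6393, s=40, m=35, n=39122)
        assert 0 < p < 1e-4

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            ConcordanceInput(l=3, s=2, m=3, n=10)
        with pytest.raises(ValueError):
            ConcordanceInput(l=20, s=2, m=1, n=10)
        with pytest.raises(ValueError):
            ConcordanceInput(l=-1, s=2, m=0, n=10)


class TestClassifyExceptional:
    def test_flags_follow_interval_sides(self):
        class Dummy:
            alpha_ci_ = np.array([[0.1, -0.9, -0.1], [0.9, -0.1, 0.1]])
            beta_ci_ = np.array([[-0.2, 0.05, -3.0], [0.2, 0.5, -0.5]])

        flags = cc.classify_exceptional(Dummy())
        assert list(flags["alpha_flag"]) == ["+", "-", "none"]
        assert list(flags["beta_flag"]) == ["none", "+", "-"]
        assert flags.attrs["counts"] == {
            "n_pos_alpha": 1,
            "n_neg_alpha": 1,
            "n_pos_beta": 1,
            "n_neg_beta": 1,
        }


@pytest.fixture(scope="module")
def cline_smoke_fit():
    """Small neutral-cline fit used by several structural checks."""
    rng = np.random.default_rng(62)
    freqs = cc.simulate_parental_frequencies(120, 1.0, 0.4, seed=63)
    h_true = rng.beta(2, 2, 20)
    geno = cc.simulate_cline_genotypes(h_true, freqs, seed=64)
    gl = cc.genotype_likelihoods(cc.simulate_reads(geno, 8, seed=65))
    fit = cc.fit_genomic_clines(
        gl, freqs.f0, freqs.f1, n_iter=1500, burn_in=600, thin=5,
        n_chains=2, seed=66,
    )
    return h_true, fit


class TestGenomicClineModel:
    def test_hybrid_index_recovery(self, cline_smoke_fit):
        h_true, fit = cline_smoke_fit
        assert np.corrcoef(fit.h_mean_, h_true)[0, 1] > 0.9
        assert np.all((fit.h_draws_ >= 0) & (fit.h_draws_ <= 1))

    def test_summaries_ordered_and_flagging_consistent(self, cline_smoke_fit):
        _, fit = cline_smoke_fit
        assert np.all(fit.alpha_ci_[0] <= fit.alpha_ci_[1])
        flagged = fit.alpha_flag_ != "none"
        excludes = (fit.alpha_ci_[0] > 0) | (fit.alpha_ci_[1] < 0)
        np.testing.assert_array_equal(flagged, excludes)

    def test_locus_and_hybrid_tables(self, cline_smoke_fit):
        _, fit = cline_smoke_fit
        locus = fit.locus_table()
        assert {"alpha_median", "alpha_flag", "beta_flag"} <= set(locus.columns)
        hyb = fit.hybrid_table()
        assert len(hyb) == len(fit.h_mean_)

    def test_too_few_hybrids_rejected(self, cline_smoke_fit):
        freqs = cc.simulate_parental_frequencies(20, 1.0, 1.0, seed=67)
        geno = cc.simulate_cline_genotypes(np.array([0.5]), freqs, seed=68)
        gl = cc.genotype_likelihoods(cc.simulate_reads(geno, 8, seed=69))
        with pytest.raises(ValueError, match="two admixed"):
            cc.fit_genomic_clines(gl, freqs.f0, freqs.f1)

    def test_identical_parental_frequencies_rejected(self):
        freqs = cc.simulate_parental_frequencies(20, 1.0, 1.0, seed=70)
        geno = cc.simulate_cline_genotypes(np.array([0.4, 0.6]), freqs, seed=71)
        gl = cc.genotype_likelihoods(cc.simulate_reads(geno, 8, seed=72))
        same = np.full(20, 0.5)
        with pytest.raises(ValueError, match="unidentifiable"):
            cc.fit_genomic_clines(gl, same, same)
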