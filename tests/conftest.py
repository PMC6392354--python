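"""Shared fixtures: small simulated hybrid-zone datasets.

Everything is generated at test time from fixed seeds; session scope keeps
the MCMC-backed fixtures affordable.
"""

import pytest

import chubclines as cc


@pytest.fixture(scope="session")
def fixed_freqs():
    """Fully diverged parental pools: every locus a near-fixed difference."""
    return cc.simulate_parental_frequencies(
        200, divergence=1.0, prop_fixed=1.0, seed=101
    )


@pytest.fixture(scope="session")
def diverged_freqs():
    """Strongly but not fully diverged pools with 20% fixed differences."""
    return cc.simulate_parental_frequencies(
        300, divergence=0.9, prop_fixed=0.2, seed=102
    )


@pytest.fixture(scope="session")
def small_cohort(diverged_freqs):
    """Mixed cohort with truth labels, reads at depth ~7 and likelihoods."""
    truth, geno = cc.simulate_cohort(
        diverged_freqs,
        {"P0": 8, "P1": 8, "F1": 4, "F2": 4, "BC0": 3, "BC1": 3, "LATE": 10},
        seed=103,
    )
    reads = cc.simulate_reads(
        geno, mean_depth=7.0, error_rate=0.01, seed=104,
        individuals=truth.individuals,
    )
    gl = cc.genotype_likelihoods(reads, error_rate=0.01)
    return truth, geno, reads, gl


def ids_of(truth, cls):
    """Individual ids of one simulated class."""
    return [i for i, c in zip(truth.individuals, truth.classes) if c == cls]


@pytest.fixture(scope="session")
def parental_panels(small_cohort):
    truth = small_cohort[0]
    return ids_of(truth, "P0"), ids_of(truth, "P1")
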