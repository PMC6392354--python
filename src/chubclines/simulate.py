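"""Synthetic hybrid-zone data generator.

Emulates a two-species hybrid zone sampled by genotyping-by-sequencing:
two divergent parental gene pools (population 0, prairie-like; population 1,
shoal-like), admixed individuals of known class (F1, F2, backcrosses,
late-generation hybrids), shallow variable read depth (~7 reads per locus),
binomial sequencing error, and water-quality covariates whose logs are
linearly associated with ancestry. Ground truth (class labels, genome-average
ancestry q, interpopulation ancestry Q12, per-locus ancestry states) is
retained so downstream estimators can be validated by recovery.

Loci are unlinked: per-locus ancestry is drawn independently, matching the
assumptions of the downstream models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GLMatrix

__all__ = [
    "ParentalFrequencies",
    "HybridZoneTruth",
    "ReadCountMatrix",
    "CLASSES",
    "simulate_parental_frequencies",
    "simulate_cohort",
    "simulate_reads",
    "simulate_cline_genotypes",
    "genotype_likelihoods",
    "simulate_environment",
    "ENV_COVARIATES",
    "DEFAULT_ENV_SLOPES",
    "DEFAULT_ENV_INTERCEPTS",
]

#: hybrid classes: pure parents, first/second generation, backcross to
#: either parent, late-generation (many generations of admixture)
CLASSES = ("P0", "P1", "F1", "F2", "BC0", "BC1", "LATE")


@dataclass
class ParentalFrequencies:
    """Per-locus alternate-allele frequencies in the two parental pools."""

    f0: np.ndarray  # population 0 (prairie-like)
    f1: np.ndarray  # population 1 (shoal-like)
    contigs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0, dtype=float)
        self.f1 = np.asarray(self.f1, dtype=float)
        if self.f0.shape != self.f1.shape:
            raise ValueError("f0 and f1 must have the same length")
        if np.any((self.f0 < 0) | (self.f0 > 1) | (self.f1 < 0) | (self.f1 > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.contigs is None:
            self.contigs = np.array([f"contig_{i}" for i in range(self.n_loci)], dtype=object)

    @property
    def n_loci(self) -> int:
        return len(self.f0)


@dataclass
class HybridZoneTruth:
    """Simulated ground truth for a cohort.

    ``ancestry`` holds, per individual x locus, the number of gene copies
    derived from population 1 (0, 1 or 2); state 1 is the interpopulation
    (heterospecific-ancestry) state.
    """

    individuals: np.ndarray
    classes: np.ndarray
    ancestry: np.ndarray  # (N, L) in {0, 1, 2}
    true_q: np.ndarray
    true_q12: np.ndarray

    def recompute(self) -> tuple[np.ndarray, np.ndarray]:
        """Recompute (q, Q12) from the stored per-locus ancestry states."""
        l = self.ancestry.shape[1]
        q = (np.sum(self.ancestry == 2, axis=1) + 0.5 * np.sum(self.ancestry == 1, axis=1)) / l
        q12 = np.sum(self.ancestry == 1, axis=1) / l
        return q, q12

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": self.individuals,
                "class": self.classes,
                "true_q": self.true_q,
                "true_q12": self.true_q12,
            }
        )


@dataclass
class ReadCountMatrix:
    """Per-cell read totals and alternate-allele read counts."""

    individuals: np.ndarray
    contigs: np.ndarray
    n_reads: np.ndarray  # (N, L)
    n_alt: np.ndarray  # (N, L)

    def __post_init__(self) -> None:
        if np.any(self.n_alt > self.n_reads) or np.any(self.n_alt < 0):
            raise ValueError("need 0 <= n_alt <= n_reads")


def simulate_parental_frequencies(
    n_loci: int,
    divergence: float = 0.8,
    prop_fixed: float = 0.1,
    seed: int | None = None,
) -> ParentalFrequencies:
    """Draw divergent allele-frequency pairs for the two parental pools.

    A fraction ``prop_fixed`` of loci are near-fixed differences
    (f0 <= 0.001, f1 >= 0.999). The rest are drawn from a symmetric pair of
    Beta distributions with means (1 - divergence)/2 and (1 + divergence)/2,
    so the expected frequency difference grows with ``divergence``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0 < divergence <= 1:
        raise ValueError("divergence must lie in (0, 1]")
    if not 0 <= prop_fixed <= 1:
        raise ValueError("prop_fixed must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_fixed = int(round(prop_fixed * n_loci))
    f0 = np.empty(n_loci)
    f1 = np.empty(n_loci)
    f0[:n_fixed] = rng.uniform(0.0, 0.001, n_fixed)
    f1[:n_fixed] = rng.uniform(0.999, 1.0, n_fixed)
    kappa = 8.0  # Beta concentration: broad but unimodal frequency spectra
    mu0 = np.clip((1.0 - divergence) / 2.0, 0.01, 0.99)
    mu1 = np.clip((1.0 + divergence) / 2.0, 0.01, 0.99)
    n_rest = n_loci - n_fixed
    if n_rest:
        f0[n_fixed:] = rng.beta(mu0 * kappa, (1 - mu0) * kappa, n_rest)
        f1[n_fixed:] = rng.beta(mu1 * kappa, (1 - mu1) * kappa, n_rest)
    return ParentalFrequencies(f0=f0, f1=f1)


def _copy_ancestries(cls: str, n: int, n_loci: int, late_q_beta, rng) -> np.ndarray:
    """Draw per-copy ancestry (two gene copies per locus) for one class.

    Returns an (n, n_loci, 2) array of 0/1 population labels.
    """
    shape = (n, n_loci)
    if cls == "P0":
        a = np.zeros(shape + (2,), dtype=np.int8)
    elif cls == "P1":
        a = np.ones(shape + (2,), dtype=np.int8)
    elif cls == "F1":
        # one copy from each pool at every locus
        a = np.empty(shape + (2,), dtype=np.int8)
        a[:, :, 0] = 0
        a[:, :, 1] = 1
    elif cls == "F2":
        # each copy is an F1 gamete: ancestry 50/50 independently
        a = rng.integers(0, 2, shape + (2,)).astype(np.int8)
    elif cls in ("BC0", "BC1"):
        a = np.empty(shape + (2,), dtype=np.int8)
        a[:, :, 0] = rng.integers(0, 2, shape)  # F1 gamete
        a[:, :, 1] = 0 if cls == "BC0" else 1  # recurrent parent
    elif cls == "LATE":
        a_par, b_par = late_q_beta
        qstar = rng.beta(a_par, b_par, n)
        a = (rng.random(shape + (2,)) < qstar[:, None, None]).astype(np.int8)
    else:
        raise ValueError(f"unknown class {cls!r}")
    return a


def simulate_cohort(
    freqs: ParentalFrequencies,
    design: dict[str, int],
    late_q_beta: tuple[float, float] = (1.5, 1.5),
    seed: int | None = None,
) -> tuple[HybridZoneTruth, np.ndarray]:
    """Simulate a cohort of known hybrid classes.

    Returns ``(truth, genotypes)`` where genotypes is an (N, L) array of
    alternate-allele counts in {0, 1, 2}. Each gene copy's ancestry is drawn
    according to the class pedigree; its allele is then Bernoulli with the
    matching parental frequency.
    """
    design = {k: v for k, v in design.items() if v}
    if not design:
        raise ValueError("design is empty: request at least one individual")
    unknown = set(design) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown classes in design: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    l = freqs.n_loci
    blocks, labels = [], []
    for cls in CLASSES:  # fixed order for reproducibility
        n = design.get(cls, 0)
        if n == 0:
            continue
        blocks.append(_copy_ancestries(cls, n, l, late_q_beta, rng))
        labels += [cls] * n
    copies = np.concatenate(blocks, axis=0)  # (N, L, 2) population labels
    n_total = copies.shape[0]
    # allele for each copy, conditional on its ancestry
    f = np.stack([freqs.f0, freqs.f1])  # (2, L)
    p_alt = f[copies, np.arange(l)[None, :, None]]  # (N, L, 2)
    alleles = (rng.random(copies.shape) < p_alt).astype(np.int8)
    genotypes = alleles.sum(axis=2)
    ancestry = copies.sum(axis=2)  # copies of population-1 ancestry
    classes = np.array(labels, dtype=object)
    individuals = np.array(
        [f"{cls}_{i:03d}" for i, cls in enumerate(classes)], dtype=object
    )
    truth = HybridZoneTruth(
        individuals=individuals,
        classes=classes,
        ancestry=ancestry,
        true_q=np.zeros(n_total),
        true_q12=np.zeros(n_total),
    )
    truth.true_q, truth.true_q12 = truth.recompute()
    return truth, genotypes


def simulate_reads(
    genotypes: np.ndarray,
    mean_depth: float = 7.0,
    error_rate: float = 0.01,
    seed: int | None = None,
    individuals: np.ndarray | None = None,
    contigs: np.ndarray | None = None,
) -> ReadCountMatrix:
    """Sequence simulated genotypes at Poisson depth with binomial error.

    ``n_reads ~ Poisson(mean_depth)``; each read reports the alternate allele
    with probability ``error_rate``, 0.5 or ``1 - error_rate`` for genotypes
    0, 1, 2. Zero reads encodes missing data.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    genotypes = np.asarray(genotypes)
    n, l = genotypes.shape
    n_reads = rng.poisson(mean_depth, size=(n, l))
    p_g = np.array([error_rate, 0.5, 1.0 - error_rate])
    n_alt = rng.binomial(n_reads, p_g[genotypes])
    if individuals is None:
        individuals = np.array([f"ind_{i:03d}" for i in range(n)], dtype=object)
    if contigs is None:
        contigs = np.array([f"contig_{j}" for j in range(l)], dtype=object)
    return ReadCountMatrix(
        individuals=individuals, contigs=contigs, n_reads=n_reads, n_alt=n_alt
    )


def genotype_likelihoods(reads: ReadCountMatrix, error_rate: float = 0.01) -> GLMatrix:
    """Binomial genotype likelihoods from read counts, normalized per cell.

    For genotype g with alternate-read probability p_g, the likelihood is
    Binomial(n_reads, p_g) at n_alt. Cells with zero reads get the uniform
    triple (1/3, 1/3, 1/3).
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    n_reads = reads.n_reads
    n_alt = reads.n_alt
    p_g = np.array([error_rate, 0.5, 1.0 - error_rate])
    # binomial pmf per genotype; constant C(n, k) cancels in normalization
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = n_alt[:, :, None] * np.log(p_g)[None, None, :] + (
            n_reads - n_alt
        )[:, :, None] * np.log(1.0 - p_g)[None, None, :]
    loglik = np.where(n_reads[:, :, None] == 0, 0.0, loglik)
    loglik -= loglik.max(axis=2, keepdims=True)
    gl = np.exp(loglik)
    gl /= gl.sum(axis=2, keepdims=True)
    loci = pd.DataFrame(
        {
            "locus_id": [f"snp_{j}" for j in range(n_reads.shape[1])],
            "contig": reads.contigs,
        }
    )
    return GLMatrix(
        individuals=reads.individuals, loci=loci, gl=gl, depth=n_reads
    )


def simulate_cline_genotypes(
    h: np.ndarray,
    freqs: ParentalFrequencies,
    alpha: np.ndarray | float = 0.0,
    beta: np.ndarray | float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate genotypes directly from the genomic-cline generative model.

    For individual i with hybrid index ``h[i]`` and locus l, each gene copy
    derives from population 1 with probability
    ``phi = clip(h + 2h(1-h)(alpha + beta(2h-1)), 0, 1)`` and carries the
    alternate allele with the matching parental frequency. With
    ``alpha = beta = 0`` this is neutral admixture (phi = h). Returns an
    (N, L) array of alternate-allele counts.
    """
    from .clines import cline_probability

    h = np.asarray(h, dtype=float)
    l = freqs.n_loci
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (l,))
    beta = np.broadcast_to(np.asarray(beta, dtype=float), (l,))
    rng = np.random.default_rng(seed)
    phi = cline_probability(h[:, None], alpha[None, :], beta[None, :])
    ancestry = (rng.random((len(h), l, 2)) < phi[:, :, None]).astype(np.int8)
    f = np.stack([freqs.f0, freqs.f1])
    p_alt = f[ancestry, np.arange(l)[None, :, None]]
    alleles = (rng.random(ancestry.shape) < p_alt).astype(np.int8)
    return alleles.sum(axis=2)


#: water-quality covariates measured at each sampling event
ENV_COVARIATES = (
    "specific_conductance",
    "pH",
    "temperature",
    "dissolved_oxygen",
    "depth",
    "current_velocity",
)

#: default slopes of each log-covariate on prairie-like ancestry, mirroring
#: the observed sign pattern (+conductance, +pH, -dissolved oxygen, -depth,
#: +velocity; temperature unassociated)
DEFAULT_ENV_SLOPES = {
    "specific_conductance": 1.0,
    "pH": 0.4,
    "temperature": 0.0,
    "dissolved_oxygen": -0.6,
    "depth": -0.8,
    "current_velocity": 0.6,
}

#: baseline (ancestry-zero) covariate levels on the natural scale:
#: ~1000 uS/cm, pH 8, 25 C, 8 mg/L DO, 0.6 m depth, 0.4 m/s velocity
DEFAULT_ENV_INTERCEPTS = {
    "specific_conductance": np.log(1000.0),
    "pH": np.log(8.0),
    "temperature": np.log(25.0),
    "dissolved_oxygen": np.log(8.0),
    "depth": np.log(0.6),
    "current_velocity": np.log(0.4),
}


def simulate_environment(
    ancestry: np.ndarray,
    slopes: dict[str, float] | None = None,
    noise_sd: float = 0.3,
    seed: int | None = None,
    intercepts: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Water-quality covariates linearly associated with ancestry on the log
    scale.

    Each log-covariate is ``intercept + slope * ancestry + Normal(0,
    noise_sd)`` and is exponentiated, so the returned table is strictly
    positive (log-transformable). A positive slope makes the covariate
    increase with the supplied ancestry vector (pass prairie-like ancestry to
    mirror the conductance association).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ancestry = np.asarray(ancestry, dtype=float)
    rng = np.random.default_rng(seed)
    slopes = dict(DEFAULT_ENV_SLOPES if slopes is None else slopes)
    intercepts = dict(DEFAULT_ENV_INTERCEPTS if intercepts is None else intercepts)
    table = {}
    for name in slopes:
        log_val = (
            intercepts.get(name, 0.0)
            + slopes[name] * ancestry
            + rng.normal(0.0, noise_sd, len(ancestry))
        )
        table[name] = np.exp(log_val)
    return pd.DataFrame(table)
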