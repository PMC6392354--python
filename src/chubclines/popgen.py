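"""Population-genetic summaries from genotype likelihoods.

Allele frequencies are estimated by an EM algorithm that treats the true
genotype as latent with a Hardy-Weinberg prior, so shallow-coverage data
contribute proportionally to their information content. Diversity (pi),
pairwise Nei's GST and a genotype-covariance PCA are built on top of those
frequency and posterior-genotype estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import GLMatrix

__all__ = [
    "em_allele_frequency",
    "em_allele_frequencies",
    "em_loglik",
    "allele_frequency_table",
    "nucleotide_diversity",
    "pairwise_gst",
    "GenotypePCA",
    "genotype_pca",
]


def _hwe(p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities, shape (..., 3)."""
    p = np.asarray(p, dtype=float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)


def em_allele_frequencies(gl: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """EM estimate of the alternate-allele frequency at every locus.

    Parameters
    ----------
    gl : ndarray, shape (N, L, 3)
        Normalized genotype-likelihood triples.
    n_iter : int
        Number of EM iterations (run exactly; default 20).

    Starting from p = 0.5, each iteration computes genotype posteriors
    ``w_g ∝ L_g * HWE(g; p)`` and updates ``p = mean dosage / 2``. Loci where
    every individual is missing (uniform triples) stay at 0.5 and trigger a
    warning.
    """
    gl = np.asarray(gl, dtype=float)
    if gl.ndim == 2:  # single locus convenience
        gl = gl[:, None, :]
    n, l = gl.shape[:2]
    if n < 1:
        raise ValueError("need at least one individual")
    informative = ~np.all(np.abs(gl - 1.0 / 3.0) < 1e-9, axis=2)  # (N, L)
    all_missing = ~informative.any(axis=0)
    if np.any(all_missing):
        warnings.warn(
            f"{int(all_missing.sum())} locus/loci have no data; frequency "
            "reported as 0.5",
            stacklevel=2,
        )
    p = np.full(l, 0.5)
    dosage = np.array([0.0, 1.0, 2.0])
    for _ in range(n_iter):
        w = gl * _hwe(p)[None, :, :]
        w /= w.sum(axis=2, keepdims=True)
        p = (w @ dosage).sum(axis=0) / (2.0 * n)
    return p


def em_allele_frequency(gl_locus: np.ndarray, n_iter: int = 20) -> float:
    """EM allele frequency for a single locus, ``gl_locus`` shape (N, 3)."""
    return float(em_allele_frequencies(np.asarray(gl_locus)[:, None, :], n_iter)[0])


def em_loglik(gl: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Observed-data log-likelihood per locus at frequency p.

    ``sum_i log sum_g L_ig HWE(g; p)`` — the objective the EM iterations are
    guaranteed not to decrease.
    """
    gl = np.asarray(gl, dtype=float)
    if gl.ndim == 2:
        gl = gl[:, None, :]
    mix = (gl * _hwe(np.atleast_1d(p))[None, :, :]).sum(axis=2)
    return np.log(np.maximum(mix, 1e-300)).sum(axis=0)


def allele_frequency_table(
    gl: GLMatrix, populations: dict[str, list], n_iter: int = 20
) -> pd.DataFrame:
    """Per-population EM allele frequencies (populations x loci)."""
    rows = {}
    for pop, ids in populations.items():
        sub = gl.select_individuals(ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows[pop] = em_allele_frequencies(sub.gl, n_iter=n_iter)
    return pd.DataFrame(rows, index=gl.locus_ids).T


def nucleotide_diversity(
    gl: GLMatrix, populations: dict[str, list], n_iter: int = 20
) -> pd.Series:
    """Mean per-SNP diversity pi for each population.

    Per locus ``pi_l = 2 p (1-p) * 2n / (2n - 1)`` with p the EM frequency
    and n the number of individuals with data; the population value is the
    mean over loci with data. Computed over the retained SNPs only, so it is
    a per-SNP diversity, not a per-base estimate.
    """
    out = {}
    for pop, ids in populations.items():
        sub = gl.select_individuals(ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = em_allele_frequencies(sub.gl, n_iter=n_iter)
        n = sub.covered().sum(axis=0)
        ok = n > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            pi_l = 2.0 * p * (1.0 - p) * (2.0 * n) / (2.0 * n - 1.0)
        out[pop] = float(pi_l[ok].mean()) if ok.any() else np.nan
    return pd.Series(out, name="pi")


def pairwise_gst(freqs: pd.DataFrame) -> pd.DataFrame:
    """Pairwise multilocus Nei's GST from a populations x loci frequency table.

    For each pair and locus: HS is the mean within-population expected
    heterozygosity ``2p(1-p)``, HT uses the unweighted mean frequency. The
    pair's GST is the ratio of sums over loci ``(ΣHT - ΣHS) / ΣHT``. A pair
    monomorphic everywhere has undefined GST and is reported as NaN.
    """
    pops = list(freqs.index)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    f = freqs.to_numpy(dtype=float)
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            hs = 0.5 * (2 * f[i] * (1 - f[i]) + 2 * f[j] * (1 - f[j]))
            pbar = 0.5 * (f[i] + f[j])
            ht = 2 * pbar * (1 - pbar)
            denom = ht.sum()
            out[i, j] = out[j, i] = (
                (ht.sum() - hs.sum()) / denom if denom > 0 else np.nan
            )
    return pd.DataFrame(out, index=pops, columns=pops)


class GenotypePCA(BaseEstimator):
    """PCA of the genetic covariance among individuals.

    The mean posterior genotype ``g = L1 + 2 L2`` is computed per cell,
    columns (loci) are mean-centered, and the individual-by-individual
    covariance matrix is eigendecomposed. Scores are the projections onto the
    principal axes; ``explained_variance_ratio_`` is eigenvalue / trace.

    Parameters
    ----------
    n_components : int or None
        Number of components to keep (default: min(N, L)).
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, gl: GLMatrix, y=None) -> "GenotypePCA":
        self.fit_transform(gl)
        return self

    def fit_transform(self, gl: GLMatrix, y=None) -> np.ndarray:
        x = gl.mean_genotype()
        xc = x - x.mean(axis=0, keepdims=True)
        if np.allclose(xc, 0.0):
            raise ValueError(
                "genotype matrix is constant: covariance has zero variance, "
                "variance proportions are undefined"
            )
        n, l = xc.shape
        gram = xc @ xc.T / (l - 1 if l > 1 else 1)
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        n_comp = self.n_components or min(n, l)
        n_comp = min(n_comp, len(evals))
        scores = evecs * np.sqrt(np.maximum(evals, 0.0) * (l - 1 if l > 1 else 1))
        self.explained_variance_ = evals[:n_comp]
        self.explained_variance_ratio_ = evals[:n_comp] / evals.sum()
        self.scores_ = scores[:, :n_comp]
        self.individuals_ = gl.individuals
        return self.scores_

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores_[:, i] for i in range(self.scores_.shape[1])}
        frame = pd.DataFrame({"individual": self.individuals_, **cols})
        return frame


def genotype_pca(gl: GLMatrix, n_components: int | None = None) -> GenotypePCA:
    """Fit a :class:`GenotypePCA` and return the fitted estimator."""
    return GenotypePCA(n_components=n_components).fit(gl)
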