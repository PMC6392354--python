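"""Bayesian admixture and ancestry-class estimation from genotype likelihoods.

Two hierarchical models, both driven by Gibbs sampling over latent genotypes
so that uncalled, shallow-coverage data are handled through their likelihood
triples rather than hard genotype calls:

* :class:`AdmixtureModel` — k-cluster admixture. Each gene copy carries a
  latent cluster label; cluster allele frequencies get Beta(1, 1) priors and
  per-individual admixture proportions q get flat Dirichlet priors. Multiple
  chains are label-aligned and pooled; convergence is monitored with the
  Gelman-Rubin potential scale reduction factor.

* :class:`AncestryClassModel` — the two-source ancestry-class model. Each
  locus of a target individual is in one of three diploid ancestry states
  (both copies from population 0, one from each, both from population 1)
  with individual-level Dirichlet(1, 1, 1) prior on the state proportions.
  The interpopulation proportion Q12 together with genome-average ancestry
  q = Q_pop1 + Q12/2 separates F1s (q ~ 0.5, Q12 ~ 1) from F2s, backcrosses
  and late-generation hybrids.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import GLMatrix
from .popgen import em_allele_frequencies

__all__ = [
    "AdmixtureModel",
    "AncestryClassModel",
    "fit_admixture",
    "fit_ancestry_classes",
    "max_interpop_ancestry",
    "gelman_rubin",
    "effective_sample_size",
]


def max_interpop_ancestry(q):
    """Maximum possible interpopulation ancestry at genome-average ancestry q.

    An individual with ancestry proportion q can have at most ``2 min(q,
    1 - q)`` of its loci in the heterospecific (one copy from each source)
    state; F1s sit at the apex (0.5, 1.0) of this triangular envelope.
    """
    arr = np.asarray(q, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("q must lie in [0, 1]")
    out = 2.0 * np.minimum(arr, 1.0 - arr)
    return float(out) if np.isscalar(q) else out


def gelman_rubin(chains) -> np.ndarray | float:
    """Potential scale reduction factor from >= 2 equal-length chains.

    ``chains`` has shape (n_chains, n_draws) or (n_chains, n_draws, ...).
    Returns ``sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain
    variance and B/n the variance of chain means. Identical chains give
    ``sqrt((n-1)/n)`` (slightly below 1); disjoint chains give values far
    above 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim < 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of draws")
    n = chains.shape[1]
    if n < 10:
        raise ValueError("need chains of length >= 10")
    w = chains.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = chains.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        psrf = np.sqrt(var_plus / w)
    psrf = np.where(w == 0, np.where(b_over_n == 0, 1.0, np.inf), psrf)
    return float(psrf) if psrf.ndim == 0 else psrf


def effective_sample_size(draws) -> float:
    """Autocorrelation-based ESS of a single pooled draw sequence.

    Uses the initial-positive-sequence truncation: n / (1 + 2 sum rho_t) with
    the sum stopped at the first non-positive autocorrelation.
    """
    x = np.asarray(draws, dtype=float)
    n = len(x)
    x = x - x.mean()
    var = x.var()
    if var == 0 or n < 4:
        return float(n)
    acf_sum = 0.0
    for lag in range(1, n // 2):
        rho = np.dot(x[:-lag], x[lag:]) / ((n - lag) * var)
        if rho <= 0:
            break
        acf_sum += rho
    return float(n / (1.0 + 2.0 * acf_sum))


# ---------------------------------------------------------------------------
# k-cluster admixture


class AdmixtureModel(BaseEstimator):
    """k-cluster Bayesian admixture from genotype likelihoods.

    Gibbs sampler over latent genotypes, per-gene-copy cluster labels,
    cluster allele frequencies f (Beta(1,1) prior) and individual admixture
    proportions q (flat Dirichlet prior). For each cell the pair of gene
    copies is sampled jointly: the weight of assigning copies to clusters
    (z1, z2) carrying alleles (a1, a2) is
    ``GL(a1 + a2) * q[z1] q[z2] * f-term(z1, a1) * f-term(z2, a2)``.

    Parameters
    ----------
    k : int
        Number of clusters.
    n_iter, burn_in, thin : int
        Iterations per chain, discarded prefix, and thinning stride. Defaults
        are desk-scale; field-scale settings (100,000 iterations thinned by
        10 after 5,000 burn-in) are accepted.
    n_chains : int
        Independent chains; label switching between chains is resolved by
        permutation matching of posterior mean frequencies before pooling.
    random_state : int or None
        Seed for all chains (chains use independent spawned streams).

    Attributes
    ----------
    q_mean_, q_median_ : ndarray (N, k)
    q_ci_ : ndarray (2, N, k) equal-tailed 95% bounds
    freq_mean_ : ndarray (k, L)
    q_draws_ : ndarray (total_draws, N, k) pooled aligned draws
    gelman_rubin_ : ndarray (N, k) PSRF of each q parameter
    ess_ : ndarray (N, k) effective sample sizes of pooled q draws
    """

    def __init__(
        self,
        k: int = 2,
        n_iter: int = 5000,
        burn_in: int = 500,
        thin: int = 5,
        n_chains: int = 2,
        random_state: int | None = None,
    ):
        self.k = k
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.random_state = random_state

    def fit(self, gl: GLMatrix, y=None, anchor_freqs=None) -> "AdmixtureModel":
        """Fit on a GLMatrix.

        ``anchor_freqs`` (length L, optional) anchors cluster labels: after
        chain alignment the cluster whose mean frequencies best agree with
        the anchor (e.g. EM frequencies of a parental-1 reference panel) is
        placed at column index 1, fixing the direction of q.
        """
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_chains)
        chain_q, chain_f = [], []
        for ss in seeds:
            qd, fd = self._run_chain(gl, np.random.default_rng(ss))
            chain_q.append(qd)
            chain_f.append(fd)
        chain_q, chain_f = self._align_chains(chain_q, chain_f)
        if anchor_freqs is not None:
            chain_q, chain_f = self._anchor(chain_q, chain_f, anchor_freqs)
        stacked_q = np.stack(chain_q)  # (chains, draws, N, k)
        self.gelman_rubin_ = gelman_rubin(stacked_q)
        pooled_q = np.concatenate(chain_q, axis=0)
        pooled_f = np.concatenate(chain_f, axis=0)
        self.q_draws_ = pooled_q
        self.q_mean_ = pooled_q.mean(axis=0)
        self.q_median_ = np.median(pooled_q, axis=0)
        self.q_ci_ = np.quantile(pooled_q, [0.025, 0.975], axis=0)
        self.freq_mean_ = pooled_f.mean(axis=0)
        n, k = self.q_mean_.shape
        self.ess_ = np.array(
            [
                [effective_sample_size(pooled_q[:, i, c]) for c in range(k)]
                for i in range(n)
            ]
        )
        self.individuals_ = gl.individuals
        max_gr = float(np.nanmax(self.gelman_rubin_))
        if max_gr > 1.1:
            warnings.warn(
                f"possible non-convergence: max Gelman-Rubin PSRF {max_gr:.3f}"
                " exceeds 1.1; inspect gelman_rubin_ and increase n_iter",
                stacklevel=2,
            )
        return self

    # -- internals --------------------------------------------------------
    def _run_chain(self, gl: GLMatrix, rng):
        k = self.k
        glm = gl.gl  # (N, L, 3)
        n, l = glm.shape[:2]
        m = 2 * k  # per-copy states: (cluster, allele)
        # allele and cluster of each per-copy state
        a_of = np.arange(m) % 2
        z_of = np.arange(m) // 2
        geno_of_pair = a_of[:, None] + a_of[None, :]  # (m, m) in {0,1,2}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p0 = em_allele_frequencies(glm)
        f = np.clip(p0[None, :] + rng.normal(0, 0.05, (k, l)), 0.01, 0.99)
        q = rng.dirichlet(np.ones(k), size=n)
        l_idx = np.broadcast_to(np.arange(l), (n, l))
        keep = (np.arange(self.n_iter) >= self.burn_in) & (
            (np.arange(self.n_iter) - self.burn_in) % self.thin == 0
        )
        q_draws = np.empty((int(keep.sum()), n, k))
        f_draws = np.empty((int(keep.sum()), k, l))
        out = 0
        gl_pair = glm[:, :, geno_of_pair]  # (N, L, m, m)
        for it in range(self.n_iter):
            # per-copy weight u[i,l,t] = q[i,z] * (f[z,l] if a else 1-f[z,l])
            f_term = np.where(a_of[None, :] == 1, f.T[:, z_of], (1 - f).T[:, z_of])
            u = q[:, None, z_of] * f_term[None, :, :]  # (N, L, m)
            w = gl_pair * u[:, :, :, None] * u[:, :, None, :]
            w = w.reshape(n, l, m * m)
            cs = np.cumsum(w, axis=2)
            r = rng.random((n, l, 1)) * cs[:, :, -1:]
            pair = (cs < r).sum(axis=2)
            t1, t2 = pair // m, pair % m
            z1, a1 = z_of[t1], a_of[t1]
            z2, a2 = z_of[t2], a_of[t2]
            # cluster-locus allele counts -> Beta update of f
            flat1 = (z1 * l + l_idx).ravel()
            flat2 = (z2 * l + l_idx).ravel()
            alt = np.bincount(flat1, weights=a1.ravel(), minlength=k * l)
            alt += np.bincount(flat2, weights=a2.ravel(), minlength=k * l)
            tot = np.bincount(flat1, minlength=k * l).astype(float)
            tot += np.bincount(flat2, minlength=k * l)
            alt = alt.reshape(k, l)
            ref = tot.reshape(k, l) - alt
            f = rng.beta(1.0 + alt, 1.0 + ref)
            # individual-cluster copy counts -> Dirichlet update of q
            i_idx = np.broadcast_to(np.arange(n)[:, None], (n, l))
            cz = np.bincount((i_idx * k + z1).ravel(), minlength=n * k)
            cz = cz + np.bincount((i_idx * k + z2).ravel(), minlength=n * k)
            gam = rng.standard_gamma(1.0 + cz.reshape(n, k))
            q = gam / gam.sum(axis=1, keepdims=True)
            if keep[it]:
                q_draws[out] = q
                f_draws[out] = f
                out += 1
        return q_draws, f_draws

    def _align_chains(self, chain_q, chain_f):
        """Resolve between-chain label switching by permutation matching."""
        from itertools import permutations

        ref = chain_f[0].mean(axis=0)  # (k, L)
        for c in range(1, len(chain_f)):
            mean_f = chain_f[c].mean(axis=0)
            best, best_d = None, np.inf
            for perm in permutations(range(self.k)):
                d = float(((mean_f[list(perm)] - ref) ** 2).sum())
                if d < best_d:
                    best, best_d = list(perm), d
            chain_f[c] = chain_f[c][:, best, :]
            chain_q[c] = chain_q[c][:, :, best]
        return chain_q, chain_f

    def _anchor(self, chain_q, chain_f, anchor_freqs):
        anchor = np.asarray(anchor_freqs, dtype=float)
        mean_f = np.concatenate(chain_f, axis=0).mean(axis=0)
        dist = ((mean_f - anchor[None, :]) ** 2).sum(axis=1)
        target = int(np.argmin(dist))
        order = [c for c in range(self.k) if c != target]
        order.insert(min(1, self.k - 1), target)
        chain_f = [fd[:, order, :] for fd in chain_f]
        chain_q = [qd[:, :, order] for qd in chain_q]
        return chain_q, chain_f

    def summary(self) -> pd.DataFrame:
        """Per-individual q summaries (mean, median, 95% CI per cluster)."""
        rows = []
        n, k = self.q_mean_.shape
        for i in range(n):
            row = {"individual": self.individuals_[i]}
            for c in range(k):
                row[f"q{c}_mean"] = self.q_mean_[i, c]
                row[f"q{c}_median"] = self.q_median_[i, c]
                row[f"q{c}_lo"] = self.q_ci_[0, i, c]
                row[f"q{c}_hi"] = self.q_ci_[1, i, c]
                row[f"q{c}_psrf"] = self.gelman_rubin_[i, c]
                row[f"q{c}_ess"] = self.ess_[i, c]
            rows.append(row)
        return pd.DataFrame(rows)


def fit_admixture(
    gl: GLMatrix,
    k: int = 2,
    n_iter: int = 5000,
    thin: int = 5,
    burn_in: int = 500,
    n_chains: int = 2,
    seed: int | None = None,
    anchor_freqs=None,
) -> AdmixtureModel:
    """Functional wrapper around :class:`AdmixtureModel`."""
    model = AdmixtureModel(
        k=k,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        n_chains=n_chains,
        random_state=seed,
    )
    return model.fit(gl, anchor_freqs=anchor_freqs)


# ---------------------------------------------------------------------------
# two-source ancestry classes


def _state_emission(glm: np.ndarray, f0: np.ndarray, f1: np.ndarray) -> np.ndarray:
    """P(data | diploid ancestry state) per cell, shape (N, L, 3).

    State s counts gene copies from population 1: s=0 both copies population
    0, s=1 one from each, s=2 both from population 1. Genotype probabilities
    mix the parental allele frequencies accordingly.
    """
    p_g = np.empty((3, len(f0), 3))  # (state, L, genotype)
    p_g[0] = np.stack([(1 - f0) ** 2, 2 * f0 * (1 - f0), f0**2], axis=1)
    p_g[2] = np.stack([(1 - f1) ** 2, 2 * f1 * (1 - f1), f1**2], axis=1)
    p_g[1] = np.stack(
        [(1 - f0) * (1 - f1), f0 * (1 - f1) + f1 * (1 - f0), f0 * f1], axis=1
    )
    # E[i,l,s] = sum_g GL[i,l,g] * p_g[s,l,g]
    return np.einsum("nlg,slg->nls", glm, p_g)


class AncestryClassModel(BaseEstimator):
    """Two-source diploid ancestry-class model (q and Q12 per individual).

    Parental allele frequencies are point estimates (EM on the two reference
    panels). Per individual the three state proportions (Q_pop0, Q12,
    Q_pop1) get a Dirichlet(1, 1, 1) prior; Gibbs sampling alternates
    per-locus state draws with Dirichlet updates of the proportions.

    Parameters mirror :class:`AdmixtureModel`; field-scale settings (15,000
    iterations thinned by 5 after 5,000 burn-in) are accepted via the same
    knobs.
    """

    def __init__(
        self,
        n_iter: int = 5000,
        burn_in: int = 500,
        thin: int = 5,
        n_chains: int = 2,
        random_state: int | None = None,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.random_state = random_state

    def fit(
        self,
        gl: GLMatrix,
        parental0_ids,
        parental1_ids,
        hybrid_ids=None,
        parental_freqs: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> "AncestryClassModel":
        """Estimate ancestry classes for the target individuals.

        ``parental0_ids`` / ``parental1_ids`` define the two source-species
        reference panels (or pass ``parental_freqs=(f0, f1)`` directly).
        ``hybrid_ids`` restricts the targets; by default every individual in
        ``gl`` is classified. Explicit targets may not overlap the panels.
        """
        p0 = list(parental0_ids) if parental0_ids is not None else []
        p1 = list(parental1_ids) if parental1_ids is not None else []
        if set(p0) & set(p1):
            raise ValueError("parental panels overlap")
        if parental_freqs is None:
            if not p0 or not p1:
                raise ValueError(
                    "both parental panels must be non-empty (or supply "
                    "parental_freqs)"
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f0 = em_allele_frequencies(gl.select_individuals(p0).gl)
                f1 = em_allele_frequencies(gl.select_individuals(p1).gl)
        else:
            f0, f1 = (np.asarray(f, dtype=float) for f in parental_freqs)
        if hybrid_ids is not None:
            overlap = set(hybrid_ids) & (set(p0) | set(p1))
            if overlap:
                raise ValueError(
                    f"hybrid set overlaps parental panels: {sorted(overlap)}"
                )
            target = gl.select_individuals(list(hybrid_ids))
        else:
            target = gl
        emission = _state_emission(target.gl, f0, f1)
        n, l = emission.shape[:2]
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_chains)
        chains = [
            self._run_chain(emission, np.random.default_rng(ss)) for ss in seeds
        ]
        stacked = np.stack(chains)  # (chains, draws, N, 3)
        self.gelman_rubin_ = gelman_rubin(stacked)
        pooled = np.concatenate(chains, axis=0)
        self.Q_draws_ = pooled
        self.Q_mean_ = pooled.mean(axis=0)
        self.Q_ci_ = np.quantile(pooled, [0.025, 0.975], axis=0)
        q_draws = pooled[:, :, 2] + 0.5 * pooled[:, :, 1]
        self.q_draws_ = q_draws
        self.q_mean_ = q_draws.mean(axis=0)
        self.q12_draws_ = pooled[:, :, 1]
        self.q12_mean_ = pooled[:, :, 1].mean(axis=0)
        self.q12_ci_ = np.quantile(pooled[:, :, 1], [0.025, 0.975], axis=0)
        self.individuals_ = target.individuals
        self.parental_freqs_ = (f0, f1)
        max_gr = float(np.nanmax(self.gelman_rubin_))
        if max_gr > 1.1:
            warnings.warn(
                f"possible non-convergence: max Gelman-Rubin PSRF {max_gr:.3f}"
                " exceeds 1.1",
                stacklevel=2,
            )
        return self

    def _run_chain(self, emission: np.ndarray, rng) -> np.ndarray:
        n, l = emission.shape[:2]
        big_q = np.full((n, 3), 1.0 / 3.0)
        keep = (np.arange(self.n_iter) >= self.burn_in) & (
            (np.arange(self.n_iter) - self.burn_in) % self.thin == 0
        )
        draws = np.empty((int(keep.sum()), n, 3))
        out = 0
        for it in range(self.n_iter):
            w = emission * big_q[:, None, :]
            cs = np.cumsum(w, axis=2)
            r = rng.random((n, l, 1)) * cs[:, :, -1:]
            s = (cs < r).sum(axis=2)  # (N, L) in {0,1,2}
            counts = np.stack([(s == v).sum(axis=1) for v in range(3)], axis=1)
            gam = rng.standard_gamma(1.0 + counts)
            big_q = gam / gam.sum(axis=1, keepdims=True)
            if keep[it]:
                draws[out] = big_q
                out += 1
        return draws

    def summary(self) -> pd.DataFrame:
        """Per-individual posterior means and 95% CIs of (q, Q12)."""
        return pd.DataFrame(
            {
                "individual": self.individuals_,
                "q_mean": self.q_mean_,
                "q12_mean": self.q12_mean_,
                "q12_lo": self.q12_ci_[0],
                "q12_hi": self.q12_ci_[1],
                "Q_pop0_mean": self.Q_mean_[:, 0],
                "Q_pop1_mean": self.Q_mean_[:, 2],
                "q12_max_possible": max_interpop_ancestry(
                    np.clip(self.q_mean_, 0.0, 1.0)
                ),
            }
        )


def fit_ancestry_classes(
    gl: GLMatrix,
    parental0_ids,
    parental1_ids,
    n_iter: int = 5000,
    thin: int = 5,
    burn_in: int = 500,
    seed: int | None = None,
    n_chains: int = 2,
    hybrid_ids=None,
) -> AncestryClassModel:
    """Functional wrapper around :class:`AncestryClassModel`."""
    model = AncestryClassModel(
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        n_chains=n_chains,
        random_state=seed,
    )
    return model.fit(gl, parental0_ids, parental1_ids, hybrid_ids=hybrid_ids)
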