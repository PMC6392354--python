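# Methods

This note documents the models, the numerical choices behind them, what the
synthetic-data generator does and does not emulate, and the design
decisions made where the design was genuinely open.

## Data model

The pipeline currency is the normalized genotype-likelihood triple
`(L0, L1, L2)` per individual × biallelic SNP: the probability of the
observed reads under 0, 1 or 2 copies of the alternate allele, normalized
to sum to one (the binomial coefficient cancels). A cell with zero reads is
the uninformative triple (1/3, 1/3, 1/3). VCF input accepts GL (log10) and
PL (phred integer); GL is preferred when both are present because integer
PL cannot represent likelihood ratios to better than half a phred, which
would break write→read round-trip fidelity. Population 1 is fixed by
convention as the shoal-like (widespread) gene pool; all ancestry
proportions (q, Q12, h) point toward it.

## Synthetic hybrid zone

`simulate_parental_frequencies` draws a fraction `prop_fixed` of loci as
near-fixed differences (f0 ≤ 0.001, f1 ≥ 0.999) and the rest from Beta
distributions with means (1 ∓ divergence)/2 and concentration 8 — broad,
unimodal frequency spectra whose expected divergence grows with the
parameter. `simulate_cohort` draws per-locus, per-gene-copy ancestry
according to the class pedigree (P0/P1 at Hardy–Weinberg; F1 one copy per
pool; F2 copies 50/50 independently; BC one F1-gamete copy plus one
recurrent-parent copy; LATE a per-individual admixture level
q\* ~ Beta(a, b), default (1.5, 1.5), with copies Bernoulli(q\*) per
locus), then draws each copy's allele from the matching parental
frequency. Reads are Poisson with mean depth 7 by default, mirroring the
shallow-GBS regime the models are designed for (the study reports only a
mean and SD of per-locus coverage, so Poisson is the natural one-parameter
choice); alternate-read probabilities are (e, 0.5, 1 − e) for genotypes
0/1/2 with sequencing error e = 0.01 by default.

Deliberate non-features: loci are unlinked (the inference models are also
linkage-free), error is symmetric and site-independent (no
platform-specific error profiles), sites are biallelic SNPs only, and
environmental covariates are generated at the individual level. Passing
recovery tests on these simulations therefore demonstrates correctness of
the estimators under their own assumptions — not robustness to linkage,
batch effects, or reference bias in real GBS data.

Environmental covariates are log-linear in ancestry:
`log x = intercept + slope · a + N(0, noise_sd)`, exponentiated so the
table is strictly positive. Default slopes (on prairie-like ancestry)
follow the observed sign pattern — conductance +1.0, pH +0.4, dissolved
oxygen −0.6, depth −0.8, velocity +0.6, temperature 0 — with magnitudes
chosen once so the weakest association is detectable at n ≈ 300 and unit
log-scale noise; baselines are typical prairie-river values (≈1000 µS/cm,
pH 8, 25 °C, 8 mg/L, 0.6 m, 0.4 m/s).

## Filters

Individuals with mean depth < 2 are removed first (strict inequality; an
individual exactly at 2 is kept). Locus rules then run in a fixed order:
call-rate (≥ 50% of retained individuals with ≥ 1 read — inclusive
boundary), minor allele frequency (EM estimate on the full retained
sample; strictly below 0.05 excluded), then one uniformly chosen SNP per
contig under the given seed. MAF is computed after individual filtering —
frequencies should come from the sample actually analysed. Without a depth
channel, "covered" falls back to "triple is non-uniform".

## EM allele frequencies

Starting from p = 0.5, each of exactly 20 iterations computes genotype
posteriors `w_g ∝ L_g · HWE(g; p)` and sets p to half the mean posterior
dosage. Missing cells contribute their prior expectation and leave the
fixed point unchanged. The observed-data log-likelihood is non-decreasing
across iterations (standard EM guarantee; asserted in tests). An
all-missing locus stays at 0.5 and triggers a warning rather than an
error, so whole-matrix sweeps do not abort.

## Admixture model

The Gibbs sampler augments each individual × locus cell with the pair of
gene copies' (cluster, allele) states, sampled jointly from the 4k²
combinations with weight `GL(a1+a2) · q_i[z1] q_i[z2] · f-term(z1,a1) ·
f-term(z2,a2)`; cluster frequencies then update from Beta(1 + alt,
1 + ref) and admixture proportions from Dirichlet(1 + copy counts). Flat
priors (Beta(1,1), Dirichlet(1,…,1)) are used instead of a hierarchical
frequency model: no prior parameters were available to match, and flat
priors make the desk-scale behaviour transparent. Label switching between
chains is resolved by best-permutation matching of posterior mean
frequency vectors against the first chain (k ≤ 4, so exhaustive search is
cheap); an optional anchor frequency vector (e.g. EM frequencies of a
designated parental-1 panel) then fixes which cluster is population 1, so
q columns have a stable direction. Convergence is summarized by the
Gelman–Rubin PSRF per q parameter (warning above 1.1) and
initial-positive-sequence effective sample sizes. Default desk-scale
settings (5,000 iterations, 500 burn-in, thin 5, 2 chains) are
configurable up to field-scale runs (100,000/10/5,000).

## Ancestry-class model

Parental allele frequencies are EM point estimates from the two reference
panels (a documented simplification — jointly sampling them would add
little at the panel sizes simulated here, and the option to pass
frequencies directly exists). Each target individual's loci get diploid
ancestry states with emission probabilities mixing f0/f1 per state, a
Dirichlet(1,1,1) prior on the state proportions, and a two-block Gibbs
sweep. Every posterior draw satisfies the simplex constraint and the
envelope Q12 ≤ 2 min(q, 1 − q) by construction.

## Genomic clines

The copy-level ancestry probability is the quadratic cline
`phi = h + 2h(1−h)(α + β(2h−1))` truncated to [0, 1]; the genotype at a
locus is Binomial(2, π) with π = φ f1 + (1 − φ) f0, mixed over the
likelihood triple. Sampling is Metropolis-within-Gibbs with per-parameter
random-walk proposals adapted during burn-in toward 20–40% acceptance
(windows of 50 iterations, ×1.25 / ×0.8 scale steps), h proposals
reflected into [0, 1], and chains initialized at a least-squares moment
estimate of h.

Two numerical choices matter here. First, the prior scales σ_α, σ_β are by
default *sampled* (conjugate inverse-gamma with an InvGamma(2, 1)
hyperprior, σ clipped to [0.25, 3]) rather than fixed: with fixed wide
priors the joint posterior has a near-flat ridge — every h shifted up
while every α shifts down leaves the cline probabilities almost unchanged
— and at desk scale the 2L free locus parameters can buy enough likelihood
along that ridge to beat the prior, biasing h and mass-flagging loci. The
hierarchical variance restores collective shrinkage: under neutral data σ
collapses to its floor and pins α near zero; when a subset of loci carries
real effects σ adapts upward. The floor prevents the opposite failure
(total collapse vetoing genuinely exceptional loci). Second, a coordinated
"shear" Metropolis move proposes (h + δ, α − 2δ) for all parameters at
once, letting chains traverse the ridge instead of drifting along it
one-directionally; with it, two chains agree (PSRF ≈ 1.01) where they
previously diverged (PSRF > 5). Measured behaviour at 30–50 hybrids × 300
loci, depth 8: null flag rate ≈ 2% (nominal ≤ 5%), power ≈ 100% for α = 1
effects with no sign inversions, hybrid-index recovery r ≈ 0.995.

Exceptional loci are flagged from the 95% equal-tailed credible interval
(excludes zero; sign by interval side), not by an outlier-quantile rule —
the interval criterion is the one the package's concordance test is
calibrated against. Two zones are fitted independently; their
exceptional-α sets are compared with the exact hypergeometric upper tail
computed by log-sum-exp of `hypergeom.logpmf`, which stays accurate at
genome scale (e.g. p ≈ 7.5 × 10⁻²³ for 35 shared of 40 and 6,393 among
39,122 SNPs) where naive summation underflows. m = 0 returns exactly 1.

## Environment association

Stepwise selection starts from the full model and applies the best
strictly-AIC-improving single-term addition or deletion until none
remains; ties break toward the smaller model, then alphabetically, making
the procedure deterministic and column-order invariant. Covariates are
log-transformed; the response (an assignment probability in [0, 1]) is
left untransformed — the bounded response makes a log of the response
unnatural, and the association structure of interest is monotone either
way. LMG shares are computed by the subset-weighted identity over all 2^p
covariate subsets (equivalent to averaging R² increments over all p!
orderings; p ≤ 12 enforced), normalized to percent of the full-model R²,
with percentile bootstrap intervals (default 1,000 resamples; 10,000
accepted via configuration).

## Pipeline

Stages communicate through files (VCF/CSV/JSON) so any stage can be rerun
in isolation or replaced by an external tool. Every stochastic stage
derives its seed deterministically from the single config seed and the
manifest records outputs with SHA-256 checksums; identical configs
reproduce identical bytes. The cline stage includes only non-panel
individuals whose posterior mean Q12 exceeds 0.05 (configurable), the
second zone reuses the first zone's parental frequencies, and π is
reported per retained SNP — not per base — so its absolute scale is not
comparable to sequence-level diversity estimates that include invariant
sites.

## Problem sizes

Tests and the acceptance script run the MCMC models at desk scale —
hundreds of loci, tens of individuals, a few thousand iterations — sizes
chosen so the whole suite completes in minutes while leaving the
acceptance checks (calibration, power, recovery correlations) with
comfortable margins. All iteration counts are parameters; field-scale
settings are accepted unchanged.

## Known limitations

* No linkage: neither simulator nor models account for LD between SNPs.
* Parental frequencies enter the ancestry-class and cline models as point
  estimates; very small or shallow parental panels would understate
  uncertainty.
* π is per-SNP, conditioned on the retained polymorphic loci.
* The admixture model's flat frequency priors are not the hierarchical
  F-model of dedicated software; at k > 2 on weakly structured data the
  flat prior mixes more slowly.
* The cline model's hierarchical σ uses a single shared scale per
  parameter class, not per-locus local shrinkage.
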