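"""Locus and individual filters for genotype-likelihood matrices.

Individuals with shallow mean coverage (< 2 reads per locus by default) are
dropped first; loci are then filtered in a fixed order: call-rate (at least
half the retained individuals with a read), minor allele frequency (EM
estimate, strict < 0.05 excluded), and finally one randomly chosen SNP per
contig. The order is deliberate: allele frequencies are estimated from the
genotype likelihoods of the sample that survives the earlier rules.
"""

from __future__ import annotations

import numpy as np

from .core import FilterReport, GLMatrix
from .popgen import em_allele_frequencies

__all__ = ["filter_individuals", "filter_loci", "LOCUS_RULE_ORDER"]

#: fixed order in which the three locus rules are applied
LOCUS_RULE_ORDER = ("call_rate", "maf", "one_per_contig")


def filter_individuals(
    gl: GLMatrix, min_mean_depth: float = 2.0
) -> tuple[GLMatrix, FilterReport]:
    """Remove individuals whose mean per-locus depth is below the threshold.

    The comparison is strict (< min_mean_depth removed), so an individual at
    exactly the threshold is retained.
    """
    if gl.depth is None:
        raise ValueError(
            "GLMatrix has no depth channel; the mean-depth filter cannot be "
            "applied. Skip this filter explicitly if depths are unavailable."
        )
    mean_depth = gl.depth.mean(axis=1)
    keep = mean_depth >= min_mean_depth
    report = FilterReport(
        axis="individuals",
        n_input=gl.n_individuals,
        removed={"low_mean_depth": int((~keep).sum())},
        n_output=int(keep.sum()),
    )
    return gl.subset(individual_mask=keep), report


def filter_loci(
    gl: GLMatrix,
    min_called_fraction: float = 0.5,
    min_maf: float = 0.05,
    one_per_contig: bool = True,
    seed: int | None = None,
) -> tuple[GLMatrix, FilterReport]:
    """Apply the three locus rules in order: call-rate, MAF, one-per-contig.

    * call-rate: keep loci where the fraction of individuals with at least
      one read is >= ``min_called_fraction`` (inclusive).
    * MAF: estimate allele frequencies by EM on the full retained sample;
      exclude loci with minor allele frequency strictly below ``min_maf``.
    * one-per-contig: among surviving SNPs sharing a contig, keep one chosen
      uniformly at random under ``seed``.
    """
    removed: dict[str, int] = {}
    keep = np.ones(gl.n_loci, dtype=bool)

    frac = gl.covered().mean(axis=0)
    fail = keep & (frac < min_called_fraction)
    removed["call_rate"] = int(fail.sum())
    keep &= ~fail

    sub = gl.subset(locus_mask=keep)
    if sub.n_loci:
        p = em_allele_frequencies(sub.gl)
        maf = np.minimum(p, 1.0 - p)
        fail_sub = maf < min_maf
    else:
        fail_sub = np.zeros(0, dtype=bool)
    fail = np.zeros(gl.n_loci, dtype=bool)
    fail[np.flatnonzero(keep)] = fail_sub
    removed["maf"] = int(fail.sum())
    keep &= ~fail

    if one_per_contig:
        rng = np.random.default_rng(seed)
        fail = np.zeros(gl.n_loci, dtype=bool)
        surviving = np.flatnonzero(keep)
        contigs = gl.contigs[surviving]
        for contig in dict.fromkeys(contigs):  # insertion order, deterministic
            members = surviving[contigs == contig]
            if len(members) > 1:
                chosen = rng.choice(members)
                fail[members[members != chosen]] = True
        removed["one_per_contig"] = int(fail.sum())
        keep &= ~fail

    report = FilterReport(
        axis="loci",
        n_input=gl.n_loci,
        removed=removed,
        n_output=int(keep.sum()),
    )
    return gl.subset(locus_mask=keep), report
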