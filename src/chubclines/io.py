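"""VCF input/output for genotype-likelihood matrices.

Reads biallelic SNP records carrying GL (log10 likelihoods) or PL
(phred-scaled likelihoods) FORMAT fields into a :class:`~chubclines.core.GLMatrix`
and writes matrices back out as VCF v4.2 with GT (uncalled), DP, GL and PL
per sample. When both GL and PL are present GL is preferred: PL is
integer-quantized phred, so only GL can reproduce likelihood triples at full
precision on a write/read round trip.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import GLMatrix

__all__ = ["read_vcf_gl", "write_vcf_gl"]


def read_vcf_gl(path: str | os.PathLike) -> GLMatrix:
    """Read a VCF of biallelic SNPs with GL or PL into a GLMatrix.

    PL values are converted via ``L = 10**(-PL/10)`` and normalized; GL
    (log10) values are exponentiated and normalized. Records lacking both
    fields, or with more than one ALT allele, raise a ValueError naming the
    record.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path)
    individuals = np.array(vcf.samples, dtype=object)
    n = len(individuals)
    gl_rows, depth_rows, meta = [], [], []
    any_depth = False
    for var in vcf:
        label = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise ValueError(
                f"record {label} is not biallelic (ALT={var.ALT}); "
                "only biallelic SNPs are supported"
            )
        triple = _likelihood_triple(var, n, label)
        gl_rows.append(triple)
        depth = None
        try:
            depth = var.format("DP")
        except KeyError:
            depth = None
        if depth is not None:
            any_depth = True
            d = depth.astype(float).reshape(n)
            d[d < 0] = 0
            depth_rows.append(d)
        else:
            depth_rows.append(np.full(n, np.nan))
        meta.append(
            {
                "locus_id": var.ID if var.ID not in (None, ".") else label,
                "contig": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    if not meta:
        raise ValueError(f"no usable records in {path}")
    gl = np.stack(gl_rows, axis=1)  # (N, L, 3)
    depth = None
    if any_depth:
        depth = np.stack(depth_rows, axis=1)
        depth = np.nan_to_num(depth, nan=0.0).astype(int)
    return GLMatrix(
        individuals=individuals, loci=pd.DataFrame(meta), gl=gl, depth=depth
    )


def _likelihood_triple(var, n: int, label: str) -> np.ndarray:
    """Normalized (n, 3) likelihoods from one record, preferring GL."""
    pl = gl = None
    try:
        gl = var.format("GL")
    except KeyError:
        gl = None
    if gl is None:
        try:
            pl = var.format("PL")
        except KeyError:
            pl = None
    if pl is not None:
        pl = pl.astype(float).reshape(n, -1)
        if pl.shape[1] != 3:
            raise ValueError(f"record {label}: PL must have 3 values per sample")
        # cyvcf2 encodes missing integers as large negatives
        missing = np.any(pl < 0, axis=1) | np.any(pl > 2**30, axis=1)
        lik = np.power(10.0, -pl / 10.0)
    elif gl is not None:
        gl = gl.astype(float).reshape(n, -1)
        if gl.shape[1] != 3:
            raise ValueError(f"record {label}: GL must have 3 values per sample")
        missing = ~np.isfinite(gl).all(axis=1)
        gl = np.where(np.isfinite(gl), gl, 0.0)
        gl = gl - gl.max(axis=1, keepdims=True)
        lik = np.power(10.0, gl)
    else:
        raise ValueError(f"record {label} has neither GL nor PL; cannot load")
    lik[missing] = 1.0
    lik /= lik.sum(axis=1, keepdims=True)
    return lik


def write_vcf_gl(gl: GLMatrix, path: str | os.PathLike) -> None:
    """Write a GLMatrix as VCF v4.2 with GT, DP, GL and PL FORMAT fields.

    Genotypes are left uncalled (``./.``); GL holds log10 of the normalized
    triple and PL its phred-scaled, 0-anchored integer form.
    """
    path = os.fspath(path)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=chubclines",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (uncalled)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10 genotype likelihoods">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
    ]
    for contig in pd.unique(gl.contigs):
        lines.append(f"##contig=<ID={contig}>")
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    lines.append(header + "\t" + "\t".join(str(s) for s in gl.individuals))
    loci = gl.loci
    pos = loci["pos"] if "pos" in loci.columns else pd.Series(range(1, gl.n_loci + 1))
    ref = loci["ref"] if "ref" in loci.columns else pd.Series(["A"] * gl.n_loci)
    alt = loci["alt"] if "alt" in loci.columns else pd.Series(["G"] * gl.n_loci)
    log10gl = np.log10(np.maximum(gl.gl, 1e-300))
    pl = np.rint(-10.0 * (log10gl - log10gl.max(axis=2, keepdims=True))).astype(int)
    pl = np.minimum(pl, 99999)
    depth = gl.depth
    for j in range(gl.n_loci):
        fields = [
            str(loci["contig"].iloc[j]),
            str(int(pos.iloc[j])),
            str(loci["locus_id"].iloc[j]),
            str(ref.iloc[j]),
            str(alt.iloc[j]),
            ".",
            "PASS",
            ".",
            "GT:DP:GL:PL",
        ]
        for i in range(gl.n_individuals):
            d = 0 if depth is None else int(depth[i, j])
            gl_str = ",".join(f"{v:.7f}" for v in log10gl[i, j])
            pl_str = ",".join(str(v) for v in pl[i, j])
            fields.append(f"./.:{d}:{gl_str}:{pl_str}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
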