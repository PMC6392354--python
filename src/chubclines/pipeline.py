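"""End-to-end pipeline: simulate -> filter -> admixture -> ancestry classes
-> popgen summaries -> genomic clines (two zones) -> concordance -> env
association.

Stage boundaries are files on disk (VCF/CSV/JSON), so any stage can be
re-run in isolation or swapped for an external tool. Every stochastic stage
draws its seed deterministically from the single config seed, and the
manifest records outputs, seeds and content checksums, so a re-run with the
same config reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .admixture import fit_admixture, fit_ancestry_classes
from .clines import ConcordanceInput, concordance_probability, fit_genomic_clines
from .env_assoc import lmg_importance, stepwise_select
from .filters import filter_individuals, filter_loci
from .io import read_vcf_gl, write_vcf_gl
from .popgen import (
    GenotypePCA,
    allele_frequency_table,
    em_allele_frequencies,
    nucleotide_diversity,
    pairwise_gst,
)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "report", "StageError"]


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "seed": 42,
    "outdir": "chubclines_out",
    "n_loci": 500,
    "divergence": 0.9,
    "prop_fixed": 0.2,
    "mean_depth": 7.0,
    "error_rate": 0.01,
    "design": {"P0": 12, "P1": 12, "F1": 2, "LATE": 54},
    "upstream_design": {"LATE": 10},
    "late_q_beta": [1.5, 1.5],
    "q12_min": 0.05,
    "env_noise_sd": 0.3,
    "n_boot": 200,
    "mcmc": {
        "admixture": {"n_iter": 1200, "burn_in": 400, "thin": 5, "n_chains": 2},
        "classes": {"n_iter": 2000, "burn_in": 500, "thin": 5, "n_chains": 2},
        "clines": {"n_iter": 2500, "burn_in": 1000, "thin": 5, "n_chains": 2},
    },
}

#: fixed offsets turning the config seed into per-stage seeds
_STAGE_SEED_OFFSETS = {
    "simulate": 1,
    "filter": 2,
    "admixture": 3,
    "classes": 4,
    "clines_a": 5,
    "clines_b": 6,
    "envassoc": 7,
}


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML config, filling unspecified keys from the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(cfg: dict, stage: str) -> int:
    return (int(cfg["seed"]) * 1000 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def run_pipeline(config: dict | str | os.PathLike) -> dict:
    """Execute every stage in order and return the output manifest."""
    if isinstance(config, dict):
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = {**json.loads(json.dumps(DEFAULT_CONFIG)), **config}
    else:
        cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": {}}

    def record(stage: str, seed, **files):
        manifest["stages"][stage] = {
            "seed": seed,
            "outputs": {
                name: {"path": str(p), "sha256": _checksum(Path(p))}
                for name, p in files.items()
            },
        }

    # -- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        seed = _stage_seed(cfg, stage)
        freqs = sim.simulate_parental_frequencies(
            cfg["n_loci"], cfg["divergence"], cfg["prop_fixed"], seed=seed
        )
        truth_a, geno_a = sim.simulate_cohort(
            freqs, cfg["design"], tuple(cfg["late_q_beta"]), seed=seed + 1
        )
        reads_a = sim.simulate_reads(
            geno_a,
            cfg["mean_depth"],
            cfg["error_rate"],
            seed=seed + 2,
            individuals=truth_a.individuals,
            contigs=freqs.contigs,
        )
        gl_a = sim.genotype_likelihoods(reads_a, cfg["error_rate"])
        vcf_a = outdir / "zone_a.vcf"
        write_vcf_gl(gl_a, vcf_a)
        truth_a_csv = outdir / "zone_a_truth.csv"
        truth_a.to_frame().to_csv(truth_a_csv, index=False)
        env_csv = outdir / "environment.csv"
        env = sim.simulate_environment(
            1.0 - truth_a.true_q, noise_sd=cfg["env_noise_sd"], seed=seed + 3
        )
        env.insert(0, "individual", truth_a.individuals)
        env.to_csv(env_csv, index=False)
        files = {"vcf_a": vcf_a, "truth_a": truth_a_csv, "environment": env_csv}
        if cfg.get("upstream_design"):
            truth_b, geno_b = sim.simulate_cohort(
                freqs, cfg["upstream_design"], tuple(cfg["late_q_beta"]), seed=seed + 4
            )
            truth_b.individuals = np.array(
                ["up_" + str(x) for x in truth_b.individuals], dtype=object
            )
            reads_b = sim.simulate_reads(
                geno_b,
                cfg["mean_depth"],
                cfg["error_rate"],
                seed=seed + 5,
                individuals=truth_b.individuals,
                contigs=freqs.contigs,
            )
            gl_b = sim.genotype_likelihoods(reads_b, cfg["error_rate"])
            vcf_b = outdir / "zone_b.vcf"
            write_vcf_gl(gl_b, vcf_b)
            truth_b_csv = outdir / "zone_b_truth.csv"
            truth_b.to_frame().to_csv(truth_b_csv, index=False)
            files.update({"vcf_b": vcf_b, "truth_b": truth_b_csv})
        record(stage, seed, **files)
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        raise StageError(stage, str(exc)) from exc

    # -- filter -----------------------------------------------------------
    stage = "filter"
    try:
        seed = _stage_seed(cfg, stage)
        gl_a = read_vcf_gl(outdir / "zone_a.vcf")
        gl_a, rep_ind = filter_individuals(gl_a)
        gl_a, rep_loc = filter_loci(gl_a, one_per_contig=True, seed=seed)
        filtered_vcf = outdir / "zone_a_filtered.vcf"
        write_vcf_gl(gl_a, filtered_vcf)
        report_csv = outdir / "filter_report.csv"
        pd.concat([rep_ind.to_frame(), rep_loc.to_frame()]).to_csv(
            report_csv, index=False
        )
        record(stage, seed, filtered_vcf=filtered_vcf, report=report_csv)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    truth_a = pd.read_csv(outdir / "zone_a_truth.csv")
    classes_of = dict(zip(truth_a["individual"], truth_a["class"]))
    gl_a = read_vcf_gl(outdir / "zone_a_filtered.vcf")
    panel0 = [i for i in gl_a.individuals if classes_of.get(i) == "P0"]
    panel1 = [i for i in gl_a.individuals if classes_of.get(i) == "P1"]

    # -- admixture --------------------------------------------------------
    stage = "admixture"
    try:
        seed = _stage_seed(cfg, stage)
        anchor = None
        if panel1:
            anchor = em_allele_frequencies(gl_a.select_individuals(panel1).gl)
        mcmc = cfg["mcmc"]["admixture"]
        admix = fit_admixture(gl_a, k=2, seed=seed, anchor_freqs=anchor, **mcmc)
        admix_csv = outdir / "admixture_q.csv"
        admix.summary().to_csv(admix_csv, index=False)
        record(stage, seed, q_summary=admix_csv)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- ancestry classes -------------------------------------------------
    stage = "classes"
    try:
        seed = _stage_seed(cfg, stage)
        if not panel0 or not panel1:
            raise ValueError("no parental reference panels in the cohort")
        mcmc = cfg["mcmc"]["classes"]
        classes = fit_ancestry_classes(
            gl_a, panel0, panel1, seed=seed, **mcmc
        )
        classes_csv = outdir / "ancestry_classes.csv"
        classes.summary().to_csv(classes_csv, index=False)
        record(stage, seed, classes=classes_csv)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- popgen summaries -------------------------------------------------
    stage = "popgen"
    try:
        pops: dict[str, list] = {}
        for ind in gl_a.individuals:
            pops.setdefault(classes_of.get(ind, "unknown"), []).append(ind)
        freq_table = allele_frequency_table(gl_a, pops)
        gst = pairwise_gst(freq_table)
        gst_csv = outdir / "gst.csv"
        gst.to_csv(gst_csv)
        pi = nucleotide_diversity(gl_a, pops)
        pi_csv = outdir / "pi.csv"
        pi.to_csv(pi_csv, header=True)
        pca = GenotypePCA(n_components=5).fit(gl_a)
        pca_csv = outdir / "pca_scores.csv"
        frame = pca.to_frame()
        frame.to_csv(pca_csv, index=False)
        var_csv = outdir / "pca_variance.csv"
        pd.Series(
            pca.explained_variance_ratio_,
            index=[f"PC{i + 1}" for i in range(len(pca.explained_variance_ratio_))],
            name="variance_proportion",
        ).to_csv(var_csv, header=True)
        record(stage, None, gst=gst_csv, pi=pi_csv, pca=pca_csv, pca_variance=var_csv)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- genomic clines (per zone) + concordance --------------------------
    stage = "clines"
    try:
        f0 = em_allele_frequencies(gl_a.select_individuals(panel0).gl)
        f1 = em_allele_frequencies(gl_a.select_individuals(panel1).gl)
        class_summary = pd.read_csv(outdir / "ancestry_classes.csv")
        q12_of = dict(zip(class_summary["individual"], class_summary["q12_mean"]))
        hybrids_a = [
            i
            for i in gl_a.individuals
            if i not in set(panel0) | set(panel1)
            and q12_of.get(i, 0.0) > cfg["q12_min"]
        ]
        mcmc = cfg["mcmc"]["clines"]
        zones = {}
        fit_a = fit_genomic_clines(
            gl_a.select_individuals(hybrids_a),
            f0,
            f1,
            seed=_stage_seed(cfg, "clines_a"),
            **mcmc,
        )
        fit_a.locus_table().to_csv(outdir / "clines_zone_a.csv", index=False)
        fit_a.hybrid_table().to_csv(outdir / "hybrid_index_zone_a.csv", index=False)
        zones["a"] = fit_a
        files = {
            "clines_a": outdir / "clines_zone_a.csv",
            "h_a": outdir / "hybrid_index_zone_a.csv",
        }
        if (outdir / "zone_b.vcf").exists():
            gl_b = read_vcf_gl(outdir / "zone_b.vcf")
            # keep only the loci surviving the zone-A filters
            keep = pd.Index(gl_b.locus_ids).get_indexer(gl_a.locus_ids)
            gl_b = gl_b.subset(locus_mask=keep)
            # classes for zone B reuse the zone-A parental frequencies
            from .admixture import AncestryClassModel

            cls_b = AncestryClassModel(
                random_state=_stage_seed(cfg, "classes") + 1,
                **cfg["mcmc"]["classes"],
            ).fit(gl_b, None, None, parental_freqs=(f0, f1))
            hybrids_b = [
                i
                for i, q12 in zip(cls_b.individuals_, cls_b.q12_mean_)
                if q12 > cfg["q12_min"]
            ]
            fit_b = fit_genomic_clines(
                gl_b.select_individuals(hybrids_b),
                f0,
                f1,
                seed=_stage_seed(cfg, "clines_b"),
                **mcmc,
            )
            fit_b.locus_table().to_csv(outdir / "clines_zone_b.csv", index=False)
            fit_b.hybrid_table().to_csv(
                outdir / "hybrid_index_zone_b.csv", index=False
            )
            zones["b"] = fit_b
            files.update(
                {
                    "clines_b": outdir / "clines_zone_b.csv",
                    "h_b": outdir / "hybrid_index_zone_b.csv",
                }
            )
        # concordance of exceptional-alpha sets across zones
        if len(zones) == 2:
            exc_a = set(np.flatnonzero(zones["a"].alpha_flag_ != "none"))
            exc_b = set(np.flatnonzero(zones["b"].alpha_flag_ != "none"))
            large, small = (
                (exc_a, exc_b) if len(exc_a) >= len(exc_b) else (exc_b, exc_a)
            )
            conc = ConcordanceInput(
                l=len(large),
                s=len(small),
                m=len(large & small),
                n=gl_a.n_loci,
            )
            p = concordance_probability(conc)
            conc_json = outdir / "concordance.json"
            conc_json.write_text(
                json.dumps(
                    {
                        "l": conc.l,
                        "s": conc.s,
                        "m": conc.m,
                        "n": conc.n,
                        "p": p,
                    },
                    indent=2,
                )
            )
            files["concordance"] = conc_json
        record(stage, _stage_seed(cfg, "clines_a"), **files)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    manifest["stages"]["clines"]["n_hybrids_zone_a"] = len(hybrids_a)
    manifest["stages"]["clines"]["hybrids_zone_a"] = hybrids_a

    # -- environment association -----------------------------------------
    stage = "envassoc"
    try:
        seed = _stage_seed(cfg, stage)
        env = pd.read_csv(outdir / "environment.csv")
        qtab = pd.read_csv(outdir / "admixture_q.csv")
        merged = env.merge(qtab[["individual", "q0_mean"]], on="individual")
        covars = merged[list(sim.ENV_COVARIATES)]
        response = merged["q0_mean"]  # prairie-like assignment probability
        selection = stepwise_select(response, covars)
        sel_csv = outdir / "env_regression.csv"
        selection.summary_frame().to_csv(sel_csv, index=False)
        if selection.selected_:
            importance = lmg_importance(
                response,
                covars[selection.selected_],
                n_boot=cfg["n_boot"],
                seed=seed,
            )
            imp_csv = outdir / "env_importance.csv"
            importance.summary_frame().to_csv(imp_csv, index=False)
            record(stage, seed, regression=sel_csv, importance=imp_csv)
        else:
            record(stage, seed, regression=sel_csv)
        manifest["stages"][stage]["selected"] = selection.selected_
        manifest["stages"][stage]["r_squared"] = float(
            selection.results_.rsquared
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def report(manifest: dict) -> str:
    """Render a human-readable summary of a completed pipeline run."""
    stages = manifest.get("stages", {})
    required = {"simulate", "filter", "admixture", "classes", "popgen", "clines"}
    missing = required - set(stages)
    if missing:
        raise ValueError(f"manifest incomplete; missing stages: {sorted(missing)}")
    outdir = Path(manifest["config"]["outdir"])
    lines = ["# Hybrid-zone pipeline report", ""]
    rep = pd.read_csv(outdir / "filter_report.csv")
    lines.append("## Filtering")
    lines += [f"- {r.axis} {r.rule}: {r['count']}" for _, r in rep.iterrows()]
    lines.append("")
    lines.append("## Population summaries")
    pi = pd.read_csv(outdir / "pi.csv", index_col=0)
    lines.append("pi per population: " + ", ".join(
        f"{idx}={float(v):.4f}" for idx, v in pi.iloc[:, 0].items()
    ))
    var = pd.read_csv(outdir / "pca_variance.csv", index_col=0)
    lines.append(
        "PCA variance proportions: "
        + ", ".join(f"{i}={float(v):.3f}" for i, v in var.iloc[:, 0].items())
    )
    gst = pd.read_csv(outdir / "gst.csv", index_col=0)
    lines.append(f"GST matrix over {gst.shape[0]} populations written to gst.csv")
    lines.append("")
    lines.append("## Genomic clines")
    for zone in ("a", "b"):
        path = outdir / f"clines_zone_{zone}.csv"
        if not path.exists():
            continue
        tab = pd.read_csv(path)
        counts = {
            "n_pos_alpha": int((tab["alpha_flag"] == "+").sum()),
            "n_neg_alpha": int((tab["alpha_flag"] == "-").sum()),
            "n_pos_beta": int((tab["beta_flag"] == "+").sum()),
            "n_neg_beta": int((tab["beta_flag"] == "-").sum()),
        }
        lines.append(f"zone {zone}: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
    conc_path = outdir / "concordance.json"
    if conc_path.exists():
        conc = json.loads(conc_path.read_text())
        lines.append(
            f"concordance: l={conc['l']} s={conc['s']} m={conc['m']} "
            f"n={conc['n']} p={conc['p']:.4g}"
        )
    lines.append("")
    if "envassoc" in stages:
        lines.append("## Environment association")
        lines.append(
            "selected covariates: "
            + (", ".join(stages["envassoc"].get("selected", [])) or "(none)")
        )
        r2 = stages["envassoc"].get("r_squared")
        if r2 is not None:
            lines.append(f"model R^2 = {float(r2):.3f}")
    return "\n".join(lines)
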