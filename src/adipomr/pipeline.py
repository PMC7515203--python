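"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes the stages (simulate -> mr -> expression ->
deconvolution -> model) in dependency order into an immutable run directory,
records provenance (config hash, seeds, package version) next to every
stage's outputs, and writes a JSON summary; ``make_report`` renders the
summary as markdown tables.  Every applied threshold is logged for
auditability.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deconvolution, expression, insulin_model, mr, synthetic
from ._version import __version__

log = logging.getLogger("adipomr")

STAGES = ["simulate", "mr", "expression", "deconvolution", "model"]


class PipelineError(RuntimeError):
    pass


def default_config(seed: int = 1) -> dict:
    """A small all-synthetic demo configuration."""
    return {
        "seed": seed,
        "stages": {s: True for s in STAGES},
        "simulate": {
            "mr": {"n_variants": 120, "causal_effect": -0.67,
                   "pleiotropy_frac": 0.05, "pleiotropy_mode": "directional"},
            "ld": {"block_size": 4, "within_r2": 0.5},
            "cells": {"n_subjects": 6, "n_celltypes": 8, "n_genes": 1200,
                      "cells_per_subject": 800, "libsize_mean": 2000},
            "cohort": {"n_individuals": 324, "target_r2_total": 0.44},
        },
        "mr": {"p_threshold": 5e-8, "r2_threshold": 0.01, "n_sim": 2000,
               "confounders": [], "confounder_p_threshold": 5e-8},
        "deconvolution": {"min_logfc": 1.0, "max_p": 0.05},
        "model": {"preset": "bmi", "n_groups": 100},
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _provenance(config: dict, stage: str) -> dict:
    return {
        "stage": stage,
        "config_hash": _config_hash(config),
        "seed": config.get("seed"),
        "package_version": __version__,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: dict | str | Path, out_root: str | Path = "runs") -> Path:
    """Run the enabled stages; returns the run directory.

    A stage failure halts the run with the stage's error after writing a
    partial-results manifest.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    stages = {s: bool(config.get("stages", {}).get(s, True)) for s in STAGES}
    run_dir = Path(out_root) / f"run_{time.strftime('%Y%m%dT%H%M%S')}_{_config_hash(config)}"
    run_dir.mkdir(parents=True, exist_ok=False)
    log.setLevel(logging.INFO)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setLevel(logging.INFO)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    summary: dict = {"config_hash": _config_hash(config), "seed": seed,
                     "package_version": __version__, "stages": {}}
    state: dict = {}
    try:
        for stage in STAGES:
            if not stages[stage]:
                log.info("stage %s skipped by config", stage)
                summary["stages"][stage] = {"status": "skipped"}
                continue
            t0 = time.time()
            log.info("stage %s started", stage)
            stage_dir = run_dir / stage
            stage_dir.mkdir(exist_ok=True)
            result = _STAGE_FUNCS[stage](config, state, stage_dir, seed)
            with open(stage_dir / "provenance.json", "w") as fh:
                json.dump(_provenance(config, stage), fh, indent=2)
            summary["stages"][stage] = {
                "status": "ok", "seconds": round(time.time() - t0, 2), **_jsonable(result)
            }
            log.info("stage %s finished in %.1fs", stage, time.time() - t0)
    except Exception as exc:
        summary["error"] = {"stage": stage, "message": str(exc)}
        with open(run_dir / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2)
        log.removeHandler(handler)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    with open(run_dir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2)
    log.removeHandler(handler)
    return run_dir


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config, state, outdir: Path, seed: int) -> dict:
    sim = config.get("simulate", {})
    mr_cfg = synthetic.MRSimConfig(**sim.get("mr", {}), seed=seed)
    ivs, mr_truth = synthetic.simulate_mr_summary(mr_cfg)
    ld_cfg = sim.get("ld", {"block_size": 4, "within_r2": 0.5})
    ld = synthetic.simulate_ld_blocks(mr_cfg.n_variants, ld_cfg["block_size"],
                                      ld_cfg["within_r2"], seed=seed + 1)
    synthetic.write_ivtable(ivs, outdir / "ivs.tsv")
    synthetic.write_ld_matrix(ld, outdir / "ld.tsv")

    cell_cfg = synthetic.CellSimConfig(**sim.get("cells", {}), seed=seed + 2)
    adata, cell_truth = synthetic.simulate_sc_reference(cell_cfg)
    synthetic.write_sc_reference(adata, outdir / "sc_reference")
    bulk = synthetic.simulate_bulk_mixtures(
        cell_truth, cell_truth.true_proportions, seed=seed + 3,
        gene_lengths=adata.var["length"],
    )
    bulk.counts.to_csv(outdir / "bulk_counts.tsv", sep="\t")
    bulk.gene_meta.to_csv(outdir / "bulk_genes.tsv", sep="\t")

    pheno_cfg = synthetic.PhenoSimConfig(**sim.get("cohort", {}), seed=seed + 4)
    cohort, cohort_truth = synthetic.simulate_cohort(pheno_cfg)
    synthetic.write_cohort(cohort, outdir / "cohort.tsv")
    state.update(
        ivs=ivs, ld=ld, adata=adata, cell_truth=cell_truth, bulk=bulk,
        cohort_raw=cohort, cohort_truth=cohort_truth,
    )
    return {
        "n_variants": len(ivs), "n_cells": int(adata.n_obs),
        "n_individuals": len(cohort), "true_causal_effect": mr_truth.causal_effect,
    }


def _stage_mr(config, state, outdir: Path, seed: int) -> dict:
    opts = config.get("mr", {})
    p_thr = opts.get("p_threshold", 5e-8)
    r2_thr = opts.get("r2_threshold", 0.01)
    log.info("IV selection thresholds: p<%g, r2<%g", p_thr, r2_thr)
    ivs = mr.select_ivs(state["ivs"], state["ld"], p_thr, r2_thr)
    confounders = opts.get("confounders", [])
    if confounders:
        ivs, dropped = mr.exclude_confounded_ivs(
            ivs, confounders, opts.get("confounder_p_threshold", 5e-8)
        )
        dropped.to_csv(outdir / "confounded_ivs.tsv", sep="\t", index=False)
    report = mr.run_mr_battery(ivs, n_sim=opts.get("n_sim", 5000), seed=seed)
    ivs.to_csv(outdir / "selected_ivs.tsv", sep="\t", index=False)
    with open(outdir / "mr_report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    # Fig-1B-style scatter data
    ivs[["variant_id", "beta_exp", "se_exp", "beta_out", "se_out"]].to_csv(
        outdir / "scatter.tsv", sep="\t", index=False
    )
    state["mr_report"] = report
    return {"forward": report}


def _stage_expression(config, state, outdir: Path, seed: int) -> dict:
    cohort = state["cohort_raw"].set_index("individual_id")
    metrics = expression.rna_metrics_excluding_mt(cohort)
    metrics.to_csv(outdir / "rna_metrics.tsv", sep="\t")
    # exonic+intronic+intergenic sum to 100 over nuclear reads; keep two
    tech = pd.concat(
        [metrics[["exonic_pct", "intergenic_pct"]],
         cohort[[c for c in cohort.columns if c.startswith(("tech_", "pc"))]]],
        axis=1,
    )
    adjusted = expression.adjust_mt_expression(
        cohort["mt_expression"], tech,
        factors=[c for c in tech.columns if not c.startswith("pc")],
        pcs=["pc1", "pc2", "pc3"],
    )
    adjusted.to_frame().to_csv(outdir / "mt_adjusted.tsv", sep="\t")
    state["mt_adjusted"] = adjusted
    nondiab = ~cohort["t2d_flag"].astype(bool)
    assoc = np.corrcoef(adjusted[nondiab], cohort.loc[nondiab, "bodyfat_pct"])[0, 1]
    return {"n_samples": len(adjusted), "corr_mt_bodyfat": float(assoc)}


def _stage_deconvolution(config, state, outdir: Path, seed: int) -> dict:
    opts = config.get("deconvolution", {})
    log.info("reference QC thresholds: >=%d genes/cell, >=%d cells/gene",
             deconvolution.MIN_GENES_PER_CELL, deconvolution.MIN_CELLS_PER_GENE)
    adata, qc_report = deconvolution.qc_reference(state["adata"])
    bulk_tpm = state["bulk"].tpm
    loo = deconvolution.loo_validate(
        adata, bulk_tpm, min_logfc=opts.get("min_logfc", 1.0),
        max_p=opts.get("max_p", 0.05),
    )
    loo.estimated.to_csv(outdir / "loo_estimated.tsv", sep="\t")
    loo.true.to_csv(outdir / "loo_true.tsv", sep="\t")
    loo.per_celltype.to_csv(outdir / "loo_per_celltype.tsv", sep="\t")

    # Full-reference proportions for the bulk samples (S3-Table analogue).
    sig = deconvolution.select_signature_genes(
        adata, min_logfc=opts.get("min_logfc", 1.0), max_p=opts.get("max_p", 0.05)
    )
    pseudo, profiles = deconvolution.build_pseudobulk(adata)
    kept, filt = deconvolution.concordance_filter(bulk_tpm, pseudo)
    log.info("concordance filter: chi-square <= 1 kept %d/%d genes",
             int(filt['kept'].sum()), len(filt))
    filt.to_csv(outdir / "concordance_filter.tsv", sep="\t")
    genes = pd.Index(sig["gene"].unique()).intersection(kept).intersection(bulk_tpm.index)
    props = deconvolution.deconvolve_samples(bulk_tpm, profiles, genes)
    props.to_csv(outdir / "proportions.tsv", sep="\t")
    state["loo"] = loo
    return {
        "qc": qc_report, "n_signature_genes": int(sig["gene"].nunique()),
        "n_genes_after_filter": len(genes),
        "loo_overall_r": loo.overall_r, "loo_overall_rmse": loo.overall_rmse,
    }


def _stage_model(config, state, outdir: Path, seed: int) -> dict:
    opts = config.get("model", {})
    cohort = insulin_model.prepare_cohort(state["cohort_raw"])
    fit = insulin_model.fit_model1(cohort)
    fit.to_frame().to_csv(outdir / "model1.tsv", sep="\t")
    r2 = insulin_model.variance_explained(
        cohort, insulin_model.default_predictor_sets(cohort)
    )
    r2.to_frame().to_csv(outdir / "variance_explained.tsv", sep="\t")
    scan = insulin_model.celltype_association_scan(cohort)
    scan.to_csv(outdir / "celltype_associations.tsv", sep="\t")
    preset = opts.get("preset", "bmi")
    cv = insulin_model.cross_validate_100fold(
        cohort, insulin_model.preset_predictors(cohort, preset),
        n_groups=opts.get("n_groups", 100), seed=seed,
    )
    pd.DataFrame(
        {"observed": cv["observed"], "predicted": cv["predictions"]}
    ).to_csv(outdir / "oof_predictions.tsv", sep="\t", index=False)
    model = insulin_model.elastic_net_fit(
        cohort[insulin_model.preset_predictors(cohort, preset)],
        cohort["matsuda"], seed=seed,
    )
    model.to_json(outdir / "elastic_net_model.json")
    state["model1"] = fit
    return {
        "model1_r2": fit.r2, "n": fit.n,
        "variance_explained": r2.to_dict(),
        "oof_pearson_r": cv["pearson_r"], "oof_p": cv["p"],
        "elastic_net_lambda": model.lambda_,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "mr": _stage_mr,
    "expression": _stage_expression,
    "deconvolution": _stage_deconvolution,
    "model": _stage_model,
}


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def make_report(run_dir: str | Path) -> Path:
    """Render a human-readable markdown summary of a completed run."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise PipelineError(f"no summary.json in {run_dir}")
    with open(summary_path) as fh:
        summary = json.load(fh)
    lines = [
        "# adipomr run report",
        f"- config hash: `{summary['config_hash']}`",
        f"- seed: {summary['seed']}",
        f"- package version: {summary['package_version']}",
        "",
    ]
    stages = summary.get("stages", {})
    mr_stage = stages.get("mr", {})
    if mr_stage.get("status") == "ok":
        fwd = mr_stage["forward"]
        lines.append("## Mendelian randomization")
        if fwd.get("assessable"):
            presso, egger = fwd["presso"], fwd["egger"]
            lines += [
                "| method | estimate | se | p (adjusted) | pleiotropy p |",
                "|---|---|---|---|---|",
                f"| PRESSO-corrected | {presso['estimate']:.4f} | {presso['se']:.4f} "
                f"| {presso['p_adjusted']:.3g} | global {presso['presso_global_p']:.3g} |",
                f"| Egger | {egger['estimate']:.4f} | {egger['se']:.4f} "
                f"| {egger['p_adjusted']:.3g} | intercept {egger['intercept_p']:.3g} |",
                f"| heterogeneity | Q = {fwd['heterogeneity']['Q']:.2f} | | "
                f"{fwd['heterogeneity']['Q_p']:.3g} | |",
                "",
            ]
        else:
            lines.append("direction not assessable: "
                         f"{fwd.get('reason', 'no instruments')}\n")
    dec = stages.get("deconvolution", {})
    if dec.get("status") == "ok":
        lines += [
            "## Deconvolution (leave-one-out)",
            f"- signature genes: {dec['n_signature_genes']}",
            f"- genes after concordance filter: {dec['n_genes_after_filter']}",
            f"- overall Pearson r: {dec['loo_overall_r']:.3f}",
            f"- overall RMSE: {dec['loo_overall_rmse']:.4f}",
            "",
        ]
        per_ct = run_dir / "deconvolution" / "loo_per_celltype.tsv"
        if per_ct.exists():
            tbl = pd.read_csv(per_ct, sep="\t", index_col=0)
            lines.append("| cell type | pearson r | RMSE |")
            lines.append("|---|---|---|")
            for ct, row in tbl.iterrows():
                lines.append(f"| {ct} | {row['pearson_r']:.3f} | {row['rmse']:.4f} |")
            lines.append("")
    mod = stages.get("model", {})
    if mod.get("status") == "ok":
        lines += [
            "## Insulin-sensitivity model",
            f"- Model 1 R^2: {mod['model1_r2']:.4f} (n = {mod['n']})",
            f"- out-of-fold Pearson r: {mod['oof_pearson_r']:.3f} "
            f"(p = {mod['oof_p']:.3g})",
            "- variance explained by predictor set: "
            + ", ".join(f"{k} {v:.3f}" for k, v in mod["variance_explained"].items()),
            "",
        ]
    for stage, info in stages.items():
        if info.get("status") == "skipped":
            lines.append(f"_stage `{stage}` skipped_")
    report_path = run_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
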