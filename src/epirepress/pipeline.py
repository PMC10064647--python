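"""End-to-end orchestration: one config in, one run directory out.

``simulate_workspace`` writes a complete synthetic input workspace (the same
TSV/GMT formats the pipeline reads) plus a YAML manifest; ``run_pipeline``
executes methylation processing → differential expression → GSEA on both
sides → integration → signature scoring and refinement → survival
stratification, writing each stage's artifact, a provenance record and a
human-readable summary into the run directory.  Reruns with the same config
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as wio
from . import gsea as gs
from . import integrate as ig
from . import methylome as me
from . import signature as sg
from . import survival as sv
from . import synthio
from . import transcriptome as tr

__all__ = ["simulate_workspace", "run_pipeline"]


def simulate_workspace(cfg: synthio.SynthConfig, outdir) -> dict:
    """Generate every pipeline input into ``outdir``; returns the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    M, U, det, ann, truth = synthio.make_methylation_dataset(cfg)
    expr = synthio.make_expression_dataset(cfg, truth)
    sets = synthio.make_gene_sets(cfg, truth)
    cohort_expr, clinical, latent = synthio.make_cohort(
        cfg, sorted(truth.repressed_gene_ids) or list(expr.index[:10]))
    truth.true_patient_score = latent

    files = {
        "meth_m": "intensity_M.tsv", "meth_u": "intensity_U.tsv",
        "detection_p": "detection_p.tsv", "annotation": "probe_annotation.tsv",
        "assignments": "probe_assignments.tsv", "expression": "expression_tpm.tsv",
        "gene_sets": "gene_sets.gmt", "cohort_expression": "cohort_expression.tsv",
        "cohort_clinical": "cohort_clinical.tsv",
    }
    wio.write_matrix_tsv(M, out / files["meth_m"], "probe_id")
    wio.write_matrix_tsv(U, out / files["meth_u"], "probe_id")
    wio.write_matrix_tsv(det, out / files["detection_p"], "probe_id")
    wio.write_matrix_tsv(ann.probes, out / files["annotation"], "probe_id")
    ann.assignments.to_csv(out / files["assignments"], sep="\t", index=False)
    wio.write_matrix_tsv(expr, out / files["expression"], "gene_id")
    wio.write_gmt(sets, out / files["gene_sets"])
    wio.write_matrix_tsv(cohort_expr, out / files["cohort_expression"], "gene_id")
    wio.write_matrix_tsv(clinical, out / files["cohort_clinical"], "patient_id")

    truth_files = {
        "hyper_probes": "truth_hyper_probes.txt", "hypo_probes": "truth_hypo_probes.txt",
        "repressed_genes": "truth_repressed_genes.txt",
        "causal_sets": "truth_causal_sets.txt", "latent_score": "truth_latent_score.tsv",
    }
    (out / truth_files["hyper_probes"]).write_text("\n".join(sorted(truth.hyper_probe_ids)) + "\n")
    (out / truth_files["hypo_probes"]).write_text("\n".join(sorted(truth.hypo_probe_ids)) + "\n")
    (out / truth_files["repressed_genes"]).write_text("\n".join(sorted(truth.repressed_gene_ids)) + "\n")
    (out / truth_files["causal_sets"]).write_text("\n".join(sorted(truth.causal_set_names)) + "\n")
    latent.to_frame().to_csv(out / truth_files["latent_score"], sep="\t",
                             float_format=wio.FLOAT_FORMAT, index_label="patient_id")

    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["region_mix"] = dict(cfg.region_mix)
    cfg_dict["set_size_range"] = list(cfg.set_size_range)
    wio.write_manifest(out / "manifest.yaml", cfg_dict, files, truth_files)

    pcfg = wio.PipelineConfig(
        meth_m=str(out / files["meth_m"]), meth_u=str(out / files["meth_u"]),
        detection_p=str(out / files["detection_p"]),
        annotation=str(out / files["annotation"]),
        expression=str(out / files["expression"]),
        gene_sets=str(out / files["gene_sets"]),
        cohort_expression=str(out / files["cohort_expression"]),
        cohort_clinical=str(out / files["cohort_clinical"]),
        sample_conditions=dict(truth.conditions),
        seed=cfg.seed,
    )
    pcfg.to_yaml(out / "pipeline_config.yaml")
    manifest = wio.read_manifest(out / "manifest.yaml")
    manifest["pipeline_config"] = str(out / "pipeline_config.yaml")
    manifest["assignments"] = str(out / files["assignments"])
    return manifest


def _load_annotation(cfg: wio.PipelineConfig) -> me.ProbeAnnotation:
    probes = wio.parse_matrix_tsv(cfg.annotation)
    assign_path = Path(cfg.annotation).with_name("probe_assignments.tsv")
    assignments = pd.read_csv(assign_path, sep="\t", dtype=str).fillna({"gene_id": ""})
    return me.ProbeAnnotation(probes, assignments)


def run_pipeline(cfg: wio.PipelineConfig, outdir) -> dict:
    """Run every stage and write artifacts into ``outdir``; returns a summary dict."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # -- methylome ----------------------------------------------------------
    M = wio.parse_matrix_tsv(cfg.meth_m)
    U = wio.parse_matrix_tsv(cfg.meth_u)
    det = wio.parse_matrix_tsv(cfg.detection_p)
    ann = _load_annotation(cfg)
    conditions = pd.Series(dict(cfg.sample_conditions))
    beta = me.compute_beta(M, U, conditions, offset=cfg.intensity_offset)
    beta, removal_log = me.filter_probes(beta, ann, det)
    beta = me.peak_correct(beta, ann)
    dmc = me.diff_methylation(beta, delta_beta_threshold=cfg.delta_beta, alpha=cfg.p_adj)
    dmc.to_csv(out / "dmc_table.tsv", sep="\t", float_format=wio.FLOAT_FORMAT)
    removal_log.to_csv(out / "probe_removal_log.tsv", sep="\t", index=False)
    dmc_summary = me.summarize_dmc(dmc, ann)

    # -- transcriptome ------------------------------------------------------
    expr = wio.parse_matrix_tsv(cfg.expression)
    deg = tr.standin_de(expr, conditions, fdr=cfg.de_fdr, tpm_min=cfg.tpm_min)
    deg.to_csv(out / "deg_table.tsv", sep="\t", float_format=wio.FLOAT_FORMAT)
    deg_summary = tr.summarize_deg(deg)

    # -- GSEA on both sides -------------------------------------------------
    sets = wio.parse_gmt(cfg.gene_sets)
    meth_scores = gs.gene_level_delta_beta(dmc, ann.assignments, rule=cfg.aggregation)
    meth_rank = gs.make_rank_file(meth_scores)
    expr_rank = gs.make_rank_file(deg["beta_fc"])
    rng = np.random.default_rng(cfg.seed)
    meth_gsea = gs.permutation_stats(meth_rank, sets, n_perm=cfg.n_perm,
                                     weight_p=cfg.weight_p, seed=rng, alpha=cfg.gsea_fdr)
    expr_gsea = gs.permutation_stats(expr_rank, sets, n_perm=cfg.n_perm,
                                     weight_p=cfg.weight_p, seed=rng, alpha=cfg.gsea_fdr)
    for name, res in [("gsea_methylation.tsv", meth_gsea), ("gsea_expression.tsv", expr_gsea)]:
        dump = res.copy()
        dump["leading_edge"] = dump["leading_edge"].map(",".join)
        dump.to_csv(out / name, sep="\t", float_format=wio.FLOAT_FORMAT)
    wio.write_rnk(meth_rank, out / "methylation.rnk")
    wio.write_rnk(expr_rank, out / "expression.rnk")

    # -- integration --------------------------------------------------------
    flags = ig.gene_methylation_status(dmc, ann.assignments)
    lists = ig.build_lists(flags, deg)
    lists.repressed_pathways = ig.epigenetically_repressed_pathways(meth_gsea, expr_gsea)
    lists.signature_genes = ig.derive_signature(
        lists.list2_down_hyper, lists.repressed_pathways, sets, combine=cfg.signature_combine)
    for fname, genes in [("list1_up_hypo.tsv", lists.list1_up_hypo),
                         ("list2_down_hyper.tsv", lists.list2_down_hyper),
                         ("body_up_hyper.tsv", lists.body_up_hyper),
                         ("body_down_hypo.tsv", lists.body_down_hypo),
                         ("signature_genes.tsv", lists.signature_genes)]:
        pd.Series(genes, name="gene_id").to_csv(out / fname, sep="\t", index=False)

    # -- signature scoring + refinement on the cohort ----------------------
    cohort_expr = wio.parse_matrix_tsv(cfg.cohort_expression)
    clinical = wio.parse_matrix_tsv(cfg.cohort_clinical)
    summary = {
        "config_hash": cfg.config_hash(),
        "dmc": dmc_summary.as_dict(),
        "deg": deg_summary,
        "repressed_pathways": lists.repressed_pathways,
        "n_list1": len(lists.list1_up_hypo), "n_list2": len(lists.list2_down_hyper),
        "n_signature": len(lists.signature_genes),
    }
    refined: list[str] = []
    if lists.signature_genes and lists.repressed_pathways:
        gene_pathways = {
            g: [p for p in lists.repressed_pathways if g in sets[p].genes]
            for g in lists.signature_genes
        }
        refined, report = sg.refine_signature(
            cohort_expr, lists.signature_genes, gene_pathways, sets,
            r_min=cfg.refine_r, p_max=cfg.refine_p)
        report.to_csv(out / "refinement_report.tsv", sep="\t", index=False,
                      float_format=wio.FLOAT_FORMAT)
        score_genes = refined or lists.signature_genes
        score = sg.signature_score(cohort_expr, score_genes)
        score.scores.to_frame().to_csv(out / "patient_scores.tsv", sep="\t",
                                       float_format=wio.FLOAT_FORMAT,
                                       index_label="patient_id")

        strata = sv.stratify(score.scores, clinical, scheme=cfg.stratification)
        strata.to_csv(out / "cohort_strata.tsv", sep="\t", float_format=wio.FLOAT_FORMAT,
                      index_label="patient_id")
        low = strata[strata["group"] == "low"]
        high = strata[strata["group"] == "high"]
        chi2, p = sv.logrank(low["time_months"], low["event"],
                             high["time_months"], high["event"])
        for label, grp in [("low", low), ("high", high)]:
            km = sv.km_estimate(grp["time_months"], grp["event"])
            km.to_csv(out / f"km_{label}.tsv", sep="\t", index=False,
                      float_format=wio.FLOAT_FORMAT)
        summary.update({
            "n_refined": len(refined), "refined_genes": refined,
            "logrank_chi2": chi2, "logrank_p": p,
            "group_sizes": {k: int(v) for k, v in strata["group"].value_counts().items()},
        })

    provenance = {
        "version": __version__, "seed": cfg.seed, "config_hash": cfg.config_hash(),
        "config": {k: (dict(v) if isinstance(v, dict) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    lines = [
        f"differential CpGs: {dmc_summary.n_dmc} "
        f"({dmc_summary.pct_hyper}% hyper, {dmc_summary.pct_hypo}% hypo)",
        f"differential genes: {deg_summary['n_total']} "
        f"({deg_summary['n_down']} down, {deg_summary['n_up']} up)",
        f"epigenetically repressed pathways: {len(lists.repressed_pathways)}",
        f"signature genes: {len(lists.signature_genes)} (refined: {len(refined)})",
    ]
    if "logrank_p" in summary:
        lines.append(f"low-vs-high log-rank p = {summary['logrank_p']:.4g}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
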