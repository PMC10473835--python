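"""Full-analysis orchestration: ingest -> preprocess -> DE -> scans -> clustering
-> metabolite links, with a machine-readable run report.

Stage order is fixed: bridging first, then LOD filtering, then outlier
removal, then the statistical stages.  The report records sample/protein
counts at every stage, every QC exclusion with its reason, DE up/down/ns
counts, cluster sizes, enrichment and scan tables, the seeds used and a
hash of the normalized config, so a rerun with the same config and inputs
reproduces every output.
"""

from __future__ import annotations

import json
import os
import time

import numpy as np
import pandas as pd

from . import clustering, diffexp, io, metabolites, preprocess, scans
from .config import config_hash, validate_config
from .exceptions import NpxccError


def _stage(report, name, t0, **info):
    report["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3), **info})


def run_full(cfg: dict, outdir: str | None = None) -> dict:
    """Execute every stage the inputs allow and write outputs + report.

    Required inputs: npx_a, npx_b, metadata.  Metabolite and genotype
    stages run only when their files are configured.  Returns the report
    dict (also written as JSON and markdown under the output directory).
    """
    cfg = validate_config(cfg)
    outdir = outdir or cfg["output_dir"]
    os.makedirs(outdir, exist_ok=True)
    report: dict = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "stages": [],
    }
    thr, modes = cfg["thresholds"], cfg["modes"]

    # -- ingest -------------------------------------------------------------
    t0 = time.time()
    paths = cfg["inputs"]
    for key in ("npx_a", "npx_b", "metadata"):
        if not paths.get(key):
            raise NpxccError(f"missing required input path: inputs.{key}")
    a = io.read_npx_long(paths["npx_a"], cfg["cohort_a"])
    b = io.read_npx_long(paths["npx_b"], cfg["cohort_b"])
    meta = io.read_metadata(paths["metadata"])
    io.join_metadata(a, meta)  # validates overlap
    _stage(report, "ingest", t0,
           samples={a.cohort: a.n_samples, b.cohort: b.n_samples},
           proteins={a.cohort: a.n_proteins, b.cohort: b.n_proteins})

    # -- preprocess ----------------------------------------------------------
    t0 = time.time()
    pcfg = preprocess.PreprocessConfig(
        lod_max_frac=thr["lod_max_frac"],
        lod_mode=modes["lod_mode"],
        outlier_sd=thr["outlier_sd"],
        outlier_components=int(thr["outlier_components"]),
        pca_scale=modes["pca_scale"],
    )
    clean_a, clean_b, qc = preprocess.preprocess_pipeline(a, b, pcfg)
    qc.to_json(os.path.join(outdir, "qc_report.json"))
    qc.to_tsv(os.path.join(outdir, "qc"))
    report["qc"] = {
        "counts": qc.counts,
        "n_excluded_proteins": len({e["protein"] for e in qc.excluded_proteins}),
        "n_outlier_samples": int(len(qc.outlier_samples)),
    }
    _stage(report, "preprocess", t0, **qc.counts)

    # -- differential expression ---------------------------------------------
    t0 = time.time()
    de = diffexp.run_de(
        clean_a, clean_b, meta,
        covariates=cfg["covariates"],
        moderated=bool(modes["moderation"]),
        fdr_cut=thr["fdr_cut"],
        fc_cut=thr["fc_cut"],
    )
    de.to_tsv(os.path.join(outdir, "de_results.tsv"))
    de.volcano_table().to_csv(os.path.join(outdir, "volcano.tsv"), sep="\t")
    report["de"] = {
        "counts": de.counts,
        "moderation": {"d0": de.params.d0, "s0_sq": de.params.s0_sq},
        "n_proteins": int(len(de.table)),
        "top": de.summary().head(10).reset_index().to_dict(orient="records"),
    }
    _stage(report, "diffexp", t0, **de.counts)

    # -- factor scans ----------------------------------------------------------
    t0 = time.time()
    scan_frames = []
    for m in (clean_a, clean_b):
        sub = meta.reindex(m.study_values().index)
        for factor in ("age", "sex", "bmi", "season", "residency"):
            if factor not in sub.columns or sub[factor].dropna().nunique() < 2:
                continue
            scan_frames.append(scans.factor_scan(m, sub, factor, cohort=m.cohort))
    factor_table = pd.concat(scan_frames, ignore_index=True) if scan_frames else pd.DataFrame()
    if len(factor_table):
        factor_table.to_csv(os.path.join(outdir, "factor_scans.tsv"), sep="\t", index=False)
    report["factor_scans"] = {
        "n_tests": int(len(factor_table)),
        "n_significant": int((factor_table["fdr"] < thr["fdr_cut"]).sum()) if len(factor_table) else 0,
    }
    _stage(report, "factor_scans", t0)

    # -- pQTL -------------------------------------------------------------------
    if paths.get("genotypes"):
        t0 = time.time()
        geno = io.read_genotypes(paths["genotypes"])
        pqtl = scans.pqtl_scan(geno, clean_a, meta)
        pqtl.to_csv(os.path.join(outdir, "pqtl.tsv"), sep="\t", index=False)
        report["pqtl"] = {
            "n_pairs": int(len(pqtl)),
            "n_genome_wide": int(pqtl["genome_wide"].sum()),
            "n_suggestive": int(pqtl["suggestive"].sum()),
        }
        _stage(report, "pqtl", t0)

    # -- clustering + metabolite links ------------------------------------------
    if paths.get("metabolite_matrix") and paths.get("metabolite_annotation"):
        t0 = time.time()
        metab = io.read_metabolites(paths["metabolite_matrix"], paths["metabolite_annotation"])
        food = metabolites.select_food_metabolites(metab)
        overlap = clean_a.study_values().index.intersection(food.values.index)
        m_assign = clustering.cluster_metabolome(food.values.loc[overlap], k=int(modes["cluster_k"]))
        npx_study = clean_a.study_values().loc[overlap]
        if modes["clustering_method"] == "kmeans":
            p_assign = clustering.cluster_proteome(
                npx_study, k=int(modes["cluster_k"]),
                restarts=int(modes["cluster_restarts"]), seed=cfg["seed"],
            )
        else:
            p_assign = clustering.cluster_metabolome(npx_study, k=int(modes["cluster_k"]))
        ann = meta.reindex(overlap)[
            [c for c in ("age", "sex", "bmi", "season", "residency") if c in meta.columns]
        ].copy()
        ann["food_metabolome_cluster"] = m_assign.labels.astype(str)
        enrich = clustering.cluster_enrichment(p_assign, ann)
        pd.DataFrame(
            {"sample_id": p_assign.labels.index,
             "proteome_cluster": p_assign.labels.to_numpy(),
             "metabolome_cluster": m_assign.labels.reindex(p_assign.labels.index).to_numpy()}
        ).to_csv(os.path.join(outdir, "clusters.tsv"), sep="\t", index=False)
        enrich.to_csv(os.path.join(outdir, "cluster_enrichment.tsv"), sep="\t", index=False)
        report["clustering"] = {
            "proteome_sizes": {int(k): int(v) for k, v in p_assign.sizes().items()},
            "metabolome_sizes": {int(k): int(v) for k, v in m_assign.sizes().items()},
            "enrichment": enrich.drop(columns=["contingency"], errors="ignore").to_dict(orient="records"),
        }
        _stage(report, "clustering", t0)

        t0 = time.time()
        scan = metabolites.metabolite_protein_scan(
            food, clean_a, meta, fdr_family=modes["fdr_family"]
        )
        scan.to_csv(os.path.join(outdir, "metabolite_protein_scan.tsv"), sep="\t", index=False)
        summ = metabolites.class_summary(scan, fdr_cut=thr["fdr_cut"])
        summ.to_csv(os.path.join(outdir, "metabolite_class_summary.tsv"), sep="\t")
        report["metabolite_links"] = {
            "n_pairs": int(len(scan)),
            "n_significant": int((scan["fdr"] < thr["fdr_cut"]).sum()),
            "class_summary": summ.reset_index().to_dict(orient="records"),
        }
        _stage(report, "metabolite_links", t0)

    report["report_hash"] = _report_hash(report)
    _write_report(report, outdir)
    return report


def _report_hash(report: dict) -> str:
    """Content hash of the report with per-stage wall times stripped, so two
    runs with the same config and inputs hash identically."""
    import copy
    import hashlib

    clean = copy.deepcopy(report)
    for st in clean.get("stages", []):
        st.pop("seconds", None)
    text = json.dumps(clean, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _write_report(report: dict, outdir: str) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default)

    lines = ["# npxcc run report", "", f"config hash: `{report['config_hash']}`", ""]
    for st in report["stages"]:
        lines.append(f"- **{st['stage']}** ({st['seconds']}s): "
                     + ", ".join(f"{k}={v}" for k, v in st.items() if k not in ("stage", "seconds")))
    if "de" in report:
        c = report["de"]["counts"]
        lines += ["", f"Differential expression: {c['up']} up, {c['down']} down, {c['ns']} ns."]
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
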