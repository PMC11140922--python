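"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: synthetic data generation -> variant QC
-> structure estimation -> GWAS scans (flight capability, forewing
length) -> LD gene annotation -> inbred-line co-segregation ->
enrichment + MCL clustering -> DAPC profiling.  All randomness flows
from one root seed through per-stage derived streams, and a manifest
records the config snapshot, seeds, per-stage output digests and
timings; a rerun with the same seed reproduces byte-identical TSV/JSON
outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataio import (
    write_category_scheme,
    write_gene_table,
    write_go_tables,
    write_sample_table,
    write_vcf,
)
from .enrichment import (
    build_term_graph,
    categorize_terms,
    category_overrepresentation,
    describe_clusters,
    mcl_cluster,
    term_enrichment,
)
from .gwas import bin_flight, candidate_overlap, ld_annotate, model_grid
from .inbred import InbredQCConfig, inbred_qc, segregating_candidates, segregation_summary
from .profiler import replicate_profiling
from .structure import (
    DEFAULT_KINSHIP_THRESHOLD,
    king_kinship,
    kinship_factors,
    partition_unrelated,
    pc_adjusted_kinship,
    pca_unrelated_project,
)
from .synth import SynthConfig, simulate_annotation, simulate_cohort, simulate_inbred_lines
from .variant_qc import QCConfig, run_qc

__all__ = ["DEFAULTS", "validate_config", "run_all"]

#: Pipeline defaults: the thresholds every stage applies unless overridden.
DEFAULTS: dict = {
    "seed": 0,
    "synth": {},  # SynthConfig field overrides
    "qc": {
        "hwe_alpha": 1e-6,
        "maf_global_min": 0.10,
        "maf_esm_min": 0.30,
        "locus_max_missing": 0.5,
        "min_mean_depth": 5.0,
        "sample_max_missing": 0.5,
    },
    "structure": {
        "kinship_threshold": DEFAULT_KINSHIP_THRESHOLD,
        "n_pcs": 4,
        "n_kinship_factors": 2,
    },
    "gwas": {
        "pc_grid": [0, 2, 4],
        "p_max": 0.05,
        "r_min": 0.90,
    },
    "inbred": {
        "min_depth": 10,
        "max_heterozygosity": 0.93,
        "min_genotyping_rate": 0.70,
        "mode": "conjunction",
    },
    "enrich": {
        "term_alpha": 0.05,
        "category_fdr": 0.05,
        "edge_min_weight": 0.5,
        "inflation": 2.0,
    },
    "profile": {
        "n_train_per_class": 50,
        "n_reps": 10,
        "n_panel_loci": 12,
        "pc_grid": None,  # adaptive: doubling grid up to the panel rank
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    for key, base in defaults.items():
        if key in override:
            val = override[key]
            out[key] = _merge(base, val, f"{path}{key}.") if isinstance(base, dict) else val
        else:
            out[key] = base
    unknown = set(override) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(path + k for k in unknown)}")
    return out


def validate_config(config: dict | None) -> dict:
    """Inject defaults and range-check a pipeline config."""
    config = dict(config or {})
    # the synth section is free-form (any SynthConfig field), so it is
    # validated against the dataclass rather than merged key-by-key
    synth_override = dict(config.pop("synth", {}))
    unknown_synth = set(synth_override) - set(SynthConfig.__dataclass_fields__)
    if unknown_synth:
        raise ValueError(
            f"unknown config key(s): {sorted('synth.' + k for k in unknown_synth)}")
    cfg = _merge({k: v for k, v in DEFAULTS.items() if k != "synth"}, config)
    cfg["synth"] = synth_override
    if cfg["structure"]["kinship_threshold"] < 0:
        raise ValueError("kinship_threshold must be non-negative")
    for key in ("maf_global_min", "maf_esm_min", "locus_max_missing", "sample_max_missing"):
        v = cfg["qc"][key]
        if not 0 <= v <= 1:
            raise ValueError(f"qc.{key} must lie in [0, 1]")
    if not 0 < cfg["gwas"]["r_min"] <= 1:
        raise ValueError("gwas.r_min must lie in (0, 1]")
    SynthConfig(seed=cfg["seed"], **{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in cfg["synth"].items()
                                     if k != "seed"})  # raises on bad synth fields
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: dict | None, out_dir) -> dict:
    """Run the full pipeline on synthetic data; return the manifest."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"version": __version__, "config": cfg, "seed": seed,
                      "stages": {}, "summary": {}}

    def stage(name):
        manifest["stages"][name] = {"t_start": time.time(), "outputs": {}}
        return manifest["stages"][name]

    def finish(rec, **outputs):
        for key, path in outputs.items():
            rec["outputs"][key] = {"path": str(path), "sha256": _digest(Path(path))}
        rec["seconds"] = round(time.time() - rec.pop("t_start"), 3)

    # --- synth ---------------------------------------------------------
    rec = stage("synth")
    scfg = SynthConfig(seed=seed, **{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in cfg["synth"].items()})
    matrix, pheno, truth = simulate_cohort(scfg)
    genes, terms, scheme = simulate_annotation(scfg)
    write_vcf(matrix, out / "cohort.vcf")
    write_sample_table(pheno, out / "pheno.tsv")
    write_gene_table(genes, out / "genes.tsv")
    write_go_tables(terms, out / "go_map.tsv", out / "go_terms.tsv")
    write_category_scheme(scheme, out / "categories.json")
    (out / "truth.json").write_text(json.dumps(
        {k: v for k, v in truth.items() if k != "colony_alt_freq"}, indent=1))
    finish(rec, vcf=out / "cohort.vcf", pheno=out / "pheno.tsv", genes=out / "genes.tsv",
           go_map=out / "go_map.tsv", go_terms=out / "go_terms.tsv",
           categories=out / "categories.json", truth=out / "truth.json")

    # --- qc -------------------------------------------------------------
    rec = stage("qc")
    qc_matrix, qc_report = run_qc(matrix, pheno, QCConfig(seed=seed, **cfg["qc"]))
    write_vcf(qc_matrix, out / "qc.vcf")
    (out / "qc_report.json").write_text(json.dumps({
        "n_loci_in": qc_report.n_loci_in, "n_samples_in": qc_report.n_samples_in,
        "n_loci_out": qc_matrix.n_loci, "n_samples_out": qc_matrix.n_samples,
        "loci_discarded": qc_report.loci_discarded,
        "samples_discarded": qc_report.samples_discarded,
        "log": qc_report.log, "seed": qc_report.seed}, indent=1))
    finish(rec, vcf=out / "qc.vcf", report=out / "qc_report.json")
    manifest["summary"]["qc_loci_retained"] = qc_matrix.n_loci
    manifest["summary"]["qc_samples_retained"] = qc_matrix.n_samples

    # --- structure -------------------------------------------------------
    rec = stage("structure")
    scfg_s = cfg["structure"]
    kin = king_kinship(qc_matrix)
    unrelated = partition_unrelated(kin, threshold=scfg_s["kinship_threshold"])
    n_pcs = int(scfg_s["n_pcs"])
    model = pca_unrelated_project(qc_matrix, unrelated, max(cfg["gwas"]["pc_grid"] + [n_pcs]))
    adj = pc_adjusted_kinship(qc_matrix, model, n_pcs=n_pcs)
    kfac = kinship_factors(adj, n_factors=int(scfg_s["n_kinship_factors"]))
    np.savetxt(out / "pc_scores.tsv", model.scores, delimiter="\t")
    (out / "structure.json").write_text(json.dumps({
        "n_pcs": n_pcs,
        "n_unrelated": int(unrelated.sum()),
        "proportion_structure_explained": float(
            model.eigenvalues[:n_pcs].sum() / model.eigenvalues.sum()),
    }, indent=1))
    finish(rec, scores=out / "pc_scores.tsv", structure=out / "structure.json")
    manifest["summary"]["proportion_structure_explained"] = float(
        model.eigenvalues[:n_pcs].sum() / model.eigenvalues.sum())

    # --- gwas -------------------------------------------------------------
    rec = stage("gwas")
    pheno_m = pheno.set_index("sample_id").loc[qc_matrix.samples]
    flight_raw = pheno_m["flight_score"].to_numpy(dtype=float, na_value=np.nan)
    flight = np.where(np.isnan(flight_raw), np.nan, (flight_raw >= 3).astype(float))
    forewing = pheno_m["forewing_length_mm"].to_numpy(dtype=float, na_value=np.nan)

    results_fc, sel_fc = model_grid(qc_matrix, flight, model.scores, cfg["gwas"]["pc_grid"],
                                    link="binomial", kinship_covariates=kfac)
    results_fl, sel_fl = model_grid(qc_matrix, forewing, model.scores, cfg["gwas"]["pc_grid"],
                                    link="gaussian", kinship_covariates=kfac)
    assoc_fc = results_fc[sel_fc]
    assoc_fl = results_fl[sel_fl]
    assoc_fc.table.to_csv(out / "assoc_flight.tsv", sep="\t", index=False)
    assoc_fl.table.to_csv(out / "assoc_forewing.tsv", sep="\t", index=False)

    set_fc = ld_annotate(qc_matrix, assoc_fc, genes, "flight_capability",
                         r_min=cfg["gwas"]["r_min"], p_max=cfg["gwas"]["p_max"])
    set_fl = ld_annotate(qc_matrix, assoc_fl, genes, "forewing_length",
                         r_min=cfg["gwas"]["r_min"], p_max=cfg["gwas"]["p_max"])
    (out / "candidates_gwas.json").write_text(json.dumps(
        {"flight_capability": set_fc.genes, "forewing_length": set_fl.genes}, indent=1))
    finish(rec, flight=out / "assoc_flight.tsv", forewing=out / "assoc_forewing.tsv",
           candidates=out / "candidates_gwas.json")
    manifest["summary"]["flight_outliers_p05"] = int(len(assoc_fc.outliers()))
    manifest["summary"]["forewing_outliers_p05"] = int(len(assoc_fl.outliers()))
    manifest["summary"]["flight_model_gif"] = assoc_fc.gif
    manifest["summary"]["flight_model_pcs"] = cfg["gwas"]["pc_grid"][sel_fc]

    # --- inbred -----------------------------------------------------------
    rec = stage("inbred")
    imatrix, ipheno, itruth = simulate_inbred_lines(scfg)
    write_vcf(imatrix, out / "inbred.vcf")
    write_sample_table(ipheno, out / "inbred_pheno.tsv")
    iqc = inbred_qc(imatrix, InbredQCConfig(
        min_depth=cfg["inbred"]["min_depth"],
        max_heterozygosity=cfg["inbred"]["max_heterozygosity"],
        min_genotyping_rate=cfg["inbred"]["min_genotyping_rate"]))
    seg = segregating_candidates(iqc, ipheno, mode=cfg["inbred"]["mode"])
    mean_d, sd_d, n_loci, n_contigs = segregation_summary(seg)
    pd.DataFrame({"locus": seg.candidate_ids, "freq_diff": seg.freq_diff}).to_csv(
        out / "segregation.tsv", sep="\t", index=False)
    finish(rec, vcf=out / "inbred.vcf", pheno=out / "inbred_pheno.tsv",
           segregation=out / "segregation.tsv")
    manifest["summary"]["inbred_candidate_snps"] = n_loci
    manifest["summary"]["inbred_candidate_contigs"] = n_contigs
    manifest["summary"]["inbred_mean_freq_diff"] = mean_d
    manifest["summary"]["inbred_sd_freq_diff"] = sd_d

    # --- enrichment -------------------------------------------------------
    rec = stage("enrich")
    universe = {g.gene_id for g in genes if g.go_terms}
    enr_tables = {}
    clusters_rows = []
    n_sig_categories = {}
    for cset in (set_fc, set_fl):
        cands = cset.gene_ids & universe
        if not cands:
            continue
        term_rep = term_enrichment(cands, terms, universe=universe, tag=cset.tag)
        enriched_ids = set(term_rep.enriched(alpha=cfg["enrich"]["term_alpha"])["term_id"])
        enriched_terms = [t for t in terms if t.term_id in enriched_ids]
        cat_rep = category_overrepresentation(enriched_terms, terms, scheme, tag=cset.tag)
        n_sig_categories[cset.tag] = int((cat_rep.table["p_adj"]
                                          < cfg["enrich"]["category_fdr"]).sum())
        enr_tables[cset.tag] = (term_rep, cat_rep)
        if enriched_terms:
            graph = build_term_graph(enriched_terms, min_weight=cfg["enrich"]["edge_min_weight"])
            clusters = mcl_cluster(graph, inflation=cfg["enrich"]["inflation"])
            catmap = categorize_terms(enriched_terms, scheme)
            for c in describe_clusters(clusters, enriched_terms, catmap):
                clusters_rows.append({
                    "analysis": cset.tag,
                    "descriptor": " ".join(c.descriptor),
                    "n_terms": len(c.members),
                    "category_hits": c.n_category_hits,
                    "gene_support": f"{c.gene_support_range[0]}-{c.gene_support_range[1]}",
                    "well_supported": c.well_supported,
                })
    pd.concat(
        [rep[0].table.assign(analysis=tag) for tag, rep in enr_tables.items()],
        ignore_index=True).to_csv(out / "term_enrichment.tsv", sep="\t", index=False)
    pd.concat(
        [rep[1].table.assign(analysis=tag) for tag, rep in enr_tables.items()],
        ignore_index=True).to_csv(out / "category_tests.tsv", sep="\t", index=False)
    pd.DataFrame(clusters_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
    finish(rec, terms=out / "term_enrichment.tsv", categories=out / "category_tests.tsv",
           clusters=out / "clusters.tsv")
    manifest["summary"]["significant_categories"] = n_sig_categories
    manifest["summary"]["n_term_clusters"] = len(clusters_rows)

    # --- profiling ----------------------------------------------------------
    rec = stage("profile")
    have_flight = ~np.isnan(flight)
    pmatrix = qc_matrix.take_samples(have_flight)
    labels = flight[have_flight].astype(int)
    # marker panel: top flight-GWAS outliers (stand-in for the externally
    # literature-supported panel, which needs sources outside the pipeline)
    order = np.argsort(assoc_fc.table["p"].to_numpy())
    panel = [f"{qc_matrix.loci[j].contig}:{qc_matrix.loci[j].position}"
             for j in order[: cfg["profile"]["n_panel_loci"]]]
    prof = replicate_profiling(
        pmatrix, labels, panel,
        n_train_per_class=cfg["profile"]["n_train_per_class"],
        n_reps=cfg["profile"]["n_reps"], seed=seed,
        pc_grid=cfg["profile"]["pc_grid"])
    (out / "profiling.json").write_text(json.dumps({
        "mean_success": prof.mean_success, "se_success": prof.se_success,
        "chance_model": prof.chance_model, "replicates": prof.replicates,
        "panel": panel}, indent=1))
    finish(rec, profiling=out / "profiling.json")
    manifest["summary"]["profiling_mean_success"] = prof.mean_success
    manifest["summary"]["profiling_se"] = prof.se_success
    manifest["summary"]["profiling_max_binomial_p"] = max(
        r["binomial_p"] for r in prof.replicates)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
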