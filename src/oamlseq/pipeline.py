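"""End-to-end pipeline driver: simulate-or-load, filter, recurrence, CNV,
pathway enrichment, survival. Each stage logs record counts to stderr;
result tables are written atomically and a JSON manifest records the
config hash, seed and package version."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__, io
from .cnv import call_cnv, recurrence_enrichment
from .enrichment import PathwayTable, pathway_enrichment
from .filters import choose_one_sample_per_patient, filter_targeted
from .recurrence import build_matrix, gene_frequency
from .simulate import CohortConfig, generate_cohort
from .survival import compare_by_gene

logger = logging.getLogger("oamlseq.pipeline")

__all__ = ["run_pipeline"]


def _stage(name: str):
    return logging.getLogger(f"oamlseq.pipeline.{name}")


def run_pipeline(config: io.PipelineConfig) -> dict[str, Path]:
    """Run every stage and return the paths of the written results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # --- input stage: simulate or load -----------------------------------
    log = _stage("input")
    if config.simulate:
        cohort = generate_cohort(CohortConfig(seed=config.seed))
        io.write_cohort(cohort, outdir / "cohort")
        calls = cohort.calls
        patients = cohort.patients
        panel = list(cohort.config.panel_genes)
        coverage_pairs = cohort.coverage_pairs
        pathways = cohort.pathways
        pathway_universe = {m.gene for m in cohort.gene_models}
        survival_records = cohort.survival
        log.info("simulated cohort: %d patients, %d calls, %d coverage pairs",
                 len(patients), len(calls), len(coverage_pairs))
    else:
        if not config.variants:
            raise ValueError("variants path required when simulate is false")
        calls = io.read_variants(config.variants)
        patients = sorted({c.patient_id for c in calls})
        panel = sorted({c.gene for c in calls})
        coverage_pairs = [io.read_coverage(path, pid)
                          for pid, path in sorted(config.coverage.items())]
        pathways = io.read_gmt(config.pathways) if config.pathways else {}
        pathway_universe = set(panel).union(*pathways.values()) if pathways \
            else set(panel)
        survival_records = (io.read_survival(config.survival)
                            if config.survival else [])
        log.info("loaded %d calls for %d patients", len(calls), len(patients))

    # --- filter stage -----------------------------------------------------
    log = _stage("filter")
    calls = choose_one_sample_per_patient(calls)
    result = filter_targeted(calls, config.filter_config)
    log.info("targeted cascade: %d in, %d retained, %d removed",
             len(calls), len(result.retained), len(result.removed))
    written["filtered_variants"] = outdir / "variants_retained.tsv"
    io.write_variants(result.retained, written["filtered_variants"])
    written["filter_audit"] = outdir / "filter_audit.tsv"
    io.write_frame(result.audit_frame(), written["filter_audit"])

    # --- recurrence stage -------------------------------------------------
    log = _stage("recurrence")
    matrix = build_matrix(result.retained, patients, panel)
    freq = gene_frequency(matrix)
    log.info("matrix %d x %d, %d/%d patients mutated (%d%%)",
             matrix.n_patients, len(matrix.genes), matrix.n_mutated_cases,
             matrix.n_patients, matrix.mutated_percent())
    written["matrix_wide"] = outdir / "matrix_wide.tsv"
    io.atomic_write_text(written["matrix_wide"],
                         matrix.to_wide_frame().to_csv(sep="\t"))
    written["matrix_long"] = outdir / "matrix_long.tsv"
    io.write_frame(matrix.to_long_frame(), written["matrix_long"])
    written["gene_frequency"] = outdir / "gene_frequency.tsv"
    io.write_frame(freq, written["gene_frequency"])

    # --- CNV stage --------------------------------------------------------
    log = _stage("cnv")
    if len(coverage_pairs) >= 2:
        callsets = [call_cnv(p, config.gain_thresh, config.loss_thresh)
                    for p in coverage_pairs]
        cnv_results = recurrence_enrichment(callsets)
        log.info("%d pairs, %d genes, %d significant",
                 len(callsets), len(cnv_results),
                 int(cnv_results["significant"].sum()))
        written["cnv_results"] = outdir / "cnv_results.tsv"
        io.write_frame(cnv_results, written["cnv_results"])
    else:
        log.info("skipped (%d coverage pairs)", len(coverage_pairs))

    # --- pathway enrichment stage ----------------------------------------
    log = _stage("enrich")
    if pathways:
        table = PathwayTable.from_dict(pathways, universe=pathway_universe)
        affected = set(freq.loc[freq["n_mutated"] > 0, "gene"])
        enr = pathway_enrichment(affected, table,
                                 adjust=config.enrichment_adjust)
        log.info("%d pathways, %d affected genes", len(enr), len(affected))
        written["pathway_enrichment"] = outdir / "pathway_enrichment.tsv"
        io.write_frame(enr, written["pathway_enrichment"])
    else:
        log.info("skipped (no pathway table)")

    # --- survival stage ---------------------------------------------------
    log = _stage("survival")
    if survival_records and config.survival_gene in matrix.genes:
        try:
            cmp = compare_by_gene(matrix, survival_records,
                                  config.survival_gene, config.endpoint)
        except ValueError as exc:
            log.info("skipped: %s", exc)
        else:
            log.info("%s %s: chi2=%.3f p=%.4g (n=%d vs %d)",
                     cmp.gene, cmp.endpoint, cmp.result.chi_square,
                     cmp.result.p_value, cmp.result.n_a, cmp.result.n_b)
            for label, curve in cmp.curves.items():
                key = f"km_{label}"
                written[key] = outdir / f"km_{cmp.gene}_{label}.tsv"
                io.write_frame(curve, written[key])
            written["survival_test"] = outdir / "survival_test.json"
            io.atomic_write_text(written["survival_test"], json.dumps({
                "gene": cmp.gene, "endpoint": cmp.endpoint,
                "chi_square": cmp.result.chi_square,
                "p_value": cmp.result.p_value,
                "n_mutant": cmp.result.n_a, "n_wildtype": cmp.result.n_b,
                "median_mutant": cmp.medians["mutant"],
                "median_wildtype": cmp.medians["wildtype"],
                "n_excluded": cmp.n_excluded,
            }, indent=2))
    else:
        log.info("skipped (no survival records or gene not in panel)")

    # --- manifest ---------------------------------------------------------
    written["manifest"] = outdir / "manifest.json"
    io.atomic_write_text(written["manifest"], json.dumps({
        "package": "oamlseq", "version": __version__,
        "seed": config.seed, "config_hash": config.config_hash(),
        "outputs": sorted(str(p.name) for p in written.values()),
    }, indent=2, sort_keys=True))
    return written
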