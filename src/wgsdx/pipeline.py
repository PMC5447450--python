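"""End-to-end orchestration over an on-disk cohort directory.

Stage order: small-variant prioritization -> CNV/SV filtering, annotation and
classification -> CMA concordance -> secondary-findings screen -> cohort
statistics. Per-stage record counts go to the log so every filter is
auditable; all outputs are plain TSV/JSON and deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import io as wio
from .cnv import (
    annotate_cnv_frequency,
    annotate_gene_exon_overlap,
    breakpoint_concordance,
    classify_cnv,
    dataset_frequencies,
    filter_for_concordance,
    filter_read_depth_segments,
    filter_sv_events,
    match_cma_wgs,
    merge_fragmented_segments,
)
from .models import CnvRecord, DiagnosisRecord, ThresholdConfig
from .prioritize import count_rare_damaging, rank_candidates
from .secondary import load_default_panel, screen_secondary
from .stats import binomial_ci, diagnostic_yield, multi_diagnosis_count, two_proportion_chisq

log = logging.getLogger("wgsdx")

ALL_STAGES = ("prioritize", "cnv", "secondary", "stats")


def run_pipeline(
    cohort_dir,
    outdir,
    thresholds: Optional[ThresholdConfig] = None,
    stages: Sequence[str] = ALL_STAGES,
) -> dict:
    cfg = thresholds or ThresholdConfig()
    cohort_dir, outdir = Path(cohort_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res_dir = cohort_dir / "resources"

    disease_genes = wio.read_disease_genes(res_dir / "disease_genes.tsv")
    gene_models = wio.read_gene_models(res_dir / "genes.tsv")
    segdup = wio.read_bed(res_dir / "segdup.bed")
    syndromic = [
        (r.chrom, int(r.start), int(r.end), r.state)
        for r in pd.read_csv(res_dir / "syndromic.tsv", sep="\t", dtype=str).itertuples()
    ]
    controls_df = pd.read_csv(res_dir / "controls.tsv", sep="\t", dtype=str)
    controls: Dict[str, List[CnvRecord]] = defaultdict(list)
    for r in controls_df.itertuples():
        controls[r.sample].append(
            CnvRecord(case_id=r.sample, chrom=r.chrom, start=int(r.start), end=int(r.end),
                      state=r.state, source="read_depth")
        )
    dgv = [
        CnvRecord(case_id="DGV", chrom=r.chrom, start=int(r.start), end=int(r.end),
                  state=r.state, source="read_depth")
        for r in pd.read_csv(res_dir / "dgv.tsv", sep="\t", dtype=str).itertuples()
    ]
    ontology = wio.read_ontology(res_dir / "ontology.tsv")
    cases = wio.read_cohort(cohort_dir / "cohort.tsv")
    panel = load_default_panel()

    summary: dict = {"cohort_n": len(cases), "stages": list(stages)}
    candidate_rows: List[dict] = []
    cnv_rows: List[dict] = []
    secondary_rows: List[dict] = []
    diagnoses: List[DiagnosisRecord] = []
    secondary_findings = []
    all_read_depth: List[CnvRecord] = []
    all_cma = []

    for case in cases:
        cdir = cohort_dir / "cases" / case.case_id
        data = wio.read_case_dir(cdir, disease_genes)
        variants = data["variants"]
        log.info("%s: %d small variants read", case.case_id, len(variants))

        if "prioritize" in stages:
            candidates = rank_candidates(variants, case.sex, case.hpo_terms, ontology, cfg)
            log.info("%s: %d candidates (%d diagnostic), %d rare damaging",
                     case.case_id, len(candidates),
                     sum(c.is_diagnostic for c in candidates),
                     count_rare_damaging(variants, cfg))
            for c in candidates:
                candidate_rows.append(
                    {
                        "case_id": c.case_id, "gene": c.gene or ".",
                        "variants": ";".join(f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}" for v in c.variants),
                        "moi_model": c.moi_model, "acmg_class": c.acmg_class,
                        "quality_tier": c.tiers.quality_tier, "frequency_tier": c.tiers.frequency_tier,
                        "impact_tier": c.tiers.impact_tier, "disease_tier": c.tiers.disease_tier,
                        "phenotype_match": round(c.phenotype_match, 4), "rank": c.rank,
                    }
                )
                if c.is_diagnostic:
                    diagnoses.append(
                        DiagnosisRecord(case_id=c.case_id, locus_ids={c.gene or "unknown"},
                                        variant_types={"SNV"},
                                        moi="AR" if c.moi_model.startswith("AR") else "AD")
                    )

        if "cnv" in stages:
            read_depth = filter_read_depth_segments(data["cnv_segments"], cfg)
            merged = merge_fragmented_segments(read_depth, cfg.merge_gap_max)
            svs = filter_sv_events(data["sv_events"], cfg)
            log.info("%s: CNV %d raw -> %d kept -> %d merged; SV %d raw -> %d kept",
                     case.case_id, len(data["cnv_segments"]), len(read_depth), len(merged),
                     len(data["sv_events"]), len(svs))
            annotated = annotate_cnv_frequency(merged + svs, controls, dgv, cfg)
            annotated = annotate_gene_exon_overlap(annotated, gene_models)
            for rec in annotated:
                cls = classify_cnv(rec, syndromic, disease_genes, (), cfg)
                cnv_rows.append(
                    {
                        "case_id": rec.case_id, "chrom": rec.chrom, "start": rec.start,
                        "end": rec.end, "state": rec.state, "source": rec.source,
                        "control_freq": round(rec.control_freq, 4), "dgv_overlap": int(rec.dgv_overlap),
                        "genes_hit": ",".join(sorted(rec.genes_hit)) or ".",
                        "exons_hit": int(rec.exons_hit), "classification": cls,
                    }
                )
                if rec.source == "read_depth":
                    all_read_depth.append(rec)
                if cls == "pathogenic":
                    diagnoses.append(
                        DiagnosisRecord(case_id=rec.case_id,
                                        locus_ids={f"{rec.chrom}:{rec.start}-{rec.end}"},
                                        variant_types={"CNV"})
                    )
            all_cma.extend(data["cma_calls"])

        if "secondary" in stages:
            findings = screen_secondary(variants, panel, case.consent_secondary)
            secondary_findings.extend(findings)
            for f in findings:
                secondary_rows.append(
                    {"case_id": f.case_id, "gene": f.gene, "basis": f.basis,
                     "variant": f"{f.variant.chrom}:{f.variant.pos}:{f.variant.ref}>{f.variant.alt}",
                     "returnable": int(f.returnable)}
                )

    if "prioritize" in stages:
        pd.DataFrame(candidate_rows).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    if "cnv" in stages:
        pd.DataFrame(cnv_rows).to_csv(outdir / "cnv_annotated.tsv", sep="\t", index=False)
        wgs_freq = dataset_frequencies(all_read_depth, len(cases), cfg)
        cma_records = [
            CnvRecord(case_id=c.case_id, chrom=c.chrom, start=c.outer_start, end=c.outer_end,
                      state=c.state, source="microarray")
            for c in all_cma
        ]
        cma_freq = dataset_frequencies(cma_records, len(cases), cfg)
        wgs_kept = filter_for_concordance(all_read_depth, segdup, wgs_freq, cfg)
        cma_kept_keys = {
            r.key for r in filter_for_concordance(cma_records, segdup, cma_freq, cfg)
        }
        cma_kept = [
            c for c, r in zip(all_cma, cma_records) if r.key in cma_kept_keys
        ]
        result = breakpoint_concordance(match_cma_wgs(cma_kept, wgs_kept, cfg), cfg)
        summary["concordance"] = {
            "cma_rare": result.n_cma,
            "detected": len(result.matched_pairs),
            "detected_rate": round(result.detected_rate, 4),
            "within_boundary_rate": round(result.within_boundary_rate, 4),
            "within_window_rate": round(result.within_window_rate, 4),
        }
        with open(outdir / "concordance.json", "w") as fh:
            json.dump(summary["concordance"], fh, indent=2, sort_keys=True)
    if "secondary" in stages:
        pd.DataFrame(secondary_rows).to_csv(outdir / "secondary.tsv", sep="\t", index=False)

    if "stats" in stages:
        n = len(cases)
        count, prop = diagnostic_yield(diagnoses, n)
        lo, hi = binomial_ci(count, n)
        cnv_only_cases = {d.case_id for d in diagnoses if d.variant_types == {"CNV"}} - {
            d.case_id for d in diagnoses if d.variant_types == {"SNV"}
        }
        comparison = two_proportion_chisq(count, n, len(cnv_only_cases), n)
        multi_count, multi_frac = multi_diagnosis_count(diagnoses, n)
        summary["yield"] = {
            "diagnosed": count, "cohort_n": n, "rate": round(prop, 4),
            "ci95": [round(lo, 4), round(hi, 4)],
        }
        summary["chi2_vs_cnv_only"] = {
            "chi2": round(comparison.chi2, 4), "p": comparison.p,
            "x1": comparison.x1, "x2": comparison.x2,
        }
        summary["multi_locus"] = {"count": multi_count, "fraction": round(multi_frac, 4)}
        summary["secondary"] = {
            "findings": len(secondary_findings),
            "returnable": sum(f.returnable for f in secondary_findings),
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
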