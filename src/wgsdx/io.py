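"""Readers and writers for every interchange format the pipeline touches.

Readers reject malformed input with the offending line/locus rather than
silently coercing; every writer produces files its paired reader accepts.
BED and all interval TSVs are 0-based half-open; VCF positions are 1-based.
"""

from __future__ import annotations

import math
import os
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .models import (
    AnnotationBundle,
    Case,
    CmaCall,
    CnvRecord,
    DiseaseGeneEntry,
    GeneModel,
    GenePanelEntry,
    SequenceVariant,
    SvEvent,
    ThresholdConfig,
)
from .ontology import Ontology
from .simulate import CaseBundle, Resources, SimulationConfig, manifest_dict

__all__ = [
    "MalformedInputError",
    "read_vcf",
    "write_vcf",
    "read_annotations",
    "write_annotations",
    "attach_annotations",
    "read_bed",
    "write_bed",
    "read_cnv_segments",
    "write_cnv_segments",
    "read_sv_events",
    "write_sv_events",
    "read_cma_calls",
    "write_cma_calls",
    "read_panel",
    "read_gene_models",
    "write_gene_models",
    "read_disease_genes",
    "write_disease_genes",
    "read_cohort",
    "write_cohort_table",
    "read_ontology",
    "write_ontology",
    "load_threshold_config",
    "write_cohort_dir",
    "read_case_dir",
]


class MalformedInputError(ValueError):
    def __init__(self, path, line: Optional[int], msg: str):
        where = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{where}: {msg}")
        self.path, self.line = path, line


# --------------------------------------------------------------------------
# VCF

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">
"""


def write_vcf(variants: Sequence[SequenceVariant], path, case_id: Optional[str] = None, contigs: Optional[Mapping[str, int]] = None) -> None:
    """Write a single-sample VCF 4.2 (uncompressed text)."""
    if case_id is None:
        if not variants:
            raise ValueError("case_id required for an empty variant set")
        case_id = variants[0].case_id
    gt = {"het": "0/1", "hom": "1/1", "hemizygous": "1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contigs:
            for c, ln in contigs.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in sorted({v.chrom for v in variants}):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + case_id + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:DP:GQ:AF\t"
                f"{gt[v.zygosity]}:{v.read_depth}:{int(round(v.genotype_quality))}:{v.allele_fraction:.4f}\n"
            )


def read_vcf(path) -> List[SequenceVariant]:
    """Read a single-sample VCF into variant records.

    Genotypes map 0/1 -> het, 1/1 -> hom, haploid calls on sex chromosomes
    -> hemizygous. Multi-allelic records are split into one variant per
    called alternate allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise MalformedInputError(path, None, f"expected 1 sample, found {len(vcf.samples)}")
    case_id = vcf.samples[0]
    out: List[SequenceVariant] = []
    for rec in vcf:
        if not rec.genotypes:
            raise MalformedInputError(path, None, f"missing genotype at {rec.CHROM}:{rec.POS}")
        geno = rec.genotypes[0]
        alleles = [a for a in geno[:-1] if a is not None and a >= 0]
        if not alleles:
            raise MalformedInputError(path, None, f"missing genotype at {rec.CHROM}:{rec.POS}")
        def fmt(field):
            try:
                return rec.format(field)
            except KeyError:
                return None

        dp, gq, af = fmt("DP"), fmt("GQ"), fmt("AF")
        depth = int(dp[0][0]) if dp is not None else 0
        quality = float(gq[0][0]) if gq is not None else 0.0
        frac = float(af[0][0]) if af is not None else 0.0
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            count = alleles.count(alt_idx)
            if count == 0:
                continue
            if len(alleles) == 1:
                zyg = "hemizygous" if rec.CHROM in {"X", "Y", "chrX", "chrY"} else "hom"
            elif count == len(alleles):
                zyg = "hom"
            else:
                zyg = "het"
            out.append(
                SequenceVariant(
                    case_id=case_id, chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                    zygosity=zyg, read_depth=depth, genotype_quality=quality,
                    allele_fraction=frac,
                )
            )
    return out


# --------------------------------------------------------------------------
# annotation table

_ANN_COLS = [
    "chrom", "pos", "ref", "alt", "gene", "effect_class", "pop_freqs", "conservation",
    "damaging_predictors", "predictor_total", "splice_delta", "assertions", "mouse_phenotype",
]


def _ser_map(m: Mapping) -> str:
    return ";".join(f"{k}={v}" for k, v in sorted(m.items())) if m else "."


def _parse_map(s: str, cast=float) -> dict:
    if s in (".", "", None) or (isinstance(s, float) and math.isnan(s)):
        return {}
    return {k: cast(v) for k, v in (item.split("=", 1) for item in s.split(";"))}


def write_annotations(variants: Sequence[SequenceVariant], path) -> None:
    rows = []
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
        a = v.annotation
        if a is None:
            continue
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": a.gene or ".",
                "effect_class": a.effect_class,
                "pop_freqs": _ser_map({k: f"{f:.6g}" for k, f in a.pop_freqs.items()}),
                "conservation": _ser_map({k: f"{f:.4g}" for k, f in a.conservation_scores.items()}),
                "damaging_predictors": a.damaging_predictor_count,
                "predictor_total": a.predictor_total,
                "splice_delta": "." if a.splice_delta is None else f"{a.splice_delta:.4g}",
                "assertions": _ser_map(a.assertions),
                "mouse_phenotype": int(a.mouse_phenotype_flag),
            }
        )
    pd.DataFrame(rows, columns=_ANN_COLS).to_csv(path, sep="\t", index=False)


def read_annotations(path, disease_genes: Optional[Mapping[str, DiseaseGeneEntry]] = None) -> Dict[tuple, AnnotationBundle]:
    """Annotation bundles keyed by (chrom, pos, ref, alt); disease-gene and
    panel context is joined in from the resource table when provided."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_ANN_COLS) - set(df.columns)
    if missing:
        raise MalformedInputError(path, None, f"missing columns: {sorted(missing)}")
    disease_genes = disease_genes or {}
    out: Dict[tuple, AnnotationBundle] = {}
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            gene = None if r.gene == "." else r.gene
            out[(r.chrom, int(r.pos), r.ref, r.alt)] = AnnotationBundle(
                gene=gene,
                effect_class=r.effect_class,
                pop_freqs=_parse_map(r.pop_freqs),
                conservation_scores=_parse_map(r.conservation),
                damaging_predictor_count=int(r.damaging_predictors),
                predictor_total=int(r.predictor_total),
                splice_delta=None if r.splice_delta == "." else float(r.splice_delta),
                assertions=_parse_map(r.assertions, cast=str),
                disease_gene=disease_genes.get(gene),
                mouse_phenotype_flag=bool(int(r.mouse_phenotype)),
            )
        except (ValueError, KeyError) as exc:
            raise MalformedInputError(path, i, str(exc)) from exc
    return out


def attach_annotations(
    variants: Sequence[SequenceVariant], table: Mapping[tuple, AnnotationBundle]
) -> List[SequenceVariant]:
    out = []
    for v in variants:
        ann = table.get((v.chrom, v.pos, v.ref, v.alt))
        if ann is not None:
            v.annotation = ann
        out.append(v)
    return out


# --------------------------------------------------------------------------
# intervals / tracks


def read_bed(path) -> List[Tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedInputError(path, i, f"expected >=3 BED columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise MalformedInputError(path, i, str(exc)) from exc
            if start >= end:
                raise MalformedInputError(path, i, f"empty interval [{start},{end})")
            out.append((parts[0], start, end))
    return out


def write_bed(intervals: Iterable[Tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for c, s, e in sorted(intervals):
            fh.write(f"{c}\t{s}\t{e}\n")


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise MalformedInputError(path, None, f"missing columns: {sorted(missing)}")
    return df


def read_cnv_segments(path) -> List[Tuple[CnvRecord, bool]]:
    """Read-depth segments as (record, hypervariable) pairs."""
    df = _read_tsv(path, ["case_id", "chrom", "start", "end", "copy_state", "hypervariable"])
    out = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            cs = int(r.copy_state)
            rec = CnvRecord(
                case_id=r.case_id, chrom=r.chrom, start=int(r.start), end=int(r.end),
                state="gain" if cs > 2 else "loss", source="read_depth", copy_state=cs,
            )
            out.append((rec, bool(int(r.hypervariable))))
        except ValueError as exc:
            raise MalformedInputError(path, i, str(exc)) from exc
    return out


def write_cnv_segments(rows: Sequence[Tuple[CnvRecord, bool]], path) -> None:
    pd.DataFrame(
        [
            {"case_id": r.case_id, "chrom": r.chrom, "start": r.start, "end": r.end,
             "copy_state": r.copy_state, "hypervariable": int(h)}
            for r, h in rows
        ],
        columns=["case_id", "chrom", "start", "end", "copy_state", "hypervariable"],
    ).to_csv(path, sep="\t", index=False)


def read_sv_events(path) -> List[SvEvent]:
    df = _read_tsv(path, ["case_id", "type", "chrom", "start", "end", "support"])
    out = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            out.append(SvEvent(case_id=r.case_id, type=r.type, chrom=r.chrom,
                               start=int(r.start), end=int(r.end), support=int(r.support)))
        except ValueError as exc:
            raise MalformedInputError(path, i, str(exc)) from exc
    return out


def write_sv_events(events: Sequence[SvEvent], path) -> None:
    pd.DataFrame(
        [{"case_id": e.case_id, "type": e.type, "chrom": e.chrom, "start": e.start,
          "end": e.end, "support": e.support} for e in events],
        columns=["case_id", "type", "chrom", "start", "end", "support"],
    ).to_csv(path, sep="\t", index=False)


def read_cma_calls(path) -> List[CmaCall]:
    df = _read_tsv(path, ["case_id", "chrom", "outer_start", "inner_start", "inner_end",
                          "outer_end", "state", "classification"])
    out = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            out.append(
                CmaCall(case_id=r.case_id, chrom=r.chrom,
                        inner_start=int(r.inner_start), inner_end=int(r.inner_end),
                        outer_start=int(r.outer_start), outer_end=int(r.outer_end),
                        state=r.state, classification=r.classification)
            )
        except ValueError as exc:
            raise MalformedInputError(path, i, str(exc)) from exc
    return out


def write_cma_calls(calls: Sequence[CmaCall], path) -> None:
    pd.DataFrame(
        [{"case_id": c.case_id, "chrom": c.chrom, "outer_start": c.outer_start,
          "inner_start": c.inner_start, "inner_end": c.inner_end, "outer_end": c.outer_end,
          "state": c.state, "classification": c.classification} for c in calls],
        columns=["case_id", "chrom", "outer_start", "inner_start", "inner_end", "outer_end",
                 "state", "classification"],
    ).to_csv(path, sep="\t", index=False)


def read_panel(path) -> List[GenePanelEntry]:
    df = _read_tsv(path, ["gene", "inheritance", "condition"])
    return [GenePanelEntry(gene=r.gene, inheritance=r.inheritance, condition=r.condition)
            for r in df.itertuples()]


def read_gene_models(path) -> List[GeneModel]:
    df = _read_tsv(path, ["gene", "chrom", "start", "end", "exons"])
    out = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            exons = tuple(
                tuple(int(x) for x in part.split("-")) for part in r.exons.split(",") if part
            )
            out.append(GeneModel(gene=r.gene, chrom=r.chrom, start=int(r.start), end=int(r.end), exons=exons))
        except ValueError as exc:
            raise MalformedInputError(path, i, str(exc)) from exc
    return out


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        [{"gene": g.gene, "chrom": g.chrom, "start": g.start, "end": g.end,
          "exons": ",".join(f"{s}-{e}" for s, e in g.exons)} for g in genes],
        columns=["gene", "chrom", "start", "end", "exons"],
    ).to_csv(path, sep="\t", index=False)


def read_disease_genes(path) -> Dict[str, DiseaseGeneEntry]:
    df = _read_tsv(path, ["gene", "inheritance_modes", "condition", "phenotype_terms", "lof_mechanism"])
    out = {}
    for r in df.itertuples():
        terms = frozenset() if r.phenotype_terms in (".", "") else frozenset(r.phenotype_terms.split(","))
        out[r.gene] = DiseaseGeneEntry(
            gene=r.gene,
            inheritance_modes=frozenset(r.inheritance_modes.split(",")),
            condition=r.condition,
            phenotype_terms=terms,
            lof_mechanism=bool(int(r.lof_mechanism)),
        )
    return out


def write_disease_genes(entries: Mapping[str, DiseaseGeneEntry], path) -> None:
    pd.DataFrame(
        [{"gene": e.gene, "inheritance_modes": ",".join(sorted(e.inheritance_modes)),
          "condition": e.condition,
          "phenotype_terms": ",".join(sorted(e.phenotype_terms)) or ".",
          "lof_mechanism": int(e.lof_mechanism)} for e in entries.values()],
        columns=["gene", "inheritance_modes", "condition", "phenotype_terms", "lof_mechanism"],
    ).to_csv(path, sep="\t", index=False)


def read_cohort(path) -> List[Case]:
    df = _read_tsv(path, ["case_id", "sex", "age", "hpo_terms", "consent_secondary", "consanguinity"])
    out = []
    for r in df.itertuples():
        terms = frozenset() if r.hpo_terms in (".", "") else frozenset(r.hpo_terms.split(","))
        out.append(Case(case_id=r.case_id, sex=r.sex, age=float(r.age), hpo_terms=terms,
                        consent_secondary=bool(int(r.consent_secondary)),
                        consanguinity=bool(int(r.consanguinity))))
    return out


def write_cohort_table(cases: Sequence[Case], path) -> None:
    pd.DataFrame(
        [{"case_id": c.case_id, "sex": c.sex, "age": c.age,
          "hpo_terms": ",".join(sorted(c.hpo_terms)) or ".",
          "consent_secondary": int(c.consent_secondary),
          "consanguinity": int(c.consanguinity)} for c in cases],
        columns=["case_id", "sex", "age", "hpo_terms", "consent_secondary", "consanguinity"],
    ).to_csv(path, sep="\t", index=False)


def read_ontology(path) -> Ontology:
    df = _read_tsv(path, ["term", "parents"])
    parents = {}
    for r in df.itertuples():
        parents[r.term] = [] if r.parents in (".", "") else r.parents.split(",")
    return Ontology(parents)


def write_ontology(ontology: Ontology, path) -> None:
    rows = []
    for term in sorted(ontology.terms):
        if term == ontology.root:
            continue
        rows.append({"term": term, "parents": ",".join(sorted(ontology.parents(term))) or "."})
    pd.DataFrame(rows, columns=["term", "parents"]).to_csv(path, sep="\t", index=False)


def load_threshold_config(path) -> ThresholdConfig:
    """YAML mirroring ThresholdConfig; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = set(ThresholdConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise MalformedInputError(path, None, f"unknown config keys: {sorted(unknown)}")
    if "het_af_band" in data:
        data["het_af_band"] = tuple(data["het_af_band"])
    return ThresholdConfig(**data)


# --------------------------------------------------------------------------
# cohort directory layout


def write_cohort_dir(outdir, cfg: SimulationConfig, resources: Resources, bundles: Sequence[CaseBundle]) -> None:
    """Materialise a generated cohort into the on-disk layout the CLI reads."""
    outdir = Path(outdir)
    res = outdir / "resources"
    res.mkdir(parents=True, exist_ok=True)
    write_gene_models(resources.genes, res / "genes.tsv")
    write_disease_genes(resources.disease_genes, res / "disease_genes.tsv")
    write_bed(resources.segdup, res / "segdup.bed")
    write_bed(resources.hypervariable, res / "hypervariable.bed")
    pd.DataFrame(
        [{"chrom": c, "start": s, "end": e, "state": st} for c, s, e, st in resources.syndromic_regions],
        columns=["chrom", "start", "end", "state"],
    ).to_csv(res / "syndromic.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sample": sample, "chrom": r.chrom, "start": r.start, "end": r.end, "state": r.state}
         for sample, recs in sorted(resources.control_cnvs.items()) for r in recs],
        columns=["sample", "chrom", "start", "end", "state"],
    ).to_csv(res / "controls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end, "state": r.state} for r in resources.dgv_like],
        columns=["chrom", "start", "end", "state"],
    ).to_csv(res / "dgv.tsv", sep="\t", index=False)
    write_ontology(resources.ontology, res / "ontology.tsv")

    for b in bundles:
        cdir = outdir / "cases" / b.case.case_id
        cdir.mkdir(parents=True, exist_ok=True)
        write_vcf(b.variants, cdir / "variants.vcf", case_id=b.case.case_id, contigs=resources.genome)
        write_annotations(b.variants, cdir / "annotations.tsv")
        write_cnv_segments(b.cnv_segments, cdir / "cnv_segments.tsv")
        write_sv_events(b.sv_events, cdir / "sv_events.tsv")
        write_cma_calls(b.cma_calls, cdir / "cma_calls.tsv")

    write_cohort_table([b.case for b in bundles], outdir / "cohort.tsv")
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest_dict(cfg, bundles), fh, sort_keys=True)


def read_case_dir(case_dir, disease_genes: Optional[Mapping[str, DiseaseGeneEntry]] = None) -> dict:
    """Read one case directory back into domain records."""
    case_dir = Path(case_dir)
    variants = read_vcf(case_dir / "variants.vcf")
    table = read_annotations(case_dir / "annotations.tsv", disease_genes)
    return {
        "variants": attach_annotations(variants, table),
        "cnv_segments": read_cnv_segments(case_dir / "cnv_segments.tsv"),
        "sv_events": read_sv_events(case_dir / "sv_events.tsv"),
        "cma_calls": read_cma_calls(case_dir / "cma_calls.tsv"),
    }
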