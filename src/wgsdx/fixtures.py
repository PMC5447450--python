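"""Loaders for the packaged worked-example tables.

The TSVs under ``wgsdx/data`` transcribe the published diagnosis and
secondary-finding tables of the study this pipeline models; the loaders turn
them into domain records for the worked-example tests and the acceptance
report. The 100-case cohort itself is not public, so :func:`cohort_fixture`
reconstructs a cohort skeleton around the published case identifiers and
subgroup sizes.
"""

from __future__ import annotations

from importlib.resources import files
from typing import Dict, List, Tuple

import pandas as pd

from .models import (
    AnnotationBundle,
    Case,
    DiagnosisRecord,
    GenePanelEntry,
    SequenceVariant,
)
from .ontology import DD_TERM, build_mini_hpo

__all__ = [
    "load_cnv_diagnoses",
    "load_snv_diagnoses",
    "load_secondary_table",
    "load_panel_table",
    "cohort_fixture",
    "secondary_screen_fixture",
    "COHORT_N",
]

COHORT_N = 100


def _data(name: str) -> pd.DataFrame:
    return pd.read_csv(
        files("wgsdx.data").joinpath(name), sep="\t", dtype=str, keep_default_na=False
    )


def load_cnv_diagnoses() -> List[DiagnosisRecord]:
    df = _data("cnv_diagnoses.tsv")
    return [
        DiagnosisRecord(
            case_id=r.case_id,
            locus_ids={r.locus_id},
            variant_types={"CNV"},
            moi="AD",
            origin=r.origin,
            category=int(r.category),
        )
        for r in df.itertuples()
    ]


def load_snv_diagnoses() -> List[DiagnosisRecord]:
    df = _data("snv_diagnoses.tsv")
    return [
        DiagnosisRecord(
            case_id=r.case_id,
            locus_ids={r.locus_id},
            variant_types={"SNV"},
            moi=r.moi if r.moi in {"AD", "AR"} else "both",
            origin=r.origin,
            category=int(r.category),
        )
        for r in df.itertuples()
    ]


def load_secondary_table() -> pd.DataFrame:
    return _data("secondary_findings.tsv")


def load_panel_table() -> List[GenePanelEntry]:
    df = _data("acmg56_panel.tsv")
    return [GenePanelEntry(gene=r.gene, inheritance=r.inheritance, condition=r.condition) for r in df.itertuples()]


def cohort_fixture() -> Tuple[List[Case], List[DiagnosisRecord]]:
    """A 100-case cohort skeleton consistent with the published subgroup sizes.

    Diagnosed case identifiers come from the transcribed tables; filler
    identifiers complete the cohort. Developmental-delay phenotype labels are
    assigned deterministically so that 57 cases carry the subgroup term and
    exactly 22 of them are diagnosed (the published 22/57 subgroup). Half of
    the labelled cases carry a child term rather than the subgroup term
    itself, exercising ancestor closure.
    """
    diagnoses = load_cnv_diagnoses() + load_snv_diagnoses()
    diagnosed = sorted({d.case_id for d in diagnoses})
    known_sex: Dict[str, str] = {}
    for name in ("cnv_diagnoses.tsv", "snv_diagnoses.tsv", "secondary_findings.tsv"):
        for r in _data(name).itertuples():
            known_sex[r.case_id] = r.sex
    all_ids = sorted(set(diagnosed) | set(known_sex))
    filler = [f"9{i:03d}" for i in range(1, COHORT_N - len(all_ids) + 1)]
    cohort_ids = all_ids + filler
    assert len(cohort_ids) == COHORT_N

    undiagnosed = [c for c in cohort_ids if c not in set(diagnosed)]
    dd_ids = set(diagnosed[:22]) | set(sorted(undiagnosed)[:35])
    child_of_dd = "HP:0012758"  # exercises closure onto the subgroup term
    cases = []
    for i, cid in enumerate(cohort_ids):
        terms = set()
        if cid in dd_ids:
            terms.add(DD_TERM if i % 2 == 0 else child_of_dd)
        cases.append(Case(case_id=cid, sex=known_sex.get(cid, "F"), hpo_terms=terms))
    return cases, diagnoses


# --------------------------------------------------------------------------
# secondary-screen fixture: the 7 published actionable variants plus decoys


def _variant(case_id: str, chrom: str, pos: int, gene: str, effect: str, assertions: dict) -> SequenceVariant:
    return SequenceVariant(
        case_id=case_id,
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="G",
        zygosity="het",
        read_depth=50,
        genotype_quality=60,
        allele_fraction=0.5,
        annotation=AnnotationBundle(
            gene=gene,
            effect_class=effect,
            pop_freqs={"db1": 0.0001},
            assertions=assertions,
        ),
    )


def secondary_screen_fixture() -> Tuple[List[SequenceVariant], List[GenePanelEntry]]:
    """The published actionable-variant records plus 24 decoys.

    Decoys fail exactly one criterion each: panel membership, impact class,
    or assertion status (including benign-asserted panel-gene variants).
    """
    table = load_secondary_table()
    variants = [
        _variant(r.case_id, "17", 1000 + i, r.gene, "missense", {"clinvar_like": "pathogenic"})
        for i, r in enumerate(table.itertuples())
    ]
    decoys: List[SequenceVariant] = []
    # LoF or asserted-pathogenic in NON-panel genes (would qualify on impact alone)
    for i, gene in enumerate(["TTN", "OBSCN", "MUC16", "NEB", "PLEC", "AHNAK", "SYNE1", "FLG"]):
        effect = "nonsense" if i % 2 == 0 else "missense"
        asserts = {} if i % 2 == 0 else {"clinvar_like": "pathogenic"}
        decoys.append(_variant(f"9{i:03d}", "2", 5000 + i, gene, effect, asserts))
    # panel genes, but non-LoF and unasserted
    for i, gene in enumerate(["BRCA1", "TP53", "MYH7", "LDLR", "RYR1", "KCNQ1", "PKP2", "APC"]):
        decoys.append(_variant(f"9{i + 10:03d}", "13", 6000 + i, gene, "missense", {}))
    # panel genes with benign or VUS assertions, non-LoF
    for i, (gene, cls) in enumerate(
        [("BRCA2", "benign"), ("MSH2", "benign"), ("FBN1", "VUS"), ("SCN5A", "benign"),
         ("DSG2", "VUS"), ("COL3A1", "benign"), ("KCNH2", "VUS"), ("RET", "benign")]
    ):
        decoys.append(_variant(f"9{i + 20:03d}", "7", 7000 + i, gene, "missense", {"clinvar_like": cls}))
    return variants + decoys, load_panel_table()
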