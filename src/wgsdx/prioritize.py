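"""Tiered filtering and ranking of small variants under inheritance models.

The stages mirror the six prioritization criteria: (i) call quality,
(ii) allele frequency, (iii) predicted impact/conservation, (iv) disease-gene
and mouse-phenotype association, (v) zygosity vs. gene mode of inheritance,
and (vi) reported pathogenicity assertions. Candidates are classified with a
deliberately small, documented rule table (not the full 28-criterion ACMG
framework) and ranked deterministically.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .models import (
    EXONIC_EFFECTS,
    LOF_EFFECTS,
    AnnotationBundle,
    CandidateDiagnosis,
    DiseaseGeneEntry,
    SequenceVariant,
    ThresholdConfig,
    TierAssignment,
)
from .ontology import Ontology, phenotype_match_score

__all__ = [
    "MissingAnnotationError",
    "filter_rare_functional",
    "assign_tiers",
    "assign_inheritance_category",
    "classify_reported_pathogenicity",
    "acmg_classify_simplified",
    "phenotype_match_score",
    "rank_candidates",
    "count_rare_damaging",
]


class MissingAnnotationError(ValueError):
    def __init__(self, variant: SequenceVariant):
        super().__init__(f"variant {variant} carries no annotation bundle")
        self.variant = variant


def _require_annotation(variant: SequenceVariant) -> AnnotationBundle:
    if variant.annotation is None:
        raise MissingAnnotationError(variant)
    return variant.annotation


def _splice_damaging(ann: AnnotationBundle, cfg: ThresholdConfig) -> bool:
    return ann.splice_delta is not None and abs(ann.splice_delta) >= cfg.splice_delta_min


def filter_rare_functional(
    variants: Sequence[SequenceVariant], cfg: Optional[ThresholdConfig] = None
) -> List[SequenceVariant]:
    """Keep high-level-rare variants that are exonic or predicted to impact splicing.

    Rarity is the maximum allele frequency across all configured databases
    being below ``cfg.rare_freq_max`` (absent counts as 0). Exonic effect
    classes always qualify; any other class qualifies only with a damaging
    splice score. Order-stable; input list is not modified.
    """
    cfg = cfg or ThresholdConfig()
    out = []
    for v in variants:
        ann = _require_annotation(v)
        if ann.max_pop_freq >= cfg.rare_freq_max:
            continue
        if ann.effect_class in EXONIC_EFFECTS or _splice_damaging(ann, cfg):
            out.append(v)
    return out


def _quality_tier(v: SequenceVariant, cfg: ThresholdConfig) -> int:
    af_ok = (
        cfg.het_af_band[0] <= v.allele_fraction <= cfg.het_af_band[1]
        if v.zygosity == "het"
        else v.allele_fraction >= cfg.hom_af_min
    )
    if v.read_depth >= cfg.quality_min_depth and v.genotype_quality >= cfg.quality_min_gq and af_ok:
        return 1
    if v.read_depth >= cfg.quality_tier2_depth:
        return 2
    return 3


def _frequency_tier(ann: AnnotationBundle) -> int:
    f = ann.max_pop_freq
    if f == 0.0:
        return 1
    if f < 0.001:
        return 2
    if f < 0.01:
        return 3
    return 4


def majority_damaging(damaging: int, total: int) -> bool:
    """Damaging consensus: at least half of the available predictors."""
    return total > 0 and 2 * damaging >= total


def _impact_tier(ann: AnnotationBundle, cfg: ThresholdConfig) -> int:
    if ann.effect_class in LOF_EFFECTS:
        return 1
    if ann.effect_class == "missense":
        if majority_damaging(ann.damaging_predictor_count, ann.predictor_total):
            return 2
        if any(s >= cfg.conservation_high for s in ann.conservation_scores.values()):
            return 2
    return 3


def _disease_tier(ann: AnnotationBundle) -> int:
    if ann.disease_gene is not None:
        return 1
    if ann.mouse_phenotype_flag:
        return 2
    return 3


def assign_tiers(variant: SequenceVariant, cfg: Optional[ThresholdConfig] = None) -> TierAssignment:
    """Pure function from (variant, config) to the four ordered tiers."""
    cfg = cfg or ThresholdConfig()
    ann = _require_annotation(variant)
    return TierAssignment(
        quality_tier=_quality_tier(variant, cfg),
        frequency_tier=_frequency_tier(ann),
        impact_tier=_impact_tier(ann, cfg),
        disease_tier=_disease_tier(ann),
        pathogenicity_category=classify_reported_pathogenicity(variant),
    )


def classify_reported_pathogenicity(variant: SequenceVariant) -> str:
    """Collapse the per-source assertion map into one pathogenicity category."""
    ann = _require_annotation(variant)
    classes = set(ann.assertions.values())
    path_like = {"pathogenic", "likely_pathogenic"} & classes
    if path_like and "benign" in classes:
        return "conflicting"
    if "pathogenic" in classes:
        return "asserted_pathogenic"
    if "likely_pathogenic" in classes:
        return "asserted_likely"
    # unreported, VUS-only or benign-only: treated as novel for ranking
    return "novel"


def assign_inheritance_category(
    gene_variants: Sequence[SequenceVariant],
    disease_gene: Optional[DiseaseGeneEntry],
    case_sex: str,
) -> List[Tuple[Tuple[SequenceVariant, ...], str]]:
    """Sort one case's variants in one gene by zygosity vs. mode of inheritance.

    Returns ``(variants, category)`` entries: singletons for AD_het / AR_hom /
    XL_hemizygous / carrier_only / incompatible, and one pair entry per
    distinct-position het pair when the gene supports recessive inheritance
    (phase unknown in a proband-only design).

    When the gene is absent from the disease table no mode restriction
    applies ("novel gene"): all modes are considered.
    """
    modes = disease_gene.inheritance_modes if disease_gene is not None else frozenset({"AD", "AR", "XL"})
    entries: List[Tuple[Tuple[SequenceVariant, ...], str]] = []

    hets = [v for v in gene_variants if v.zygosity == "het"]
    distinct_het_positions = {(v.chrom, v.pos) for v in hets}
    compound_possible = "AR" in modes and len(distinct_het_positions) >= 2

    for v in gene_variants:
        if v.zygosity == "hemizygous":
            cat = "XL_hemizygous" if ("XL" in modes and case_sex == "M") else "incompatible"
        elif v.zygosity == "hom":
            cat = "AR_hom" if "AR" in modes else "incompatible"
        else:  # het
            if "AD" in modes:
                cat = "AD_het"
            elif "AR" in modes:
                cat = "AR_compound_het_candidate" if compound_possible else "carrier_only"
            else:
                cat = "incompatible"
        entries.append(((v,), cat))

    if compound_possible:
        for a, b in combinations(sorted(hets, key=lambda v: (v.chrom, v.pos, v.alt)), 2):
            if (a.chrom, a.pos) != (b.chrom, b.pos):
                entries.append(((a, b), "AR_compound_het_candidate"))
    return entries


_MOI_COMPATIBLE = {"AD_het", "AR_hom", "AR_compound_het_candidate", "XL_hemizygous"}

_CATEGORY_TO_MODEL = {
    "AD_het": "AD",
    "AR_hom": "AR_hom",
    "AR_compound_het_candidate": "AR_compound_het",
    "XL_hemizygous": "XL",
}


def acmg_classify_simplified(
    variant: SequenceVariant,
    inheritance_category: str,
    phenotype_match: float,
    cfg: Optional[ThresholdConfig] = None,
) -> str:
    """Simplified, deterministic pathogenic / likely-pathogenic / VUS rule table.

    Rules, in order (first hit wins):

    1. LoF effect in a gene with a loss-of-function disease mechanism and
       absent from every frequency database -> pathogenic
    2. asserted pathogenic AND (LoF, or missense with damaging-predictor
       consensus) -> pathogenic
    3. asserted likely-pathogenic with a compatible inheritance category
       -> likely_pathogenic
    4. unreported ("novel") missense with damaging consensus, compatible
       inheritance category and phenotype overlap -> likely_pathogenic
    5. everything else -> VUS

    This is an explicit simplification of the published framework; the full
    28-criterion scheme is out of scope.
    """
    cfg = cfg or ThresholdConfig()
    ann = _require_annotation(variant)
    reported = classify_reported_pathogenicity(variant)
    is_lof = ann.effect_class in LOF_EFFECTS
    consensus = majority_damaging(ann.damaging_predictor_count, ann.predictor_total)
    moi_ok = inheritance_category in _MOI_COMPATIBLE

    if is_lof and ann.disease_gene is not None and ann.disease_gene.lof_mechanism and ann.max_pop_freq == 0.0:
        return "pathogenic"
    if reported == "asserted_pathogenic" and (is_lof or (ann.effect_class == "missense" and consensus)):
        return "pathogenic"
    if reported == "asserted_likely" and moi_ok:
        return "likely_pathogenic"
    if (
        reported == "novel"
        and ann.effect_class == "missense"
        and consensus
        and moi_ok
        and phenotype_match > 0
    ):
        return "likely_pathogenic"
    return "VUS"


_ACMG_ORDER = {"pathogenic": 1, "likely_pathogenic": 2, "VUS": 3}
_REPORTED_ORDER = {"asserted_pathogenic": 1, "asserted_likely": 2, "novel": 3, "conflicting": 4}
# compound-het candidates are unphased, so rank them behind the directly
# observed categories at equal evidence
_INHERITANCE_ORDER = {"AD_het": 1, "AR_hom": 1, "XL_hemizygous": 1, "AR_compound_het_candidate": 2}


def rank_candidates(
    case_variants: Sequence[SequenceVariant],
    case_sex: str,
    case_terms: Iterable[str],
    ontology: Optional[Ontology],
    cfg: Optional[ThresholdConfig] = None,
) -> List[CandidateDiagnosis]:
    """Run the full per-case prioritization and return ranked candidates.

    Variants failing the rare/functional filter never become candidates;
    carrier-only and incompatible entries are dropped (a single het in a
    recessive gene is never diagnostic on its own). The sort key is
    (reported pathogenicity, impact tier, disease tier, inheritance order,
    descending phenotype match, frequency tier), ties broken by genomic
    coordinate.
    """
    cfg = cfg or ThresholdConfig()
    kept = filter_rare_functional(case_variants, cfg)

    by_gene: Dict[Optional[str], List[SequenceVariant]] = defaultdict(list)
    for v in kept:
        by_gene[_require_annotation(v).gene].append(v)

    candidates: List[CandidateDiagnosis] = []
    case_terms = frozenset(case_terms)
    for gene, gvars in by_gene.items():
        disease_gene = gvars[0].annotation.disease_gene
        for vs, category in assign_inheritance_category(gvars, disease_gene, case_sex):
            if category not in _MOI_COMPATIBLE:
                continue
            # singleton het entries in a compound-capable gene are labelled
            # AR_compound_het_candidate for tiering, but only pairs can
            # constitute a candidate diagnosis
            if category == "AR_compound_het_candidate" and len(vs) != 2:
                continue
            if ontology is not None and disease_gene is not None and disease_gene.phenotype_terms:
                pheno = phenotype_match_score(case_terms, disease_gene.phenotype_terms, ontology)
            else:
                pheno = 0.0
            classes = [acmg_classify_simplified(v, category, pheno, cfg) for v in vs]
            # a pair is only as strong as its weaker allele
            acmg = max(classes, key=_ACMG_ORDER.__getitem__)
            tiers = [assign_tiers(v, cfg) for v in vs]
            worst = TierAssignment(
                quality_tier=max(t.quality_tier for t in tiers),
                frequency_tier=max(t.frequency_tier for t in tiers),
                impact_tier=max(t.impact_tier for t in tiers),
                disease_tier=max(t.disease_tier for t in tiers),
                inheritance_category=category,
                pathogenicity_category=max(
                    (t.pathogenicity_category for t in tiers), key=_REPORTED_ORDER.__getitem__
                ),
            )
            candidates.append(
                CandidateDiagnosis(
                    case_id=vs[0].case_id,
                    variants=vs,
                    gene=gene,
                    moi_model=_CATEGORY_TO_MODEL[category],
                    acmg_class=acmg,
                    phenotype_match=pheno,
                    tiers=worst,
                    phase_unknown=(category == "AR_compound_het_candidate"),
                )
            )

    def sort_key(c: CandidateDiagnosis):
        t = c.tiers
        v0 = min(c.variants, key=lambda v: (v.chrom, v.pos))
        return (
            _REPORTED_ORDER[t.pathogenicity_category],
            t.impact_tier,
            t.disease_tier,
            _INHERITANCE_ORDER[t.inheritance_category],
            -c.phenotype_match,
            t.frequency_tier,
            v0.chrom,
            v0.pos,
        )

    candidates.sort(key=sort_key)
    for i, c in enumerate(candidates, start=1):
        c.rank = i
    return candidates


def count_rare_damaging(
    case_variants: Sequence[SequenceVariant], cfg: Optional[ThresholdConfig] = None
) -> int:
    """Rare functional variants with impact tier <= 2 (the 'damaging events'
    a genome presents for interpretation)."""
    cfg = cfg or ThresholdConfig()
    kept = filter_rare_functional(case_variants, cfg)
    return sum(1 for v in kept if assign_tiers(v, cfg).impact_tier <= 2)
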