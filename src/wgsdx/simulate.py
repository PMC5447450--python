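"""Self-contained synthetic cohort generator with a ground-truth manifest.

Generates everything the pipeline consumes — gene models, tracks, control
CNVs, per-case variant call sets (VCF + annotation table), read-depth
segments, junction SV events, array calls, phenotypes and consent flags — on
a reduced synthetic genome, with planted causal scenarios recorded in a
manifest the recovery tests assert against.

Per-genome intensities are calibrated to the clinical WGS profile this
package models: ~20,014 exonic/splicing small variants, ~498 rare damaging
events, ~248 read-depth CNVs (median ~10 kb, ~28% exonic) and ~1,604
junction SVs (median ~495 bp, ~2% exonic) at ``scale=1``; all counts scale
linearly with ``scale``.

Everything is deterministic under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import (
    AnnotationBundle,
    Case,
    CmaCall,
    CnvRecord,
    DiseaseGeneEntry,
    GeneModel,
    SequenceVariant,
    SvEvent,
)
from .ontology import CATEGORY_LABELS, Ontology, build_mini_hpo, leaves_for_category

__all__ = [
    "SimulationConfig",
    "Resources",
    "CaseBundle",
    "PlantedScenario",
    "generate_resources",
    "generate_case",
    "generate_cohort",
    "DEFAULT_SCENARIO_CYCLE",
]

BASES = np.array(list("ACGT"))

#: scenario kinds cycled over the cohort by default (7 of 10 cases planted)
DEFAULT_SCENARIO_CYCLE = (
    "AD_het",
    "AR_hom",
    "pathogenic_cnv",
    "none",
    "AR_compound_het",
    "XL_hemizygous",
    "AD_het",
    "none",
    "AR_hom",
    "pathogenic_cnv",
)

# per-class background intensities at scale=1:
# (mean count, P(rare), P(damaging-consensus | rare))
BACKGROUND_CLASSES: Dict[str, Tuple[float, float, float]] = {
    "synonymous": (9500.0, 0.12, 0.0),
    "missense": (8500.0, 0.15, 0.35),
    "nonsense": (60.0, 0.30, 1.0),
    "frameshift": (80.0, 0.30, 1.0),
    "canonical_splice": (25.0, 0.30, 1.0),
    "inframe_indel": (250.0, 0.20, 0.0),
    "ncRNA_exonic": (1200.0, 0.20, 0.0),
    "splice_region": (400.0, 0.20, 0.0),
}

FREQ_DBS = ("popdb_a", "popdb_b", "popdb_c")


@dataclass
class SimulationConfig:
    cohort_n: int = 30
    seed: int = 0
    scale: float = 0.1
    scenario_cycle: Sequence[str] = DEFAULT_SCENARIO_CYCLE
    n_genes: int = 500
    n_disease_genes: int = 80
    n_chromosomes: int = 4  # autosomes; X and Y are added on top
    chrom_length: int = 40_000_000
    cnv_count_mean: float = 248.0
    sv_count_mean: float = 1604.0
    cnv_exonic_frac: float = 0.28
    sv_exonic_frac: float = 0.02
    cnv_median_size: int = 10_000
    sv_median_size: int = 495
    cma_background_mean: float = 6.0
    cma_detectable_rate: float = 0.84
    cma_probe_jitter: int = 5_000
    fragmented_cnv_frac: float = 0.3
    segdup_genome_frac: float = 0.05
    hypervariable_genome_frac: float = 0.02
    control_cohort_n: int = 100
    opt_out_rate: float = 0.26

    def __post_init__(self) -> None:
        if not (0.0 < self.scale <= 1.0):
            raise ValueError("scale must be in (0, 1]")
        unknown = set(self.scenario_cycle) - {
            "AD_het", "AR_hom", "AR_compound_het", "XL_hemizygous", "pathogenic_cnv", "none",
        }
        if unknown:
            raise ValueError(f"unknown scenario kinds: {sorted(unknown)}")


@dataclass
class Resources:
    genome: Dict[str, int]
    genes: List[GeneModel]
    disease_genes: Dict[str, DiseaseGeneEntry]
    gene_categories: Dict[str, str]  # disease gene -> top-level phenotype category term
    segdup: List[Tuple[str, int, int]]
    hypervariable: List[Tuple[str, int, int]]
    syndromic_regions: List[Tuple[str, int, int, str]]
    control_cnvs: Dict[str, List[CnvRecord]]
    dgv_like: List[CnvRecord]
    common_cnv_pool: List[Tuple[str, int, int, str]]
    ontology: Ontology

    @property
    def genes_by_name(self) -> Dict[str, GeneModel]:
        return {g.gene: g for g in self.genes}

    @property
    def exons_by_chrom(self) -> Dict[str, List[Tuple[int, int]]]:
        cached = getattr(self, "_exons_by_chrom", None)
        if cached is None:
            cached = {}
            for g in self.genes:
                cached.setdefault(g.chrom, []).extend(g.exons)
            object.__setattr__(self, "_exons_by_chrom", cached)
        return cached


@dataclass
class PlantedScenario:
    kind: str
    gene: Optional[str] = None
    variant_keys: List[tuple] = field(default_factory=list)  # (chrom,pos,ref,alt)
    expected_category: Optional[str] = None
    expected_acmg: Optional[str] = None
    cnv: Optional[dict] = None  # chrom,start,end,state,detectable,fragmented
    origin: str = "NA"
    category_term: Optional[str] = None


@dataclass
class CaseBundle:
    case: Case
    variants: List[SequenceVariant]
    cnv_segments: List[Tuple[CnvRecord, bool]]  # raw rows: (record, hypervariable flag)
    sv_events: List[SvEvent]
    cma_calls: List[CmaCall]
    scenario: PlantedScenario


# --------------------------------------------------------------------------
# resources


def _random_intervals_covering(
    rng: np.random.Generator,
    genome: Dict[str, int],
    target_frac: float,
    size_lo: int,
    size_hi: int,
    avoid: Sequence[Tuple[str, int, int]] = (),
) -> List[Tuple[str, int, int]]:
    """Draw intervals until their union covers ~target_frac of the genome."""
    chroms = sorted(genome)
    total = sum(genome.values())
    target = target_frac * total
    covered = 0.0
    out: List[Tuple[str, int, int]] = []
    while covered < target:
        c = chroms[rng.integers(len(chroms))]
        size = int(rng.integers(size_lo, size_hi))
        start = int(rng.integers(0, max(1, genome[c] - size)))
        iv = (c, start, start + size)
        if any(a[0] == c and min(a[2], iv[2]) > max(a[1], iv[1]) for a in avoid):
            continue
        out.append(iv)
        covered += size  # overlaps among draws are rare at these densities
    return sorted(out)


def generate_resources(cfg: SimulationConfig, seed: Optional[int] = None) -> Resources:
    """Deterministically build the full annotation-resource bundle."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genome = {f"chr{i}": cfg.chrom_length for i in range(1, cfg.n_chromosomes + 1)}
    genome["chrX"] = 30_000_000
    genome["chrY"] = 10_000_000

    # non-overlapping gene models on autosomes + X
    genes: List[GeneModel] = []
    placeable = [c for c in sorted(genome) if c != "chrY"]
    per_chrom = cfg.n_genes // len(placeable) + 1
    gi = 0
    for chrom in placeable:
        slot = genome[chrom] // per_chrom
        for k in range(per_chrom):
            if gi >= cfg.n_genes:
                break
            span = int(rng.integers(8_000, 60_000))
            start = k * slot + int(rng.integers(0, max(1, slot - span)))
            n_ex = int(rng.integers(3, 9))
            positions = np.sort(rng.choice(np.arange(0, span - 300, 10), size=n_ex, replace=False))
            exons = []
            last_end = -1
            for p in positions:
                s = start + int(p)
                e = s + int(rng.integers(100, 300))
                if s <= last_end:
                    continue
                exons.append((s, min(e, start + span)))
                last_end = e
            genes.append(GeneModel(gene=f"G{gi:04d}", chrom=chrom, start=start, end=start + span, exons=tuple(exons)))
            gi += 1

    ontology = build_mini_hpo()
    categories = sorted(CATEGORY_LABELS)
    cat_leaves = {c: leaves_for_category(ontology, c) for c in categories}

    # disease genes: round-robin over MOI so every scenario kind has a pool;
    # X-linked entries must sit on chrX
    disease_genes: Dict[str, DiseaseGeneEntry] = {}
    gene_categories: Dict[str, str] = {}
    x_genes = [g for g in genes if g.chrom == "chrX"]
    autosomal = [g for g in genes if g.chrom not in ("chrX", "chrY")]
    autosomal = [autosomal[int(i)] for i in rng.permutation(len(autosomal))]
    moi_cycle = ["AD", "AR", "AD", "AR", "XL"]
    xi = ai = 0
    for i in range(cfg.n_disease_genes):
        moi = moi_cycle[i % len(moi_cycle)]
        if moi == "XL":
            if xi >= len(x_genes):
                continue
            g = x_genes[xi]
            xi += 1
        else:
            g = autosomal[ai]
            ai += 1
        cat = categories[i % len(categories)]
        leaves = cat_leaves[cat]
        terms = [leaves[int(j)] for j in rng.choice(len(leaves), size=min(3, len(leaves)), replace=False)]
        disease_genes[g.gene] = DiseaseGeneEntry(
            gene=g.gene,
            inheritance_modes=frozenset({moi}),
            condition=f"synthetic disorder {i}",
            phenotype_terms=frozenset(terms),
            lof_mechanism=bool(i % 3 != 2),  # two thirds have a LoF mechanism
        )
        gene_categories[g.gene] = cat

    # syndromic regions: large loss-sensitive regions on gene-dense autosomes
    syndromic: List[Tuple[str, int, int, str]] = []
    for i in range(8):
        chrom = f"chr{(i % cfg.n_chromosomes) + 1}"
        size = int(rng.integers(300_000, 3_000_000))
        start = int(rng.integers(0, genome[chrom] - size))
        syndromic.append((chrom, start, start + size, "loss"))

    segdup = _random_intervals_covering(
        rng, genome, cfg.segdup_genome_frac, 10_000, 100_000,
        avoid=[(c, s, e) for c, s, e, _ in syndromic],
    )
    hypervariable = _random_intervals_covering(
        rng, genome, cfg.hypervariable_genome_frac, 5_000, 50_000,
        avoid=[(c, s, e) for c, s, e, _ in syndromic],
    )

    # shared polymorphic CNV pool; controls and the common-variant set draw
    # from it so planted rare CNVs stay rare
    pool: List[Tuple[str, int, int, str]] = []
    auto_chroms = [f"chr{i}" for i in range(1, cfg.n_chromosomes + 1)]
    for _ in range(40):
        chrom = auto_chroms[int(rng.integers(len(auto_chroms)))]
        size = int(rng.integers(5_000, 80_000))
        start = int(rng.integers(0, genome[chrom] - size))
        if any(c == chrom and min(e, start + size) > max(s, start) for c, s, e, _ in syndromic):
            continue
        pool.append((chrom, start, start + size, "loss" if rng.random() < 0.5 else "gain"))

    control_cnvs: Dict[str, List[CnvRecord]] = {}
    pool_rates = rng.uniform(0.02, 0.4, size=len(pool))
    for s_i in range(cfg.control_cohort_n):
        sample = f"CTL{s_i:03d}"
        recs = []
        for (chrom, s, e, state), rate in zip(pool, pool_rates):
            if rng.random() < rate:
                jitter = int(rng.integers(-200, 200))
                recs.append(CnvRecord(case_id=sample, chrom=chrom, start=max(0, s + jitter), end=e + jitter, state=state, source="read_depth"))
        control_cnvs[sample] = recs

    dgv_like = [
        CnvRecord(case_id="DGV", chrom=c, start=s, end=e, state=st, source="read_depth")
        for (c, s, e, st), rate in zip(pool, pool_rates)
        if rate > 0.05
    ]

    return Resources(
        genome=genome,
        genes=genes,
        disease_genes=disease_genes,
        gene_categories=gene_categories,
        segdup=segdup,
        hypervariable=hypervariable,
        syndromic_regions=syndromic,
        control_cnvs=control_cnvs,
        dgv_like=dgv_like,
        common_cnv_pool=pool,
        ontology=ontology,
    )


# --------------------------------------------------------------------------
# per-case generation helpers


def _draw_pop_freqs(rng: np.random.Generator, rare: bool, force_absent: bool = False) -> Dict[str, float]:
    if force_absent:
        return {}
    if rare:
        if rng.random() < 0.25:
            return {}
        base = float(rng.uniform(1e-5, 0.049))
    else:
        base = float(rng.uniform(0.05, 0.5))
    return {db: float(np.clip(base * rng.uniform(0.8, 1.2), 0.0, 1.0)) for db in FREQ_DBS}


def _draw_quality(rng: np.random.Generator, zygosity: str) -> Tuple[int, float, float]:
    if rng.random() < 0.05:  # low-quality tail
        depth = int(rng.integers(2, 10))
        gq = float(rng.uniform(3, 25))
    else:
        depth = max(1, int(rng.poisson(50)))
        gq = float(rng.uniform(35, 99))
    if zygosity == "het":
        af = float(np.clip(rng.normal(0.5, 0.06), 0.05, 0.95))
    else:
        af = float(np.clip(rng.normal(0.97, 0.02), 0.8, 1.0))
    return depth, gq, af


def _snv_alleles(rng: np.random.Generator, effect: str) -> Tuple[str, str]:
    if effect in ("frameshift", "inframe_indel"):
        ins = "".join(BASES[rng.integers(0, 4, size=4 if effect == "inframe_indel" else 2)])
        return "A", "A" + ins
    i, j = rng.choice(4, size=2, replace=False)
    return str(BASES[i]), str(BASES[j])


def _random_exonic_pos(rng: np.random.Generator, gene: GeneModel) -> int:
    s, e = gene.exons[int(rng.integers(len(gene.exons)))]
    return int(rng.integers(s, e)) + 1  # 1-based


def _background_variants(
    rng: np.random.Generator, case_id: str, sex: str, resources: Resources, scale: float
) -> List[SequenceVariant]:
    out: List[SequenceVariant] = []
    genes = resources.genes
    seen = set()
    for effect, (mean, p_rare, p_dmg) in BACKGROUND_CLASSES.items():
        n = rng.poisson(mean * scale)
        for _ in range(n):
            gene = genes[int(rng.integers(len(genes)))]
            pos = _random_exonic_pos(rng, gene)
            if (gene.chrom, pos) in seen:
                continue
            seen.add((gene.chrom, pos))
            rare = rng.random() < p_rare
            lof = effect in ("nonsense", "frameshift", "canonical_splice")
            # background LoF mostly carries a nonzero frequency so the
            # pathogenic rule (absent + LoF mechanism) fires rarely off-target
            freqs = _draw_pop_freqs(rng, rare)
            if lof and not freqs and rng.random() > 0.2:
                freqs = {db: float(rng.uniform(1e-5, 0.049 if rare else 0.3)) for db in FREQ_DBS}
            damaging = rare and rng.random() < p_dmg
            if effect == "missense":
                total = 4
                count = int(rng.integers(2, 5)) if damaging else int(rng.integers(0, 2))
            else:
                total, count = 0, 0
            splice_delta = None
            if effect == "splice_region" and rng.random() < 0.5:
                splice_delta = float(rng.uniform(0.1, 0.6))
            cons = float(rng.normal(2.0, 0.5)) if damaging else float(rng.normal(0.0, 0.8))
            if sex == "M" and gene.chrom == "chrX":
                zyg = "hemizygous"
            else:
                zyg = "het" if rng.random() < 0.65 else "hom"
            depth, gq, af = _draw_quality(rng, "hom" if zyg == "hemizygous" else zyg)
            ref, alt = _snv_alleles(rng, effect)
            out.append(
                SequenceVariant(
                    case_id=case_id, chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
                    zygosity=zyg, read_depth=depth, genotype_quality=gq,
                    allele_fraction=1.0 if zyg == "hemizygous" else af,
                    annotation=AnnotationBundle(
                        gene=gene.gene,
                        effect_class=effect,
                        pop_freqs=freqs,
                        conservation_scores={"phylop_like": cons},
                        damaging_predictor_count=count,
                        predictor_total=total,
                        splice_delta=splice_delta,
                        disease_gene=resources.disease_genes.get(gene.gene),
                        mouse_phenotype_flag=bool(rng.random() < 0.1),
                    ),
                )
            )
    return out


def _planted_variant(
    rng: np.random.Generator,
    case_id: str,
    gene: GeneModel,
    entry: DiseaseGeneEntry,
    effect: str,
    zygosity: str,
    asserted: bool,
    avoid_pos: Sequence[int] = (),
) -> SequenceVariant:
    pos = _random_exonic_pos(rng, gene)
    while pos in avoid_pos:
        pos = _random_exonic_pos(rng, gene)
    depth = int(rng.integers(30, 70))
    ref, alt = _snv_alleles(rng, effect)
    af = 0.5 if zygosity == "het" else 0.97
    return SequenceVariant(
        case_id=case_id, chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
        zygosity=zygosity, read_depth=depth, genotype_quality=float(rng.uniform(50, 99)),
        allele_fraction=1.0 if zygosity == "hemizygous" else af,
        annotation=AnnotationBundle(
            gene=gene.gene,
            effect_class=effect,
            pop_freqs={},  # planted causal variants are absent everywhere
            conservation_scores={"phylop_like": float(rng.uniform(2.5, 5.0))},
            damaging_predictor_count=4 if effect == "missense" else 0,
            predictor_total=4 if effect == "missense" else 0,
            assertions={"clinvar_like": "pathogenic"} if asserted else {},
            disease_gene=entry,
            mouse_phenotype_flag=True,
        ),
    )


def _pick_disease_gene(
    rng: np.random.Generator, resources: Resources, moi: str, lof: bool
) -> Tuple[GeneModel, DiseaseGeneEntry]:
    by_name = resources.genes_by_name
    pool = [
        (by_name[g], e)
        for g, e in sorted(resources.disease_genes.items())
        if moi in e.inheritance_modes and (e.lof_mechanism or not lof)
    ]
    if not pool:
        raise ValueError(f"no disease gene with mode {moi} available")
    return pool[int(rng.integers(len(pool)))]


def _jittered_cma(
    rng: np.random.Generator, case_id: str, chrom: str, start: int, end: int, state: str,
    jitter: int, classification: str,
) -> CmaCall:
    j = lambda: int(rng.integers(100, max(200, jitter)))
    inner_start = min(start + j(), end - 1)
    inner_end = max(end - j(), inner_start + 1)
    return CmaCall(
        case_id=case_id, chrom=chrom,
        inner_start=inner_start, inner_end=inner_end,
        outer_start=max(0, start - j()), outer_end=end + j(),
        state=state, classification=classification,
    )


def _place_cnv(
    rng: np.random.Generator,
    resources: Resources,
    size: int,
    exonic: bool,
    max_tries: int = 30,
) -> Tuple[str, int, int]:
    genes = resources.genes
    genome = resources.genome
    if exonic:
        g = genes[int(rng.integers(len(genes)))]
        s, e = g.exons[int(rng.integers(len(g.exons)))]
        center = (s + e) // 2
        start = max(0, center - size // 2)
        return g.chrom, start, start + size
    chroms = [c for c in sorted(genome) if c != "chrY"]
    exons_by_chrom = resources.exons_by_chrom
    for _ in range(max_tries):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max(1, genome[chrom] - size)))
        end = start + size
        if not any(min(end, ee) > max(start, es) for es, ee in exons_by_chrom.get(chrom, ())):
            return chrom, start, end
    return chrom, start, end  # give up; tiny exonic leakage is tolerated


def generate_case(
    cfg: SimulationConfig,
    resources: Resources,
    case_id: str,
    scenario_kind: str,
    rng: np.random.Generator,
) -> CaseBundle:
    """Generate one case's complete call set plus its manifest entry."""
    sex = "M" if scenario_kind == "XL_hemizygous" else ("M" if rng.random() < 0.57 else "F")
    scenario = PlantedScenario(kind=scenario_kind)

    variants = _background_variants(rng, case_id, sex, resources, cfg.scale)

    # --- planted sequence-level scenario
    if scenario_kind in ("AD_het", "AR_hom", "AR_compound_het", "XL_hemizygous"):
        moi = {"AD_het": "AD", "AR_hom": "AR", "AR_compound_het": "AR", "XL_hemizygous": "XL"}[scenario_kind]
        gene, entry = _pick_disease_gene(rng, resources, moi, lof=scenario_kind != "AR_compound_het")
        if scenario_kind == "AD_het":
            planted = [_planted_variant(rng, case_id, gene, entry, "frameshift", "het", asserted=False)]
            scenario.origin = "de_novo"
            scenario.expected_category, scenario.expected_acmg = "AD_het", "pathogenic"
        elif scenario_kind == "AR_hom":
            planted = [_planted_variant(rng, case_id, gene, entry, "nonsense", "hom", asserted=False)]
            scenario.origin = "maternal+paternal"
            scenario.expected_category, scenario.expected_acmg = "AR_hom", "pathogenic"
        elif scenario_kind == "XL_hemizygous":
            planted = [_planted_variant(rng, case_id, gene, entry, "nonsense", "hemizygous", asserted=False)]
            scenario.origin = "maternal"
            scenario.expected_category, scenario.expected_acmg = "XL_hemizygous", "pathogenic"
        else:  # compound het: two asserted-pathogenic damaging missense alleles
            v1 = _planted_variant(rng, case_id, gene, entry, "missense", "het", asserted=True)
            v2 = _planted_variant(rng, case_id, gene, entry, "missense", "het", asserted=True, avoid_pos=[v1.pos])
            planted = [v1, v2]
            scenario.origin = "maternal+paternal"
            scenario.expected_category, scenario.expected_acmg = "AR_compound_het_candidate", "pathogenic"
        variants.extend(planted)
        scenario.gene = gene.gene
        scenario.variant_keys = [(v.chrom, v.pos, v.ref, v.alt) for v in planted]
        scenario.category_term = resources.gene_categories[gene.gene]
        case_terms = set(entry.phenotype_terms)
    else:
        case_terms = set()

    # phenotype noise terms
    all_terms = sorted(resources.ontology.terms - {resources.ontology.root})
    for _ in range(int(rng.integers(1, 4))):
        case_terms.add(all_terms[int(rng.integers(len(all_terms)))])

    # --- read-depth CNV background (plus raw-file decoys)
    cnv_rows: List[Tuple[CnvRecord, bool]] = []
    n_cnv = rng.poisson(cfg.cnv_count_mean * cfg.scale)
    for _ in range(n_cnv):
        size = max(2_000, int(cfg.cnv_median_size * np.exp(rng.normal(0.0, 0.8))))
        chrom, start, end = _place_cnv(rng, resources, size, exonic=rng.random() < cfg.cnv_exonic_frac)
        state = "loss" if rng.random() < 0.5 else "gain"
        copy_state = (1 if rng.random() < 0.9 else 0) if state == "loss" else (3 if rng.random() < 0.9 else 4)
        cnv_rows.append(
            (CnvRecord(case_id=case_id, chrom=chrom, start=start, end=end, state=state,
                       source="read_depth", copy_state=copy_state), False)
        )
    # decoys: hypervariable-flagged, diploid and chrY rows must be filtered out
    for _ in range(max(1, int(0.05 * n_cnv))):
        c, s, e = resources.hypervariable[int(rng.integers(len(resources.hypervariable)))]
        cnv_rows.append(
            (CnvRecord(case_id=case_id, chrom=c, start=s, end=e, state="gain",
                       source="read_depth", copy_state=3), True)
        )
    for _ in range(2):
        start = int(rng.integers(0, resources.genome["chr1"] - 50_000))
        cnv_rows.append(
            (CnvRecord(case_id=case_id, chrom="chr1", start=start, end=start + 50_000,
                       state="gain", source="read_depth", copy_state=2), False)
        )
    if sex == "M":
        start = int(rng.integers(0, resources.genome["chrY"] - 20_000))
        cnv_rows.append(
            (CnvRecord(case_id=case_id, chrom="chrY", start=start, end=start + 20_000,
                       state="loss", source="read_depth", copy_state=1), False)
        )

    # --- junction SV events (retained set + sub-threshold / wrong-type decoys)
    sv_events: List[SvEvent] = []
    n_sv = rng.poisson(cfg.sv_count_mean * cfg.scale)
    for _ in range(n_sv):
        size = max(60, int(cfg.sv_median_size * np.exp(rng.normal(0.0, 0.9))))
        chrom, start, end = _place_cnv(rng, resources, size, exonic=rng.random() < cfg.sv_exonic_frac)
        svtype = "deletion" if rng.random() < 0.7 else "tandem_duplication"
        support = 20 + int(rng.geometric(0.05))
        sv_events.append(SvEvent(case_id=case_id, type=svtype, chrom=chrom, start=start, end=end, support=support))
    for _ in range(max(1, int(0.15 * n_sv))):
        size = max(60, int(cfg.sv_median_size * np.exp(rng.normal(0.0, 0.9))))
        chrom, start, end = _place_cnv(rng, resources, size, exonic=False)
        low_support = rng.random() < 0.7
        sv_events.append(
            SvEvent(
                case_id=case_id,
                type="deletion" if low_support else "other",
                chrom=chrom, start=start, end=end,
                support=int(rng.integers(1, 20)) if low_support else 25 + int(rng.geometric(0.05)),
            )
        )

    # --- array calls: polymorphic pool draws + rare singletons, a fraction
    # of which get a concordant read-depth counterpart
    cma_calls: List[CmaCall] = []
    n_cma = rng.poisson(cfg.cma_background_mean)
    for _ in range(n_cma):
        if rng.random() < 0.3 and resources.common_cnv_pool:
            chrom, start, end, state = resources.common_cnv_pool[int(rng.integers(len(resources.common_cnv_pool)))]
        else:
            size = int(rng.integers(30_000, 500_000))
            chrom, start, end = _place_cnv(rng, resources, size, exonic=False)
            state = "loss" if rng.random() < 0.5 else "gain"
        cma_calls.append(
            _jittered_cma(rng, case_id, chrom, start, end, state, cfg.cma_probe_jitter,
                          classification="benign" if rng.random() < 0.7 else "VUS")
        )
        if rng.random() < cfg.cma_detectable_rate:
            cnv_rows.append(
                (CnvRecord(case_id=case_id, chrom=chrom,
                           start=max(0, start + int(rng.integers(-2000, 2000))),
                           end=end + int(rng.integers(-2000, 2000)),
                           state=state, source="read_depth",
                           copy_state=1 if state == "loss" else 3), False)
            )

    # --- planted pathogenic CNV with guaranteed array counterpart
    if scenario_kind == "pathogenic_cnv":
        regions = resources.syndromic_regions
        chrom, rstart, rend, state = regions[int(rng.integers(len(regions)))]
        start = max(0, rstart - int(rng.integers(0, 5_000)))
        end = rend + int(rng.integers(0, 5_000))
        copy_state = 1
        fragmented = bool(rng.random() < cfg.fragmented_cnv_frac)
        if fragmented:
            mid = (start + end) // 2
            gap = int(rng.integers(2_000, 8_000))  # below the default merge gap
            cnv_rows.append((CnvRecord(case_id=case_id, chrom=chrom, start=start, end=mid - gap // 2,
                                       state=state, source="read_depth", copy_state=copy_state), False))
            cnv_rows.append((CnvRecord(case_id=case_id, chrom=chrom, start=mid + gap // 2, end=end,
                                       state=state, source="read_depth", copy_state=copy_state), False))
        else:
            cnv_rows.append((CnvRecord(case_id=case_id, chrom=chrom, start=start, end=end,
                                       state=state, source="read_depth", copy_state=copy_state), False))
        cma_calls.append(
            _jittered_cma(rng, case_id, chrom, start, end, state, cfg.cma_probe_jitter,
                          classification="pathogenic")
        )
        scenario.cnv = {
            "chrom": chrom, "start": start, "end": end, "state": state,
            "detectable": True, "fragmented": fragmented,
        }
        scenario.expected_acmg = "pathogenic"
        scenario.origin = "de_novo"

    case = Case(
        case_id=case_id,
        sex=sex,
        age=float(np.round(rng.uniform(0.1, 17.9), 1)),
        hpo_terms=frozenset(case_terms),
        consent_secondary=bool(rng.random() >= cfg.opt_out_rate),
        consanguinity=bool(rng.random() < 0.08),
    )
    variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return CaseBundle(
        case=case,
        variants=variants,
        cnv_segments=cnv_rows,
        sv_events=sv_events,
        cma_calls=cma_calls,
        scenario=scenario,
    )


def generate_cohort(cfg: SimulationConfig) -> Tuple[Resources, List[CaseBundle]]:
    """Resources plus one bundle per case; fully determined by (cfg, cfg.seed)."""
    master = np.random.default_rng(cfg.seed)
    resources = generate_resources(cfg, seed=int(master.integers(2**31)))
    bundles = []
    cycle = list(cfg.scenario_cycle)
    for i in range(cfg.cohort_n):
        case_rng = np.random.default_rng(int(master.integers(2**31)))
        kind = cycle[i % len(cycle)]
        bundles.append(generate_case(cfg, resources, f"S{i + 1:04d}", kind, case_rng))
    return resources, bundles


def manifest_dict(cfg: SimulationConfig, bundles: Sequence[CaseBundle]) -> dict:
    """YAML-serialisable ground-truth manifest for a generated cohort."""
    cases = {}
    for b in bundles:
        s = b.scenario
        cases[b.case.case_id] = {
            "scenario": s.kind,
            "gene": s.gene,
            "variants": [list(k) for k in s.variant_keys],
            "expected_category": s.expected_category,
            "expected_acmg": s.expected_acmg,
            "cnv": s.cnv,
            "origin": s.origin,
            "category_term": s.category_term,
            "sex": b.case.sex,
            "consent_secondary": b.case.consent_secondary,
        }
    return {"seed": cfg.seed, "scale": cfg.scale, "cohort_n": cfg.cohort_n, "cases": cases}
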