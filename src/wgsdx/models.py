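"""Domain records shared across the pipeline stages.

All records are plain dataclasses with eager validation in ``__post_init__``
so malformed inputs fail at construction, not deep inside a filter.

Coordinate conventions: sequence-level variants keep VCF 1-based positions;
all interval records (CNV/SV/CMA/tracks) are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

__all__ = [
    "ZYGOSITIES",
    "EFFECT_CLASSES",
    "LOF_EFFECTS",
    "ASSERTION_CLASSES",
    "SequenceVariant",
    "AnnotationBundle",
    "DiseaseGeneEntry",
    "TierAssignment",
    "CandidateDiagnosis",
    "ThresholdConfig",
    "CnvRecord",
    "SvEvent",
    "CmaCall",
    "ConcordanceResult",
    "GeneModel",
    "GenePanelEntry",
    "SecondaryFinding",
    "Case",
    "DiagnosisRecord",
    "YieldComparison",
]

ZYGOSITIES = frozenset({"het", "hom", "hemizygous"})

EFFECT_CLASSES = frozenset(
    {
        "nonsense",
        "frameshift",
        "canonical_splice",
        "inframe_indel",
        "missense",
        "synonymous",
        "ncRNA_exonic",
        "splice_region",
        "UTR",
        "intronic",
        "intergenic",
    }
)

#: effect classes treated as loss-of-function throughout (impact tier 1,
#: secondary-screen eligibility, simplified pathogenicity rules)
LOF_EFFECTS = frozenset({"nonsense", "frameshift", "canonical_splice"})

#: effect classes that are exonic by construction and always pass the
#: functional filter; everything else needs a damaging splice score
EXONIC_EFFECTS = frozenset(
    {"nonsense", "frameshift", "canonical_splice", "inframe_indel", "missense", "ncRNA_exonic"}
)

ASSERTION_CLASSES = frozenset({"pathogenic", "likely_pathogenic", "VUS", "benign"})

MOI_MODES = frozenset({"AD", "AR", "XL"})

SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class DiseaseGeneEntry:
    """One row of the disease-gene table: gene with its inheritance modes."""

    gene: str
    inheritance_modes: frozenset = frozenset()
    condition: str = ""
    phenotype_terms: frozenset = frozenset()
    lof_mechanism: bool = False

    def __post_init__(self) -> None:
        self.inheritance_modes = frozenset(self.inheritance_modes)
        self.phenotype_terms = frozenset(self.phenotype_terms)
        _check(len(self.inheritance_modes) > 0, f"{self.gene}: inheritance_modes empty")
        _check(
            self.inheritance_modes <= MOI_MODES,
            f"{self.gene}: unknown inheritance modes {self.inheritance_modes - MOI_MODES}",
        )


@dataclass
class AnnotationBundle:
    """Join of gene/frequency/impact/assertion annotations for one variant.

    ``assertions`` maps source name (e.g. a ClinVar-like or HGMD-like
    database) to one of :data:`ASSERTION_CLASSES`; an empty mapping means
    the variant has never been reported.
    """

    gene: Optional[str] = None
    effect_class: str = "intergenic"
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    conservation_scores: Mapping[str, float] = field(default_factory=dict)
    damaging_predictor_count: int = 0
    predictor_total: int = 0
    splice_delta: Optional[float] = None
    assertions: Mapping[str, str] = field(default_factory=dict)
    disease_gene: Optional[DiseaseGeneEntry] = None
    mouse_phenotype_flag: bool = False

    def __post_init__(self) -> None:
        _check(self.effect_class in EFFECT_CLASSES, f"unknown effect_class {self.effect_class!r}")
        for db, f in self.pop_freqs.items():
            _check(0.0 <= f <= 1.0, f"pop_freq[{db}]={f} outside [0,1]")
        _check(self.damaging_predictor_count >= 0, "damaging_predictor_count < 0")
        _check(
            self.predictor_total >= self.damaging_predictor_count,
            "predictor_total < damaging_predictor_count",
        )
        for src, cls in self.assertions.items():
            _check(cls in ASSERTION_CLASSES, f"unknown assertion {cls!r} from {src!r}")

    @property
    def max_pop_freq(self) -> float:
        """Maximum allele frequency across configured databases (0 if absent)."""
        return max(self.pop_freqs.values(), default=0.0)


@dataclass
class SequenceVariant:
    """A single small-variant call for one case (VCF 1-based position)."""

    case_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str
    read_depth: int = 0
    genotype_quality: float = 0.0
    allele_fraction: float = 0.0
    annotation: Optional[AnnotationBundle] = None

    def __post_init__(self) -> None:
        _check(self.pos >= 1, f"pos {self.pos} < 1")
        _check(self.ref != self.alt, f"ref == alt at {self.chrom}:{self.pos}")
        _check(self.zygosity in ZYGOSITIES, f"unknown zygosity {self.zygosity!r}")
        _check(0.0 <= self.allele_fraction <= 1.0, "allele_fraction outside [0,1]")
        if self.zygosity == "hemizygous":
            _check(
                self.chrom in SEX_CHROMS,
                f"hemizygous call on autosome {self.chrom} at {self.pos}",
            )

    @property
    def key(self) -> tuple:
        return (self.case_id, self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # used in error messages
        return f"{self.case_id}:{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


INHERITANCE_CATEGORIES = frozenset(
    {
        "AD_het",
        "AR_hom",
        "AR_compound_het_candidate",
        "XL_hemizygous",
        "carrier_only",
        "incompatible",
    }
)

PATHOGENICITY_CATEGORIES = frozenset(
    {"asserted_pathogenic", "asserted_likely", "novel", "conflicting"}
)


@dataclass(frozen=True)
class TierAssignment:
    quality_tier: int
    frequency_tier: int
    impact_tier: int
    disease_tier: int
    inheritance_category: str = "incompatible"
    pathogenicity_category: str = "novel"

    def __post_init__(self) -> None:
        for name in ("quality_tier", "frequency_tier", "impact_tier", "disease_tier"):
            _check(getattr(self, name) >= 1, f"{name} must be >= 1")
        _check(self.inheritance_category in INHERITANCE_CATEGORIES, "bad inheritance_category")
        _check(self.pathogenicity_category in PATHOGENICITY_CATEGORIES, "bad pathogenicity_category")


@dataclass
class CandidateDiagnosis:
    """A ranked diagnostic hypothesis: one variant, or a compound-het pair."""

    case_id: str
    variants: Sequence[SequenceVariant]
    gene: Optional[str]
    moi_model: str  # AD | AR_hom | AR_compound_het | XL
    acmg_class: str  # pathogenic | likely_pathogenic | VUS
    phenotype_match: float = 0.0
    rank: int = 0
    tiers: Optional[TierAssignment] = None
    phase_unknown: bool = False

    def __post_init__(self) -> None:
        self.variants = tuple(self.variants)
        _check(self.moi_model in {"AD", "AR_hom", "AR_compound_het", "XL"}, "bad moi_model")
        _check(self.acmg_class in {"pathogenic", "likely_pathogenic", "VUS"}, "bad acmg_class")
        _check(self.phenotype_match >= 0, "phenotype_match < 0")
        if self.moi_model == "AR_compound_het":
            _check(len(self.variants) == 2, "compound het needs exactly 2 variants")
            a, b = self.variants
            _check(a.annotation.gene == b.annotation.gene, "compound het across genes")
            _check((a.chrom, a.pos) != (b.chrom, b.pos), "compound het at one position")
            _check(a.zygosity == b.zygosity == "het", "compound het variants must be het")
        else:
            _check(len(self.variants) == 1, f"{self.moi_model} needs exactly 1 variant")

    @property
    def is_diagnostic(self) -> bool:
        return self.acmg_class in {"pathogenic", "likely_pathogenic"}


@dataclass
class ThresholdConfig:
    """Every numeric cutoff used by the pipeline, with published defaults."""

    rare_freq_max: float = 0.05
    sv_support_min: int = 20
    reciprocal_overlap_min: float = 0.50
    segdup_cover_exclude: float = 0.70
    cnv_freq_exclude: float = 0.03
    breakpoint_window: int = 10_000
    quality_min_depth: int = 20
    quality_min_gq: float = 30.0
    quality_tier2_depth: int = 10
    het_af_band: tuple = (0.3, 0.7)
    hom_af_min: float = 0.85
    splice_delta_min: float = 0.1
    conservation_high: float = 2.0
    merge_gap_max: int = 10_000

    def __post_init__(self) -> None:
        for name in ("rare_freq_max", "reciprocal_overlap_min", "segdup_cover_exclude", "cnv_freq_exclude"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name}={v} outside [0,1]")
        _check(self.sv_support_min >= 0, "sv_support_min < 0")
        _check(self.breakpoint_window >= 0, "breakpoint_window < 0")


# --------------------------------------------------------------------------
# unbalanced variants


@dataclass
class CnvRecord:
    """Unified unbalanced-variant record (read-depth, junction or array).

    Annotation fields (``control_freq``, ``dgv_overlap``, ``genes_hit``,
    ``exons_hit``, ``segdup_cover``, ``classification``) are filled by the
    annotators in :mod:`wgsdx.cnv`; parsers leave them at their defaults.
    """

    case_id: str
    chrom: str
    start: int
    end: int
    state: str  # gain | loss
    source: str  # read_depth | junction | microarray
    copy_state: Optional[int] = None
    support: Optional[int] = None
    control_freq: float = 0.0
    dgv_overlap: bool = False
    genes_hit: frozenset = frozenset()
    exons_hit: bool = False
    segdup_cover: float = 0.0
    classification: Optional[str] = None

    def __post_init__(self) -> None:
        _check(self.start < self.end, f"empty interval [{self.start},{self.end})")
        _check(self.state in {"gain", "loss"}, f"bad state {self.state!r}")
        _check(self.source in {"read_depth", "junction", "microarray"}, "bad source")
        _check(0.0 <= self.control_freq <= 1.0, "control_freq outside [0,1]")
        _check(0.0 <= self.segdup_cover <= 1.0, "segdup_cover outside [0,1]")
        self.genes_hit = frozenset(self.genes_hit)

    @property
    def interval(self) -> tuple:
        return (self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        return (self.case_id, self.chrom, self.start, self.end, self.state, self.source)

    def evolve(self, **kw) -> "CnvRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class SvEvent:
    """Raw junction-based SV event prior to filtering."""

    case_id: str
    type: str  # deletion | tandem_duplication | other
    chrom: str
    start: int
    end: int
    support: int

    def __post_init__(self) -> None:
        _check(self.start < self.end, "empty SV interval")
        _check(self.support >= 0, "negative mate-pair support")


@dataclass(frozen=True)
class CmaCall:
    """Array CNV call with probe-bounded breakpoints (0-based half-open)."""

    case_id: str
    chrom: str
    inner_start: int
    inner_end: int
    outer_start: int
    outer_end: int
    state: str
    classification: str = "VUS"

    def __post_init__(self) -> None:
        _check(
            self.outer_start <= self.inner_start < self.inner_end <= self.outer_end,
            f"CMA boundary order violated on {self.chrom}: "
            f"outer [{self.outer_start},{self.outer_end}] inner [{self.inner_start},{self.inner_end}]",
        )
        _check(self.state in {"gain", "loss"}, f"bad state {self.state!r}")
        _check(
            self.classification in {"pathogenic", "VUS_likely_pathogenic", "VUS", "benign"},
            f"bad classification {self.classification!r}",
        )

    @property
    def outer_interval(self) -> tuple:
        return (self.chrom, self.outer_start, self.outer_end)

    @property
    def clinically_significant(self) -> bool:
        return self.classification in {"pathogenic", "VUS_likely_pathogenic"}


@dataclass
class ConcordanceResult:
    matched_pairs: list  # of (CmaCall, CnvRecord)
    unmatched_cma: list  # of CmaCall
    within_boundary_count: int = 0
    within_window_count: int = 0

    def __post_init__(self) -> None:
        _check(
            self.within_boundary_count <= self.within_window_count <= len(self.matched_pairs),
            "boundary/window counts inconsistent with matched pairs",
        )

    @property
    def n_cma(self) -> int:
        return len(self.matched_pairs) + len(self.unmatched_cma)

    @property
    def detected_rate(self) -> float:
        return len(self.matched_pairs) / self.n_cma if self.n_cma else 0.0

    @property
    def within_boundary_rate(self) -> float:
        n = len(self.matched_pairs)
        return self.within_boundary_count / n if n else 0.0

    @property
    def within_window_rate(self) -> float:
        n = len(self.matched_pairs)
        return self.within_window_count / n if n else 0.0


@dataclass(frozen=True)
class GeneModel:
    """Gene with transcript span and exon intervals, 0-based half-open."""

    gene: str
    chrom: str
    start: int
    end: int
    exons: tuple = ()

    def __post_init__(self) -> None:
        _check(self.start < self.end, f"{self.gene}: empty transcript span")
        for (s, e) in self.exons:
            _check(self.start <= s < e <= self.end, f"{self.gene}: exon [{s},{e}) outside span")


# --------------------------------------------------------------------------
# secondary findings


@dataclass(frozen=True)
class GenePanelEntry:
    gene: str
    inheritance: str
    condition: str = ""

    def __post_init__(self) -> None:
        _check(self.inheritance in {"AD", "AR", "AD/AR"}, f"bad inheritance {self.inheritance!r}")


@dataclass
class SecondaryFinding:
    case_id: str
    variant: SequenceVariant
    gene: str
    basis: str  # LoF | asserted_pathogenic
    returnable: bool

    def __post_init__(self) -> None:
        _check(self.basis in {"LoF", "asserted_pathogenic"}, f"bad basis {self.basis!r}")


# --------------------------------------------------------------------------
# cohort


@dataclass
class Case:
    case_id: str
    sex: str = "F"
    age: float = 0.0
    hpo_terms: frozenset = frozenset()
    consent_secondary: bool = True
    consanguinity: bool = False
    tests_ordered: tuple = ()

    def __post_init__(self) -> None:
        _check(self.sex in {"M", "F"}, f"bad sex {self.sex!r}")
        self.hpo_terms = frozenset(self.hpo_terms)


@dataclass
class DiagnosisRecord:
    case_id: str
    locus_ids: frozenset
    variant_types: frozenset = frozenset({"SNV"})
    moi: str = "AD"
    origin: str = "NA"
    category: Optional[int] = None

    def __post_init__(self) -> None:
        self.locus_ids = frozenset(self.locus_ids)
        self.variant_types = frozenset(self.variant_types)
        _check(len(self.locus_ids) >= 1, "locus_ids empty")
        _check(self.variant_types <= {"CNV", "SNV"}, "bad variant_types")
        _check(self.moi in {"AD", "AR", "both"}, f"bad moi {self.moi!r}")
        _check(
            self.origin in {"de_novo", "maternal", "paternal", "maternal+paternal", "NA"},
            f"bad origin {self.origin!r}",
        )
        if self.category is not None:
            _check(self.category in {1, 2, 3}, "category must be 1, 2 or 3")


@dataclass
class YieldComparison:
    n1: int
    x1: int
    n2: int
    x2: int
    chi2: float
    p: float
    continuity: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        _check(0 <= self.x1 <= self.n1 and 0 <= self.x2 <= self.n2, "counts inconsistent")
        _check(0.0 <= self.p <= 1.0, "p outside [0,1]")
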