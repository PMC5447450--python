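import pytest

from wgsdx.models import AnnotationBundle, DiseaseGeneEntry, SequenceVariant, ThresholdConfig
from wgsdx.ontology import build_mini_hpo
from wgsdx.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def mini_hpo():
    return build_mini_hpo()


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 10-case cohort at 1/10 scale, shared across test modules."""
    cfg = SimulationConfig(cohort_n=10, seed=11, scale=0.1)
    resources, bundles = generate_cohort(cfg)
    return cfg, resources, bundles


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_cohort):
    from wgsdx.io import write_cohort_dir

    cfg, resources, bundles = small_cohort
    d = tmp_path_factory.mktemp("cohort") / "run"
    write_cohort_dir(d, cfg, resources, bundles)
    return d


def make_variant(
    case_id="C1",
    chrom="chr1",
    pos=1000,
    ref="A",
    alt="T",
    zygosity="het",
    read_depth=50,
    genotype_quality=60.0,
    allele_fraction=0.5,
    **ann,
):
    """Terse annotated-variant builder for unit tests."""
    defaults = dict(
        gene="GENE1",
        effect_class="missense",
        pop_freqs={"db": 0.001},
        damaging_predictor_count=0,
        predictor_total=0,
    )
    defaults.update(ann)
    return SequenceVariant(
        case_id=case_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        zygosity=zygosity,
        read_depth=read_depth,
        genotype_quality=genotype_quality,
        allele_fraction=allele_fraction,
        annotation=AnnotationBundle(**defaults),
    )


def make_disease_gene(gene="GENE1", modes=("AR",), lof=True, terms=()):
    return DiseaseGeneEntry(
        gene=gene,
        inheritance_modes=frozenset(modes),
        condition="test condition",
        phenotype_terms=frozenset(terms),
        lof_mechanism=lof,
    )
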