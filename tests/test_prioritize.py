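import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgsdx.models import ThresholdConfig
from wgsdx.prioritize import (
    MissingAnnotationError,
    acmg_classify_simplified,
    assign_inheritance_category,
    assign_tiers,
    classify_reported_pathogenicity,
    count_rare_damaging,
    filter_rare_functional,
    majority_damaging,
    rank_candidates,
)

from conftest import make_disease_gene, make_variant


class TestFilterRareFunctional:
    def test_rare_missense_retained(self, thresholds):
        v = make_variant(pop_freqs={"db": 0.001})
        assert filter_rare_functional([v], thresholds) == [v]

    def test_common_missense_removed(self, thresholds):
        v = make_variant(pop_freqs={"db": 0.06})
        assert filter_rare_functional([v], thresholds) == []

    def test_max_across_databases(self, thresholds):
        v = make_variant(pop_freqs={"a": 0.001, "b": 0.2})
        assert filter_rare_functional([v], thresholds) == []

    def test_boundary_exactly_at_threshold_removed(self, thresholds):
        v = make_variant(pop_freqs={"db": 0.05})
        assert filter_rare_functional([v], thresholds) == []

    def test_intronic_without_splice_delta_removed(self, thresholds):
        v = make_variant(effect_class="intronic", splice_delta=None)
        assert filter_rare_functional([v], thresholds) == []

    def test_intronic_with_damaging_splice_delta_retained(self, thresholds):
        v = make_variant(effect_class="intronic", splice_delta=0.4)
        assert filter_rare_functional([v], thresholds) == [v]

    def test_synonymous_needs_splice_delta(self, thresholds):
        plain = make_variant(effect_class="synonymous")
        spliceful = make_variant(effect_class="synonymous", splice_delta=0.3)
        assert filter_rare_functional([plain, spliceful], thresholds) == [spliceful]

    def test_missing_annotation_rejected(self, thresholds):
        v = make_variant()
        v.annotation = None
        with pytest.raises(MissingAnnotationError, match="chr1:1000"):
            filter_rare_functional([v], thresholds)

    def test_order_stable_and_input_unmodified(self, thresholds):
        vs = [make_variant(pos=p) for p in (30, 10, 20)]
        out = filter_rare_functional(vs, thresholds)
        assert [v.pos for v in out] == [30, 10, 20]
        assert len(vs) == 3

    def test_idempotent(self, thresholds):
        vs = [make_variant(pos=p, pop_freqs={"db": f}) for p, f in [(1, 0.0), (2, 0.1), (3, 0.04)]]
        once = filter_rare_functional(vs, thresholds)
        assert filter_rare_functional(once, thresholds) == once

    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    def test_threshold_monotonicity(self, freq, thr_low):
        """Raising rare_freq_max never removes a retained variant."""
        v = make_variant(pop_freqs={"db": freq})
        lo = ThresholdConfig(rare_freq_max=min(thr_low, 0.9))
        hi = ThresholdConfig(rare_freq_max=min(thr_low, 0.9) + 0.1)
        kept_lo = filter_rare_functional([v], lo)
        kept_hi = filter_rare_functional([v], hi)
        assert set(id(x) for x in kept_lo) <= set(id(x) for x in kept_hi)


class TestAssignTiers:
    def test_lof_in_disease_gene_absent_everywhere(self, thresholds):
        v = make_variant(effect_class="frameshift", pop_freqs={}, disease_gene=make_disease_gene())
        t = assign_tiers(v, thresholds)
        assert (t.impact_tier, t.disease_tier, t.frequency_tier) == (1, 1, 1)

    def test_synonymous_lowest_impact(self, thresholds):
        v = make_variant(effect_class="synonymous", splice_delta=None)
        assert assign_tiers(v, thresholds).impact_tier == 3

    @pytest.mark.parametrize("damaging,expected", [(4, 2), (1, 3)])
    def test_missense_majority_vote(self, thresholds, damaging, expected):
        v = make_variant(damaging_predictor_count=damaging, predictor_total=5)
        assert assign_tiers(v, thresholds).impact_tier == expected

    def test_majority_vote_matches_enumeration_oracle(self):
        """Exhaustive oracle over every predictor pattern, total <= 6."""
        for total in range(0, 7):
            for pattern in itertools.product([0, 1], repeat=total):
                damaging = sum(pattern)
                oracle = total > 0 and damaging >= total / 2
                assert majority_damaging(damaging, total) == oracle

    def test_quality_tiers(self, thresholds):
        good = make_variant(read_depth=30, genotype_quality=50, allele_fraction=0.5)
        mid = make_variant(read_depth=12, genotype_quality=10, allele_fraction=0.9)
        bad = make_variant(read_depth=5, genotype_quality=5, allele_fraction=0.9)
        assert assign_tiers(good, thresholds).quality_tier == 1
        assert assign_tiers(mid, thresholds).quality_tier == 2
        assert assign_tiers(bad, thresholds).quality_tier == 3

    def test_hom_allele_fraction_band(self, thresholds):
        v = make_variant(zygosity="hom", allele_fraction=0.95, read_depth=40)
        assert assign_tiers(v, thresholds).quality_tier == 1

    def test_frequency_bands(self, thresholds):
        for freq, tier in [(0.0, 1), (0.0005, 2), (0.005, 3), (0.03, 4)]:
            v = make_variant(pop_freqs={"db": freq} if freq else {})
            assert assign_tiers(v, thresholds).frequency_tier == tier

    def test_conservation_strengthens_missense(self, thresholds):
        v = make_variant(conservation_scores={"phylop_like": 3.5})
        assert assign_tiers(v, thresholds).impact_tier == 2

    def test_pure_function(self, thresholds):
        v = make_variant()
        assert assign_tiers(v, thresholds) == assign_tiers(v, thresholds)


class TestInheritance:
    def test_ar_homozygous_frameshift(self):
        dg = make_disease_gene(modes=("AR",))
        v = make_variant(effect_class="frameshift", zygosity="hom", disease_gene=dg)
        entries = assign_inheritance_category([v], dg, "F")
        assert entries == [((v,), "AR_hom")]

    def test_ar_two_het_compound_candidate(self):
        dg = make_disease_gene(modes=("AR",))
        v1 = make_variant(pos=100, zygosity="het", disease_gene=dg)
        v2 = make_variant(pos=200, zygosity="het", disease_gene=dg)
        cats = dict()
        for vs, cat in assign_inheritance_category([v1, v2], dg, "M"):
            cats[tuple(v.pos for v in vs)] = cat
        assert cats[(100, 200)] == "AR_compound_het_candidate"

    def test_ar_single_het_is_carrier_only(self):
        dg = make_disease_gene(modes=("AR",))
        v = make_variant(zygosity="het", disease_gene=dg)
        assert assign_inheritance_category([v], dg, "F") == [((v,), "carrier_only")]

    def test_duplicate_position_never_compound(self):
        dg = make_disease_gene(modes=("AR",))
        v1 = make_variant(pos=100, alt="T", zygosity="het", disease_gene=dg)
        v2 = make_variant(pos=100, alt="G", zygosity="het", disease_gene=dg)
        entries = assign_inheritance_category([v1, v2], dg, "F")
        assert not [e for e in entries if len(e[0]) == 2]
        assert {cat for _, cat in entries} == {"carrier_only"}

    def test_ad_het(self):
        dg = make_disease_gene(modes=("AD",))
        v = make_variant(zygosity="het", disease_gene=dg)
        assert assign_inheritance_category([v], dg, "F")[0][1] == "AD_het"

    def test_xl_hemizygous_male_only(self):
        dg = make_disease_gene(gene="XG", modes=("XL",))
        v = make_variant(chrom="chrX", zygosity="hemizygous", disease_gene=dg)
        assert assign_inheritance_category([v], dg, "M")[0][1] == "XL_hemizygous"

    def test_hom_in_ad_only_gene_incompatible(self):
        dg = make_disease_gene(modes=("AD",))
        v = make_variant(zygosity="hom", disease_gene=dg)
        assert assign_inheritance_category([v], dg, "F")[0][1] == "incompatible"

    def test_novel_gene_no_restriction(self):
        v = make_variant(zygosity="hom", disease_gene=None)
        assert assign_inheritance_category([v], None, "F")[0][1] == "AR_hom"


class TestReportedPathogenicity:
    def test_single_source_pathogenic(self):
        v = make_variant(assertions={"srcA": "pathogenic"})
        assert classify_reported_pathogenicity(v) == "asserted_pathogenic"

    def test_conflict(self):
        v = make_variant(assertions={"srcA": "pathogenic", "srcB": "benign"})
        assert classify_reported_pathogenicity(v) == "conflicting"

    def test_unreported_is_novel(self):
        v = make_variant(assertions={})
        assert classify_reported_pathogenicity(v) == "novel"

    def test_likely_pathogenic(self):
        v = make_variant(assertions={"srcA": "likely_pathogenic"})
        assert classify_reported_pathogenicity(v) == "asserted_likely"


class TestAcmgRuleTable:
    """Enumerate every combination of the rule-table inputs and compare to an
    independently coded oracle of the documented rules."""

    def _oracle(self, is_lof, lof_gene, absent, asserted, consensus, moi_ok, pheno):
        if is_lof and lof_gene and absent:
            return "pathogenic"
        if asserted == "pathogenic" and (is_lof or (not is_lof and consensus)):
            return "pathogenic"
        if asserted == "likely" and moi_ok:
            return "likely_pathogenic"
        if asserted == "none" and not is_lof and consensus and moi_ok and pheno:
            return "likely_pathogenic"
        return "VUS"

    def test_exhaustive(self):
        for is_lof, lof_gene, absent, asserted, consensus, moi_ok, pheno in itertools.product(
            [True, False], [True, False], [True, False],
            ["pathogenic", "likely", "none"], [True, False], [True, False], [True, False],
        ):
            dg = make_disease_gene(lof=lof_gene)
            assertions = (
                {"s": "pathogenic"} if asserted == "pathogenic"
                else {"s": "likely_pathogenic"} if asserted == "likely" else {}
            )
            v = make_variant(
                effect_class="nonsense" if is_lof else "missense",
                pop_freqs={} if absent else {"db": 0.001},
                assertions=assertions,
                damaging_predictor_count=4 if consensus else 0,
                predictor_total=4,
                conservation_scores={},
                disease_gene=dg,
            )
            got = acmg_classify_simplified(
                v, "AR_hom" if moi_ok else "carrier_only", 0.5 if pheno else 0.0
            )
            want = self._oracle(is_lof, lof_gene, absent, asserted, consensus, moi_ok, pheno)
            assert got == want, (is_lof, lof_gene, absent, asserted, consensus, moi_ok, pheno)


class TestRanking:
    def test_asserted_lof_outranks_novel_missense(self, mini_hpo):
        dg = make_disease_gene(modes=("AD",))
        strong = make_variant(
            pos=500, effect_class="nonsense", pop_freqs={},
            assertions={"s": "pathogenic"}, disease_gene=dg,
        )
        weak = make_variant(
            pos=100, gene="GENE2", damaging_predictor_count=4, predictor_total=4,
            disease_gene=make_disease_gene(gene="GENE2", modes=("AD",)),
        )
        out = rank_candidates([weak, strong], "F", [], mini_hpo)
        assert out[0].variants[0].pos == 500

    def test_tie_broken_by_coordinate(self, mini_hpo):
        dg1 = make_disease_gene(gene="A1", modes=("AD",))
        dg2 = make_disease_gene(gene="A2", modes=("AD",))
        v1 = make_variant(pos=2000, gene="A1", effect_class="nonsense", pop_freqs={}, disease_gene=dg1)
        v2 = make_variant(pos=1000, gene="A2", effect_class="nonsense", pop_freqs={}, disease_gene=dg2)
        out = rank_candidates([v1, v2], "F", [], mini_hpo)
        assert [c.variants[0].pos for c in out] == [1000, 2000]

    def test_carrier_never_a_candidate(self, mini_hpo):
        dg = make_disease_gene(modes=("AR",))
        v = make_variant(zygosity="het", effect_class="frameshift", pop_freqs={}, disease_gene=dg)
        assert rank_candidates([v], "F", [], mini_hpo) == []

    def test_planted_ar_hom_rank_one(self, mini_hpo):
        dg = make_disease_gene(modes=("AR",), terms=["HP:90010101"])
        planted = make_variant(
            pos=777, effect_class="nonsense", zygosity="hom", pop_freqs={}, disease_gene=dg,
        )
        noise = [
            make_variant(pos=10, gene="N1", pop_freqs={"db": 0.01}),
            make_variant(pos=20, gene="N2", effect_class="synonymous"),
        ]
        out = rank_candidates(noise + [planted], "F", ["HP:90010101"], mini_hpo)
        assert out[0].variants[0].pos == 777
        assert out[0].acmg_class == "pathogenic"
        assert out[0].moi_model == "AR_hom"

    def test_compound_het_pair_candidate(self, mini_hpo):
        dg = make_disease_gene(modes=("AR",))
        v1 = make_variant(pos=100, zygosity="het", assertions={"s": "pathogenic"},
                          damaging_predictor_count=4, predictor_total=4, disease_gene=dg)
        v2 = make_variant(pos=200, zygosity="het", assertions={"s": "pathogenic"},
                          damaging_predictor_count=4, predictor_total=4, disease_gene=dg)
        out = rank_candidates([v1, v2], "F", [], mini_hpo)
        assert len(out) == 1
        c = out[0]
        assert c.moi_model == "AR_compound_het" and len(c.variants) == 2
        assert c.phase_unknown and c.acmg_class == "pathogenic"


class TestCountRareDamaging:
    def test_zero_for_empty(self, thresholds):
        assert count_rare_damaging([], thresholds) == 0

    def test_counts_lof_and_damaging_missense(self, thresholds):
        vs = [
            make_variant(pos=1, effect_class="nonsense", pop_freqs={}),
            make_variant(pos=2, damaging_predictor_count=4, predictor_total=4),
            make_variant(pos=3),  # missense, no consensus -> tier 3
            make_variant(pos=4, pop_freqs={"db": 0.3}),  # common
        ]
        assert count_rare_damaging(vs, thresholds) == 2
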