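import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgsdx.cnv import (
    annotate_cnv_frequency,
    annotate_gene_exon_overlap,
    annotate_segdup_cover,
    breakpoint_concordance,
    classify_cnv,
    coverage_fraction,
    dataset_frequencies,
    filter_for_concordance,
    filter_read_depth_segments,
    filter_sv_events,
    interval_union_length,
    match_cma_wgs,
    merge_fragmented_segments,
    reciprocal_overlap,
)
from wgsdx.models import CmaCall, CnvRecord, GeneModel, SvEvent, ThresholdConfig

from conftest import make_disease_gene


def rec(case="C1", chrom="chr1", start=0, end=1000, state="loss", source="read_depth", **kw):
    return CnvRecord(case_id=case, chrom=chrom, start=start, end=end, state=state, source=source, **kw)


def brute_force_ro(a, b):
    """Base-wise counting oracle for reciprocal overlap (lengths <= 10 kb)."""
    if a[0] != b[0]:
        return 0.0
    sa = set(range(a[1], a[2]))
    sb = set(range(b[1], b[2]))
    inter = len(sa & sb)
    if inter == 0:
        return 0.0
    return min(inter / len(sa), inter / len(sb))


class TestReciprocalOverlap:
    def test_identical(self):
        assert reciprocal_overlap(("chr1", 0, 100), ("chr1", 0, 100)) == 1.0

    def test_half(self):
        assert reciprocal_overlap(("chr1", 0, 1000), ("chr1", 500, 1500)) == 0.5

    def test_disjoint_and_cross_chromosome(self):
        assert reciprocal_overlap(("chr1", 0, 10), ("chr1", 10, 20)) == 0.0
        assert reciprocal_overlap(("chr1", 0, 10), ("chr2", 0, 10)) == 0.0

    def test_symmetry_and_range(self):
        a, b = ("chr1", 5, 500), ("chr1", 100, 900)
        assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)
        assert 0.0 <= reciprocal_overlap(a, b) <= 1.0

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            s1 = int(rng.integers(0, 5000))
            s2 = int(rng.integers(0, 5000))
            a = ("chr1", s1, s1 + int(rng.integers(1, 5000)))
            b = ("chr1", s2, s2 + int(rng.integers(1, 5000)))
            assert reciprocal_overlap(a, b) == pytest.approx(brute_force_ro(a, b))

    @given(
        st.integers(0, 3000), st.integers(1, 3000),
        st.integers(0, 3000), st.integers(1, 3000),
    )
    @settings(max_examples=100)
    def test_property_matches_oracle(self, s1, l1, s2, l2):
        a, b = ("chr1", s1, s1 + l1), ("chr1", s2, s2 + l2)
        assert reciprocal_overlap(a, b) == pytest.approx(brute_force_ro(a, b))


class TestIntervalHelpers:
    def test_union_length(self):
        assert interval_union_length([(0, 10), (5, 15), (20, 25)]) == 20

    def test_coverage_fraction_oracle(self):
        rng = np.random.default_rng(7)
        track = []
        for _ in range(20):
            s = int(rng.integers(0, 9000))
            track.append(("chr1", s, s + int(rng.integers(1, 800))))
        target = ("chr1", 2000, 7000)
        covered_bases = set()
        for c, s, e in track:
            covered_bases |= set(range(max(2000, s), min(7000, e)))
        assert coverage_fraction(target, track) == pytest.approx(len(covered_bases) / 5000)


class TestParseFilters:
    def test_diploid_dropped(self, thresholds):
        r = rec(copy_state=2, state="loss")
        assert filter_read_depth_segments([(r, False)], thresholds) == []

    def test_chry_dropped(self, thresholds):
        r = rec(chrom="chrY", copy_state=1)
        assert filter_read_depth_segments([(r, False)], thresholds) == []

    def test_hypervariable_dropped(self, thresholds):
        r = rec(copy_state=3, state="gain")
        assert filter_read_depth_segments([(r, True)], thresholds) == []

    def test_gain_retained(self, thresholds):
        r = rec(chrom="chr8", copy_state=3, state="gain")
        assert filter_read_depth_segments([(r, False)], thresholds) == [r]

    @pytest.mark.parametrize("support,kept", [(20, True), (19, False)])
    def test_sv_support_threshold(self, thresholds, support, kept):
        ev = SvEvent(case_id="C1", type="deletion", chrom="chr1", start=0, end=500, support=support)
        out = filter_sv_events([ev], thresholds)
        assert bool(out) == kept
        if kept:
            assert out[0].state == "loss" and out[0].source == "junction"

    def test_inversion_dropped_regardless_of_support(self, thresholds):
        ev = SvEvent(case_id="C1", type="other", chrom="chr1", start=0, end=500, support=100)
        assert filter_sv_events([ev], thresholds) == []

    def test_filters_idempotent_and_commute(self, thresholds):
        rows = [
            (rec(copy_state=1), False),
            (rec(start=5000, end=9000, copy_state=2), False),
            (rec(start=20000, end=30000, copy_state=3, state="gain"), True),
        ]
        once = filter_read_depth_segments(rows, thresholds)
        again = filter_read_depth_segments([(r, False) for r in once], thresholds)
        assert again == once


class TestMerge:
    def test_small_gap_merged(self):
        a = rec(start=0, end=10_000)
        b = rec(start=11_000, end=20_000)
        out = merge_fragmented_segments([a, b], gap_max=10_000)
        assert len(out) == 1 and (out[0].start, out[0].end) == (0, 20_000)

    def test_large_gap_unmerged(self):
        a = rec(start=0, end=10_000)
        b = rec(start=21_001, end=30_000)
        assert len(merge_fragmented_segments([a, b], gap_max=10_000)) == 2

    def test_state_mismatch_unmerged(self):
        a = rec(start=0, end=10_000, state="loss")
        b = rec(start=11_000, end=20_000, state="gain")
        assert len(merge_fragmented_segments([a, b], gap_max=10_000)) == 2

    def test_idempotent(self):
        recs = [rec(start=s, end=s + 5_000) for s in (0, 6_000, 50_000)]
        once = merge_fragmented_segments(recs, 10_000)
        assert merge_fragmented_segments(once, 10_000) == once

    def test_covered_bases_only_grow_by_gaps(self):
        recs = [rec(start=0, end=10_000), rec(start=12_000, end=22_000)]
        out = merge_fragmented_segments(recs, 10_000)
        before = sum(r.length for r in recs)
        after = sum(r.length for r in out)
        assert after == before + 2_000  # exactly the filled gap


class TestFrequencyAnnotation:
    def test_three_of_hundred_controls(self, thresholds):
        target = rec()
        controls = {f"S{i}": [] for i in range(100)}
        for i in range(3):
            controls[f"S{i}"] = [rec(case=f"S{i}")]
        out = annotate_cnv_frequency([target], controls, [], thresholds)
        assert out[0].control_freq == pytest.approx(0.03)

    def test_below_ro_threshold_not_counted(self, thresholds):
        target = rec(start=0, end=1000)
        # 49% reciprocal overlap against every control variant
        controls = {f"S{i}": [rec(case=f"S{i}", start=510, end=1510)] for i in range(10)}
        out = annotate_cnv_frequency([target], controls, [], thresholds)
        assert out[0].control_freq == 0.0

    def test_state_mismatch_not_counted(self, thresholds):
        target = rec(state="loss")
        controls = {"S0": [rec(case="S0", state="gain")]}
        out = annotate_cnv_frequency([target], controls, [], thresholds)
        assert out[0].control_freq == 0.0

    def test_empty_controls_warns(self, thresholds):
        with pytest.warns(UserWarning, match="empty control set"):
            out = annotate_cnv_frequency([rec()], {}, [], thresholds)
        assert out[0].control_freq == 0.0

    def test_dgv_overlap_flag(self, thresholds):
        dgv = [rec(case="DGV")]
        out = annotate_cnv_frequency([rec()], {"S0": []}, dgv, thresholds)
        assert out[0].dgv_overlap

    def test_planted_common_cnv_recovered(self, small_cohort, thresholds):
        """Pool CNVs planted in synthetic controls are recovered at their
        planted rate within binomial error."""
        cfg, resources, _ = small_cohort
        n = len(resources.control_cnvs)
        for chrom, s, e, state in resources.common_cnv_pool[:5]:
            probe = rec(case="probe", chrom=chrom, start=s, end=e, state=state)
            out = annotate_cnv_frequency([probe], resources.control_cnvs, [], thresholds)
            carriers = sum(
                any(
                    reciprocal_overlap((chrom, s, e), c.interval) >= 0.5 and c.state == state
                    for c in recs
                )
                for recs in resources.control_cnvs.values()
            )
            assert out[0].control_freq == pytest.approx(carriers / n)


class TestGeneExonOverlap:
    GENES = [
        GeneModel("GA", "chr1", 1000, 9000, exons=((1000, 1200), (8000, 8200))),
        GeneModel("GB", "chr1", 20_000, 30_000, exons=((20_000, 20_300),)),
    ]

    def test_intronic_cnv(self):
        out = annotate_gene_exon_overlap([rec(start=2000, end=7000)], self.GENES)
        assert out[0].genes_hit == {"GA"} and not out[0].exons_hit

    def test_spanning_two_genes_exonic(self):
        out = annotate_gene_exon_overlap([rec(start=500, end=25_000)], self.GENES)
        assert out[0].genes_hit == {"GA", "GB"} and out[0].exons_hit

    def test_intergenic(self):
        out = annotate_gene_exon_overlap([rec(start=10_000, end=12_000)], self.GENES)
        assert out[0].genes_hit == frozenset() and not out[0].exons_hit


class TestClassify:
    SYNDROMIC = [("chr22", 18_000_000, 21_500_000, "loss")]

    def test_syndromic_loss_pathogenic(self, thresholds):
        r = rec(chrom="chr22", start=18_100_000, end=21_400_000)
        assert classify_cnv(r, self.SYNDROMIC, {}, (), thresholds) == "pathogenic"

    def test_dgv_overlap_benign(self, thresholds):
        r = rec(dgv_overlap=True)
        assert classify_cnv(r, [], {}, (), thresholds) == "benign"

    def test_common_in_controls_benign(self, thresholds):
        r = rec(control_freq=0.05)
        assert classify_cnv(r, [], {}, (), thresholds) == "benign"

    def test_rare_exonic_gain_non_disease_gene_vus(self, thresholds):
        r = rec(state="gain", genes_hit={"XYZ"}, exons_hit=True)
        assert classify_cnv(r, [], {}, (), thresholds) == "VUS"

    def test_exonic_loss_of_dominant_gene_likely_pathogenic(self, thresholds):
        dg = {"D1": make_disease_gene(gene="D1", modes=("AD",))}
        r = rec(genes_hit={"D1"}, exons_hit=True)
        assert classify_cnv(r, [], dg, (), thresholds) == "likely_pathogenic"

    def test_dosage_sensitive_gain(self, thresholds):
        dg = {"D1": make_disease_gene(gene="D1", modes=("AD",))}
        r = rec(state="gain", genes_hit={"D1"}, exons_hit=True)
        assert classify_cnv(r, [], dg, ("D1",), thresholds) == "likely_pathogenic"
        assert classify_cnv(r, [], dg, (), thresholds) == "VUS"


class TestConcordanceFilter:
    def test_segdup_seventy_percent_excluded(self, thresholds):
        r = rec(start=0, end=10_000)
        track = [("chr1", 0, 7_000)]
        assert filter_for_concordance([r], track, {}, thresholds) == []

    def test_segdup_sixtynine_retained(self, thresholds):
        r = rec(start=0, end=10_000)
        track = [("chr1", 0, 6_900)]
        out = filter_for_concordance([r], track, {r.key: 0.029}, thresholds)
        assert len(out) == 1 and out[0].segdup_cover == pytest.approx(0.69)

    def test_common_in_either_dataset_excluded(self, thresholds):
        r = rec()
        assert filter_for_concordance([r], [], {r.key: 0.03}, thresholds) == []

    def test_idempotent(self, thresholds):
        recs = [rec(), rec(start=50_000, end=60_000)]
        track = [("chr1", 50_000, 58_000)]
        once = filter_for_concordance(recs, track, {}, thresholds)
        assert filter_for_concordance(once, track, {}, thresholds) == once

    def test_self_excluded_from_dataset_frequency(self, thresholds):
        recs = [rec(case=f"C{i}", start=0, end=1000) for i in range(3)]
        freqs = dataset_frequencies(recs, 10, thresholds)
        assert freqs[recs[0].key] == pytest.approx(0.2)  # 2 other carriers / 10


def cma(case="C1", chrom="chr1", outer=(95_000, 206_000), inner=(100_000, 200_000),
        state="loss", classification="pathogenic"):
    return CmaCall(case_id=case, chrom=chrom, inner_start=inner[0], inner_end=inner[1],
                   outer_start=outer[0], outer_end=outer[1], state=state,
                   classification=classification)


class TestMatchCmaWgs:
    def test_identical_coordinates_matched(self, thresholds):
        call = cma()
        wgs = rec(start=95_000, end=206_000)
        result = match_cma_wgs([call], [wgs], thresholds)
        assert result.matched_pairs == [(call, wgs)]

    def test_state_mismatch_unmatched(self, thresholds):
        call = cma(state="loss")
        wgs = rec(start=95_000, end=206_000, state="gain")
        result = match_cma_wgs([call], [wgs], thresholds)
        assert result.unmatched_cma == [call]

    def test_case_mismatch_unmatched(self, thresholds):
        call = cma(case="C1")
        wgs = rec(case="C2", start=95_000, end=206_000)
        assert match_cma_wgs([call], [wgs], thresholds).unmatched_cma == [call]

    def test_greatest_overlap_wins(self, thresholds):
        call = cma()
        close = rec(start=95_500, end=205_000)
        far = rec(start=120_000, end=206_000)
        result = match_cma_wgs([call], [far, close], thresholds)
        assert result.matched_pairs[0][1] is close

    def test_junction_records_ignored(self, thresholds):
        call = cma()
        j = rec(start=95_000, end=206_000, source="junction")
        assert match_cma_wgs([call], [j], thresholds).unmatched_cma == [call]


class TestBreakpointConcordance:
    def test_exactly_at_inner_boundaries(self, thresholds):
        call = cma()
        wgs = rec(start=100_000, end=200_000)
        res = breakpoint_concordance(match_cma_wgs([call], [wgs], thresholds), thresholds)
        assert res.within_boundary_count == 1 and res.within_window_count == 1

    def test_9999_outside_outer_within_window_only(self, thresholds):
        call = cma()
        wgs = rec(start=95_000 - 9_999, end=200_000)
        res = breakpoint_concordance(match_cma_wgs([call], [wgs], thresholds), thresholds)
        assert res.within_boundary_count == 0 and res.within_window_count == 1

    def test_10001_outside_fails_both(self, thresholds):
        call = cma()
        wgs = rec(start=95_000 - 10_001, end=200_000)
        res = breakpoint_concordance(match_cma_wgs([call], [wgs], thresholds), thresholds)
        assert res.within_boundary_count == 0 and res.within_window_count == 0

    def test_boundary_implies_window(self, small_cohort, thresholds):
        cfg, resources, bundles = small_cohort
        calls = [c for b in bundles for c in b.cma_calls]
        wgs = [
            r
            for b in bundles
            for r in merge_fragmented_segments(
                filter_read_depth_segments(b.cnv_segments, thresholds), thresholds.merge_gap_max
            )
        ]
        res = breakpoint_concordance(match_cma_wgs(calls, wgs, thresholds), thresholds)
        assert res.within_boundary_count <= res.within_window_count <= len(res.matched_pairs)
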