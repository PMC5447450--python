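"""Read-depth CNV and junction SV filtering, annotation, classification and
the microarray-vs-sequencing concordance procedure.

All intervals are 0-based half-open. Reciprocal overlap — the workhorse
equivalence criterion — is implemented directly here because the exact
definition (min of the two mutual fractions) is load-bearing for the
frequency annotation, the concordance matching and their tests.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple
import warnings

from .models import (
    CmaCall,
    CnvRecord,
    ConcordanceResult,
    GeneModel,
    SvEvent,
    ThresholdConfig,
)

__all__ = [
    "reciprocal_overlap",
    "interval_union_length",
    "coverage_fraction",
    "filter_read_depth_segments",
    "merge_fragmented_segments",
    "filter_sv_events",
    "annotate_cnv_frequency",
    "annotate_gene_exon_overlap",
    "annotate_segdup_cover",
    "dataset_frequencies",
    "classify_cnv",
    "filter_for_concordance",
    "match_cma_wgs",
    "breakpoint_concordance",
]

Interval = Tuple[str, int, int]  # (chrom, start, end)


# --------------------------------------------------------------------------
# interval primitives


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|); 0 for disjoint or different chromosomes."""
    if a[0] != b[0]:
        return 0.0
    inter = min(a[2], b[2]) - max(a[1], b[1])
    if inter <= 0:
        return 0.0
    return min(inter / (a[2] - a[1]), inter / (b[2] - b[1]))


def interval_union_length(intervals: Iterable[Tuple[int, int]]) -> int:
    """Total bases covered by the union of (start, end) intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def coverage_fraction(target: Interval, track: Sequence[Interval]) -> float:
    """Fraction of ``target`` covered by the union of track intervals."""
    chrom, start, end = target
    clipped = [
        (max(start, s), min(end, e))
        for c, s, e in track
        if c == chrom and min(end, e) > max(start, s)
    ]
    if not clipped:
        return 0.0
    return interval_union_length(clipped) / (end - start)


# --------------------------------------------------------------------------
# parsing-stage filters (pure record-level predicates; file IO lives in io)


def _is_y(chrom: str) -> bool:
    return chrom in {"Y", "chrY"}


def filter_read_depth_segments(
    segments: Sequence[Tuple[CnvRecord, bool]], cfg: Optional[ThresholdConfig] = None
) -> List[CnvRecord]:
    """Keep non-diploid, non-hypervariable, non-chrY read-depth segments.

    ``segments`` pairs each raw record with its hypervariable flag; state is
    derived from copy state (>2 gain, <2 loss).
    """
    out = []
    for rec, hypervariable in segments:
        if rec.copy_state == 2 or hypervariable or _is_y(rec.chrom):
            continue
        out.append(rec)
    return out


def merge_fragmented_segments(
    records: Sequence[CnvRecord], gap_max: int
) -> List[CnvRecord]:
    """Merge adjacent same-case/chrom/state fragments separated by <= gap_max bp.

    Idempotent; output sorted by (case, chrom, start). Copy state of the
    merged record is taken from the longer fragment.
    """
    groups: Dict[tuple, List[CnvRecord]] = defaultdict(list)
    for r in records:
        groups[(r.case_id, r.chrom, r.state, r.source)].append(r)
    out: List[CnvRecord] = []
    for key in sorted(groups):
        frags = sorted(groups[key], key=lambda r: (r.start, r.end))
        cur = frags[0]
        for nxt in frags[1:]:
            if nxt.start - cur.end <= gap_max:
                dominant = cur if cur.length >= nxt.length else nxt
                cur = cur.evolve(
                    start=min(cur.start, nxt.start),
                    end=max(cur.end, nxt.end),
                    copy_state=dominant.copy_state,
                )
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    out.sort(key=lambda r: (r.case_id, r.chrom, r.start, r.end))
    return out


def filter_sv_events(
    events: Sequence[SvEvent], cfg: Optional[ThresholdConfig] = None
) -> List[CnvRecord]:
    """Keep deletions/tandem duplications with sufficient mate-pair support,
    off chrY, converted to unified records."""
    cfg = cfg or ThresholdConfig()
    out = []
    for ev in events:
        if ev.type not in {"deletion", "tandem_duplication"}:
            continue
        if ev.support < cfg.sv_support_min or _is_y(ev.chrom):
            continue
        out.append(
            CnvRecord(
                case_id=ev.case_id,
                chrom=ev.chrom,
                start=ev.start,
                end=ev.end,
                state="loss" if ev.type == "deletion" else "gain",
                source="junction",
                support=ev.support,
            )
        )
    return out


# --------------------------------------------------------------------------
# annotation


def annotate_cnv_frequency(
    records: Sequence[CnvRecord],
    controls: Mapping[str, Sequence[CnvRecord]],
    dgv_like: Sequence[CnvRecord],
    cfg: Optional[ThresholdConfig] = None,
) -> List[CnvRecord]:
    """Population frequency from a control cohort plus common-variant overlap.

    ``controls`` maps control sample id -> that sample's CNVs. A control
    sample counts when it carries a same-state CNV at reciprocal overlap
    >= the configured minimum. ``dgv_overlap`` is any qualifying overlap
    with the common-variant set.
    """
    cfg = cfg or ThresholdConfig()
    n_controls = len(controls)
    if n_controls == 0:
        warnings.warn("empty control set: control_freq set to 0 for all records")
    by_chrom_state: Dict[tuple, List[Tuple[str, CnvRecord]]] = defaultdict(list)
    for sample, recs in controls.items():
        for r in recs:
            by_chrom_state[(r.chrom, r.state)].append((sample, r))
    dgv_by_chrom_state: Dict[tuple, List[CnvRecord]] = defaultdict(list)
    for r in dgv_like:
        dgv_by_chrom_state[(r.chrom, r.state)].append(r)

    out = []
    for rec in records:
        hit_samples: Set[str] = set()
        for sample, ctl in by_chrom_state.get((rec.chrom, rec.state), ()):
            if reciprocal_overlap(rec.interval, ctl.interval) >= cfg.reciprocal_overlap_min:
                hit_samples.add(sample)
        freq = len(hit_samples) / n_controls if n_controls else 0.0
        dgv = any(
            reciprocal_overlap(rec.interval, d.interval) >= cfg.reciprocal_overlap_min
            for d in dgv_by_chrom_state.get((rec.chrom, rec.state), ())
        )
        out.append(rec.evolve(control_freq=freq, dgv_overlap=dgv))
    return out


def annotate_gene_exon_overlap(
    records: Sequence[CnvRecord], gene_models: Sequence[GeneModel]
) -> List[CnvRecord]:
    """Set genes_hit (>=1 bp transcript overlap) and exons_hit (>=1 bp exon)."""
    by_chrom: Dict[str, List[GeneModel]] = defaultdict(list)
    for g in gene_models:
        by_chrom[g.chrom].append(g)
    out = []
    for rec in records:
        genes: Set[str] = set()
        exons = False
        for g in by_chrom.get(rec.chrom, ()):
            if min(rec.end, g.end) > max(rec.start, g.start):
                genes.add(g.gene)
                if not exons:
                    exons = any(min(rec.end, e) > max(rec.start, s) for s, e in g.exons)
        out.append(rec.evolve(genes_hit=frozenset(genes), exons_hit=exons))
    return out


def annotate_segdup_cover(
    records: Sequence[CnvRecord], segdup_track: Sequence[Interval]
) -> List[CnvRecord]:
    """Fraction of each CNV covered by the union of segmental duplications."""
    return [r.evolve(segdup_cover=coverage_fraction(r.interval, segdup_track)) for r in records]


def dataset_frequencies(
    records: Sequence[CnvRecord], n_samples: int, cfg: Optional[ThresholdConfig] = None
) -> Dict[tuple, float]:
    """Within-dataset frequency of each record by self-matching.

    A record's frequency is the fraction of *other* dataset samples carrying
    a same-state call at reciprocal overlap >= the configured minimum
    (cluster-then-count). The carrier's own sample is excluded so that a
    private variant has frequency 0 regardless of cohort size. Keyed by
    ``CnvRecord.key``.
    """
    cfg = cfg or ThresholdConfig()
    by_chrom_state: Dict[tuple, List[CnvRecord]] = defaultdict(list)
    for r in records:
        by_chrom_state[(r.chrom, r.state)].append(r)
    freqs: Dict[tuple, float] = {}
    for rec in records:
        carriers = {
            other.case_id
            for other in by_chrom_state[(rec.chrom, rec.state)]
            if reciprocal_overlap(rec.interval, other.interval) >= cfg.reciprocal_overlap_min
        } - {rec.case_id}
        freqs[rec.key] = len(carriers) / n_samples if n_samples else 0.0
    return freqs


# --------------------------------------------------------------------------
# classification


def classify_cnv(
    record: CnvRecord,
    syndromic_regions: Sequence[Tuple[str, int, int, str]],
    disease_genes: Mapping[str, "object"],
    dosage_sensitive: Iterable[str],
    cfg: Optional[ThresholdConfig] = None,
) -> str:
    """Deterministic rule table for CNV clinical classification.

    1. reciprocal overlap >= threshold with a known syndromic region of
       matching state -> pathogenic
    2. exonic hit of a dominant disease gene — as a loss, or as any state for
       a dosage-sensitive gene — while rare in controls and absent from the
       common-variant set -> likely_pathogenic
    3. common (control_freq >= exclusion threshold) or common-variant
       overlap -> benign
    4. otherwise -> VUS
    """
    cfg = cfg or ThresholdConfig()
    dosage_sensitive = set(dosage_sensitive)
    for chrom, start, end, state in syndromic_regions:
        if state == record.state and reciprocal_overlap(record.interval, (chrom, start, end)) >= cfg.reciprocal_overlap_min:
            return "pathogenic"
    rare = record.control_freq < cfg.cnv_freq_exclude and not record.dgv_overlap
    if rare and record.exons_hit:
        for gene in record.genes_hit:
            entry = disease_genes.get(gene)
            if entry is None or "AD" not in entry.inheritance_modes:
                continue
            if record.state == "loss" or gene in dosage_sensitive:
                return "likely_pathogenic"
    if not rare:
        return "benign"
    return "VUS"


# --------------------------------------------------------------------------
# CMA concordance


def filter_for_concordance(
    records: Sequence[CnvRecord],
    segdup_track: Sequence[Interval],
    freq_in_either: Mapping[tuple, float],
    cfg: Optional[ThresholdConfig] = None,
) -> List[CnvRecord]:
    """Exclude segdup-dominated (cover >= 70%) or common (>= 3% in either
    dataset) CNVs ahead of the cross-platform comparison. Idempotent."""
    cfg = cfg or ThresholdConfig()
    annotated = annotate_segdup_cover(records, segdup_track)
    out = []
    for rec in annotated:
        if rec.segdup_cover >= cfg.segdup_cover_exclude:
            continue
        if freq_in_either.get(rec.key, 0.0) >= cfg.cnv_freq_exclude:
            continue
        out.append(rec)
    return out


def cma_outer_record_key(call: CmaCall) -> tuple:
    """Key for a CMA call's outer interval, aligned with CnvRecord.key."""
    return (call.case_id, call.chrom, call.outer_start, call.outer_end, call.state, "microarray")


def match_cma_wgs(
    cma_calls: Sequence[CmaCall],
    wgs_records: Sequence[CnvRecord],
    cfg: Optional[ThresholdConfig] = None,
) -> ConcordanceResult:
    """Match each array call to the best same-case, same-state read-depth CNV.

    Detected means reciprocal overlap >= threshold against the call's outer
    interval; greatest overlap wins with a coordinate tie-break.
    """
    cfg = cfg or ThresholdConfig()
    by_case: Dict[tuple, List[CnvRecord]] = defaultdict(list)
    for r in wgs_records:
        if r.source == "read_depth":
            by_case[(r.case_id, r.chrom, r.state)].append(r)
    matched, unmatched = [], []
    for call in cma_calls:
        outer = (call.chrom, call.outer_start, call.outer_end)
        best = None
        best_key = None
        for rec in by_case.get((call.case_id, call.chrom, call.state), ()):
            ro = reciprocal_overlap(outer, rec.interval)
            if ro < cfg.reciprocal_overlap_min:
                continue
            key = (-ro, rec.chrom, rec.start, rec.end)
            if best_key is None or key < best_key:
                best, best_key = rec, key
        if best is None:
            unmatched.append(call)
        else:
            matched.append((call, best))
    return ConcordanceResult(matched_pairs=matched, unmatched_cma=unmatched)


def breakpoint_concordance(
    result: ConcordanceResult, cfg: Optional[ThresholdConfig] = None
) -> ConcordanceResult:
    """Score matched pairs' breakpoints against the probe-bounded windows.

    within_boundary: both sequencing breakpoints fall inside the
    [outer, inner] probe windows. within_window: both fall within
    ``breakpoint_window`` bp of those windows (so within_boundary implies
    within_window). Returns the result with counts filled in.
    """
    cfg = cfg or ThresholdConfig()
    w = cfg.breakpoint_window
    n_boundary = n_window = 0
    for call, rec in result.matched_pairs:
        start_in = call.outer_start <= rec.start <= call.inner_start
        end_in = call.inner_end <= rec.end <= call.outer_end
        if start_in and end_in:
            n_boundary += 1
        start_near = call.outer_start - w <= rec.start <= call.inner_start + w
        end_near = call.inner_end - w <= rec.end <= call.outer_end + w
        if start_near and end_near:
            n_window += 1
    result.within_boundary_count = n_boundary
    result.within_window_count = n_window
    return result
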