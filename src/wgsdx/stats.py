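"""Cohort-level diagnostic-yield statistics.

Conventions chosen to match standard clinical reporting: the two-proportion
chi-square test applies Yates continuity correction by default, and binomial
confidence intervals use the Wilson score method (Clopper–Pearson available
via ``method="exact"``).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from scipy.stats import chi2_contingency
from statsmodels.stats.proportion import proportion_confint

from .models import Case, DiagnosisRecord, SecondaryFinding, YieldComparison
from .ontology import Ontology, UnknownTermError

__all__ = [
    "diagnostic_yield",
    "two_proportion_chisq",
    "binomial_ci",
    "subgroup_yield",
    "multi_diagnosis_count",
    "combined_actionable_fraction",
    "origin_summary",
]


def diagnostic_yield(diagnoses: Sequence[DiagnosisRecord], cohort_n: int) -> Tuple[int, float]:
    """(count, proportion) of distinct diagnosed cases over the cohort.

    A case with several diagnosis records (e.g. a pathogenic CNV and SNV)
    counts once.
    """
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    diagnosed = {d.case_id for d in diagnoses}
    return len(diagnosed), len(diagnosed) / cohort_n


def two_proportion_chisq(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = True
) -> YieldComparison:
    """2x2 chi-square proportion test; Yates-corrected by default."""
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    margins = [x1 + x2, (n1 - x1) + (n2 - x2), n1, n2]
    if any(m == 0 for m in margins):
        warnings.warn("degenerate 2x2 table (zero margin): p set to 1")
        return YieldComparison(n1, x1, n2, x2, chi2=0.0, p=1.0, continuity=continuity,
                               note="zero margin")
    res = chi2_contingency(table, correction=continuity)
    return YieldComparison(n1, x1, n2, x2, chi2=float(res.statistic), p=float(res.pvalue),
                           continuity=continuity)


def binomial_ci(x: int, n: int, level: float = 0.95, method: str = "wilson") -> Tuple[float, float]:
    """Two-sided binomial CI; Wilson score by default, Clopper–Pearson via
    ``method="exact"``. Bounds as fractions in [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must be in [0, n]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0,1)")
    sm_method = {"wilson": "wilson", "exact": "beta"}[method]
    lo, hi = proportion_confint(x, n, alpha=1.0 - level, method=sm_method)
    # degenerate boundaries are exact for both methods; drop float dust
    lo = 0.0 if x == 0 else float(lo)
    hi = 1.0 if x == n else float(hi)
    return max(0.0, lo), min(1.0, hi)


def subgroup_yield(
    cases: Sequence[Case],
    diagnoses: Sequence[DiagnosisRecord],
    categories: Mapping[str, str],
    ontology: Ontology,
) -> List[Dict]:
    """Yield per phenotype category; membership via ancestor closure.

    ``categories`` maps a label to the ontology term defining the category; a
    case belongs when any of its terms closes onto that term. A case may
    appear in several categories. Categories with no members are omitted.
    Rates are rounded to one decimal percent alongside the raw fraction.
    """
    for label, term in categories.items():
        if term not in ontology:
            raise UnknownTermError(term)
    diagnosed = {d.case_id for d in diagnoses}
    rows = []
    for label, term in categories.items():
        members = [c for c in cases if term in ontology.closure(c.hpo_terms)]
        if not members:
            continue
        dx = sum(1 for c in members if c.case_id in diagnosed)
        rate = dx / len(members)
        rows.append(
            {
                "category": label,
                "term": term,
                "n": len(members),
                "diagnosed": dx,
                "rate": rate,
                "rate_pct": round(100.0 * rate, 1),
            }
        )
    return rows


def multi_diagnosis_count(
    diagnoses: Sequence[DiagnosisRecord], cohort_n: Optional[int] = None
) -> Tuple[int, float]:
    """Cases whose union of locus identifiers spans >= 2 distinct loci."""
    loci: Dict[str, Set[str]] = defaultdict(set)
    for d in diagnoses:
        loci[d.case_id] |= d.locus_ids
    count = sum(1 for ids in loci.values() if len(ids) >= 2)
    denom = cohort_n if cohort_n else len(loci)
    return count, (count / denom if denom else 0.0)


def combined_actionable_fraction(
    diagnoses: Sequence[DiagnosisRecord],
    secondary_findings: Sequence[SecondaryFinding],
    cohort_n: int,
) -> Tuple[int, float]:
    """Distinct cases with a primary diagnosis or a secondary finding."""
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    ids = {d.case_id for d in diagnoses} | {f.case_id for f in secondary_findings}
    return len(ids), len(ids) / cohort_n


def origin_summary(
    diagnoses: Sequence[DiagnosisRecord], cohort_n: Optional[int] = None
) -> Dict:
    """Tabulate diagnosed cases by variant origin.

    A case counts as de novo when any of its records is de novo. Because
    unknown (NA) origins cannot be resolved in a proband-only design, the de
    novo fraction is reported as a minimum.
    """
    by_case: Dict[str, Set[str]] = defaultdict(set)
    for d in diagnoses:
        by_case[d.case_id].add(d.origin)
    counts: Counter = Counter()
    for origins in by_case.values():
        if "de_novo" in origins:
            counts["de_novo"] += 1
        elif origins == {"NA"}:
            counts["NA"] += 1
        else:
            counts["inherited"] += 1
    n = cohort_n if cohort_n else len(by_case)
    de_novo = counts.get("de_novo", 0)
    return {
        "counts": dict(counts),
        "diagnosed_cases": len(by_case),
        "de_novo_cases": de_novo,
        "de_novo_fraction_min": de_novo / n if n else 0.0,
        "note": "NA origins unresolved in a proband-only design; the de novo fraction is a minimum",
    }
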