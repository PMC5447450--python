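"""A minimal phenotype ontology: a rooted DAG of terms with ancestor closure.

Used for the deterministic phenotype-match score (the stand-in for clinician
adjudication) and for mapping case terms to top-level system categories when
computing subgroup yields.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Mapping, Set

__all__ = ["Ontology", "UnknownTermError", "build_mini_hpo", "ROOT", "DD_TERM", "CATEGORY_LABELS"]

ROOT = "HP:0000001"

#: global developmental delay (the subgroup highlighted in the cohort)
DD_TERM = "HP:0001263"

#: top-level phenotype system categories of the mini ontology
CATEGORY_LABELS = {
    "HP:0000707": "nervous_system",
    "HP:0000924": "skeletal_system",
    "HP:0001507": "growth",
    "HP:0000478": "eye",
    "HP:0001626": "cardiovascular",
    "HP:0003011": "musculature",
    "HP:0001871": "blood",
    "HP:0001939": "metabolism",
}


class UnknownTermError(KeyError):
    """Raised when a term identifier is not part of the ontology."""

    def __init__(self, term: str):
        super().__init__(term)
        self.term = term

    def __str__(self) -> str:
        return f"unknown ontology term: {self.term}"


class Ontology:
    """Rooted DAG; each term maps to its set of parents."""

    def __init__(self, parents: Mapping[str, Iterable[str]], root: str = ROOT):
        self.root = root
        self._parents: Dict[str, FrozenSet[str]] = {root: frozenset()}
        for term, ps in parents.items():
            if term == root:
                continue
            self._parents[term] = frozenset(ps)
        for term, ps in self._parents.items():
            for p in ps:
                if p not in self._parents:
                    raise ValueError(f"term {term} has unknown parent {p}")
        self._closure_cache: Dict[str, FrozenSet[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    @property
    def terms(self) -> FrozenSet[str]:
        return frozenset(self._parents)

    def parents(self, term: str) -> FrozenSet[str]:
        try:
            return self._parents[term]
        except KeyError:
            raise UnknownTermError(term) from None

    def ancestors(self, term: str) -> FrozenSet[str]:
        """All ancestors of ``term`` including itself, excluding the root."""
        if term in self._closure_cache:
            return self._closure_cache[term]
        if term not in self._parents:
            raise UnknownTermError(term)
        out: Set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t == self.root or t in out:
                continue
            out.add(t)
            stack.extend(self._parents[t])
        closed = frozenset(out)
        self._closure_cache[term] = closed
        return closed

    def closure(self, terms: Iterable[str]) -> FrozenSet[str]:
        """Ancestor closure of a term set (root excluded)."""
        out: Set[str] = set()
        for t in terms:
            out |= self.ancestors(t)
        return frozenset(out)

    def top_category(self, term: str) -> FrozenSet[str]:
        """Top-level categories (children of the root) the term closes onto."""
        roots_children = {t for t, ps in self._parents.items() if self.root in ps}
        return frozenset(self.ancestors(term) & roots_children)


def phenotype_match_score(case_terms: Iterable[str], gene_terms: Iterable[str], ontology: Ontology) -> float:
    """Shared-term count after ancestor closure, normalised by the case closure size.

    Identical sets score 1.0; sets in disjoint branches score 0.0 (the root
    is excluded from closures so it never creates spurious overlap).
    """
    case_closed = ontology.closure(case_terms)
    gene_closed = ontology.closure(gene_terms)
    if not case_closed:
        return 0.0
    return len(case_closed & gene_closed) / len(case_closed)


def build_mini_hpo() -> Ontology:
    """Deterministic mini phenotype ontology: root -> 8 system categories,
    each with 3 mid-level terms of 3 leaves (104 terms + root).

    Synthetic identifiers follow the pattern ``HP:90ccmmll``. A handful of
    real-world-flavoured aliases (e.g. the developmental-delay term) are
    grafted in where the cohort statistics need them.
    """
    parents: Dict[str, Set[str]] = {}
    categories = list(CATEGORY_LABELS)
    for ci, cat in enumerate(categories, start=1):
        parents[cat] = {ROOT}
        for mi in range(1, 4):
            mid = f"HP:90{ci:02d}{mi:02d}00"
            parents[mid] = {cat}
            for li in range(1, 4):
                leaf = f"HP:90{ci:02d}{mi:02d}{li:02d}"
                parents[leaf] = {mid}
    # developmental delay: child of the neurodevelopmental mid-term under
    # the nervous-system category, with one leaf below it
    parents[DD_TERM] = {"HP:90010100"}
    parents["HP:0012758"] = {DD_TERM}  # mild flavour: neurodevelopmental delay leaf
    return Ontology(parents)


def leaves_for_category(ontology: Ontology, category: str) -> list:
    """Leaf terms under a top-level category, sorted for determinism."""
    leaves = []
    for t in ontology.terms:
        if t == ontology.root:
            continue
        if category in ontology.ancestors(t) and t != category:
            # leaf = no other term lists it as parent
            if not any(t in ontology.parents(u) for u in ontology.terms if u != ontology.root):
                leaves.append(t)
    return sorted(leaves)
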