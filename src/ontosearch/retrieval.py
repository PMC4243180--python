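"""Document scoring, ranking, and search-intention discovery.

Queries are disjunctive (OR) over weighted units: a document matching
any query unit — a stemmed text token in title/abstract, an original
query CUI, or an expansion CUI in the concept field — receives a
score.  This is a deliberate contrast with keyword interfaces that
implicitly AND all query words and return nothing when a single word
(e.g. "topics") appears in no document.

The scorer is a tf-idf practical scoring function: each matching unit
u in field f of document D contributes

    weight(u) * sqrt(tf(u, f, D)) * (1 + ln(doc_count / (df(u) + 1)))^2
        / sqrt(field_length(f, D))

Text tokens and original CUIs carry weight 1.0; expansion CUI weights
are normalized so the largest expansion weight is 1.  The scorer is
pluggable at the function level.

Intention discovery: from the articles a user has marked interesting,
the key concepts are extracted with weight (number of selected
documents containing the concept) * (1 + ln(doc_count / (df + 1))),
and the top concepts form a new concept-only query whose results —
minus the selections themselves — are ranked by relevance to the whole
selection set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .expansion import ExpandedQuery, WeightedConcept
from .index import InvertedIndex

RANK_CRITERIA = ("relevance", "date", "author", "title")


@dataclass(frozen=True)
class SearchResult:
    pmid: int
    score: float
    matched: frozenset[tuple[str, str]]


def _unit_idf(doc_count: int, df: int) -> float:
    return 1.0 + math.log(doc_count / (df + 1))


def _query_units(query: ExpandedQuery) -> list[tuple[float, tuple[str, ...], str]]:
    """Flatten a query into (weight, candidate fields, term) units.

    Text tokens are deduplicated keeping first occurrence; expansion
    weights are scaled so the maximum expansion weight is 1; units with
    weight 0 cannot contribute and are dropped.
    """
    units: list[tuple[float, tuple[str, ...], str]] = []
    for token in dict.fromkeys(query.text_terms):
        units.append((1.0, ("title", "abstract"), token))
    for cui in dict.fromkeys(query.original_cuis):
        units.append((1.0, ("concept",), cui))
    if query.expansion:
        max_w = max(w.weight for w in query.expansion)
        if max_w > 0:
            for w in query.expansion:
                if w.weight > 0:
                    units.append((w.weight / max_w, ("concept",), w.cui))
    return units


def score_document(
    index: InvertedIndex, query: ExpandedQuery, pmid: int
) -> float:
    """Score one document against an expanded query (OR semantics)."""
    score, _ = _score_with_matches(index, _query_units(query), pmid)
    return score


def _score_with_matches(
    index: InvertedIndex,
    units: Sequence[tuple[float, tuple[str, ...], str]],
    pmid: int,
) -> tuple[float, frozenset[tuple[str, str]]]:
    score = 0.0
    matched: set[tuple[str, str]] = set()
    for weight, fields, term in units:
        for field_name in fields:
            tf = index.tf(field_name, term, pmid)
            if tf == 0:
                continue
            length = index.field_length(field_name, pmid)
            if length == 0:
                continue
            idf = _unit_idf(index.doc_count, index.df(field_name, term))
            score += weight * math.sqrt(tf) * idf * idf / math.sqrt(length)
            matched.add((field_name, term))
    return score, frozenset(matched)


def search(
    index: InvertedIndex,
    query: ExpandedQuery,
    k: int = 20,
    require_all: bool = False,
) -> list[SearchResult]:
    """Top-k documents for an expanded query.

    Disjunctive by default: any matching unit qualifies a document.
    With ``require_all`` the query becomes conjunctive — a document
    must match every unit (the implicit-AND behavior whose failure
    mode, zero results for a query word absent from the corpus, the
    default semantics avoids).  Results sort by score descending, ties
    by ascending PMID; only positive scores are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    units = _query_units(query)
    if not units:
        raise ValueError("empty query: no text tokens and no concepts")
    candidates: set[int] = set()
    per_unit_pmids: list[set[int]] = []
    for _, fields, term in units:
        unit_pmids: set[int] = set()
        for field_name in fields:
            unit_pmids.update(index.pmids(field_name, term))
        per_unit_pmids.append(unit_pmids)
        candidates |= unit_pmids
    if require_all:
        for unit_pmids in per_unit_pmids:
            candidates &= unit_pmids
    results = []
    for pmid in candidates:
        score, matched = _score_with_matches(index, units, pmid)
        if score > 0.0:
            results.append(SearchResult(pmid=pmid, score=score,
                                        matched=matched))
    results.sort(key=lambda r: (-r.score, r.pmid))
    return results[:k]


def rank_results(
    results: Sequence[SearchResult],
    index: InvertedIndex,
    criterion: str = "relevance",
) -> list[SearchResult]:
    """Stable re-sort of retrieved results by a display criterion.

    ``relevance`` keeps the search order; ``date`` sorts newest first;
    ``author`` and ``title`` sort ascending by first author / title.
    Documents lacking the sort key (no date, no authors) go last.
    """
    if criterion not in RANK_CRITERIA:
        raise ValueError(
            f"criterion must be one of {RANK_CRITERIA}, got {criterion!r}"
        )
    if criterion == "relevance":
        return list(results)
    if criterion == "date":
        def key(r: SearchResult):
            date = index.doc_table[r.pmid].date
            return (date is None, "" if date is None else _neg_date(date))
    elif criterion == "author":
        def key(r: SearchResult):
            authors = index.doc_table[r.pmid].authors
            return (not authors, authors[0].lower() if authors else "")
    else:  # title
        def key(r: SearchResult):
            return (False, index.doc_table[r.pmid].title.lower())
    return sorted(results, key=key)


def _neg_date(date: str) -> str:
    # map each digit d -> 9-d so lexicographic ascending equals newest-first
    return "".join(str(9 - int(c)) if c.isdigit() else c for c in date)


def _validate_interest(index: InvertedIndex, interest: Sequence[int]) -> list[int]:
    if not interest:
        raise ValueError("interest list is empty")
    seen: list[int] = []
    for pmid in interest:
        if pmid in seen:
            raise ValueError(f"duplicate PMID {pmid} in interest list")
        if pmid not in index.doc_table:
            raise KeyError(f"PMID {pmid} is not in the index")
        seen.append(pmid)
    return seen


def extract_key_concepts(
    index: InvertedIndex, interest: Sequence[int], m: int = 10
) -> list[tuple[str, float]]:
    """Key concepts of the user's selected articles.

    Each concept appearing in at least one selected document gets
    weight = (number of selected documents containing it) *
    (1 + ln(doc_count / (df + 1))); the top-m by weight are returned,
    ties broken by CUI.
    """
    selected = _validate_interest(index, interest)
    support: dict[str, int] = {}
    for pmid in selected:
        for cui in index.doc_table[pmid].concepts:
            support[cui] = support.get(cui, 0) + 1
    weighted = [
        (cui, count * _unit_idf(index.doc_count, index.df("concept", cui)))
        for cui, count in support.items()
    ]
    weighted.sort(key=lambda kw: (-kw[1], kw[0]))
    return weighted[:m]


def related_articles(
    index: InvertedIndex,
    interest: Sequence[int],
    k: int = 20,
    m: int = 10,
    expander=None,
) -> list[SearchResult]:
    """Articles relevant to all of the user's selected articles.

    Builds a concept-only query from the selections' key concepts (the
    discovered "search intention"), optionally enriched by a caller-
    supplied ``expander`` (e.g. a graph-expansion closure mapping a CUI
    list to extra weighted concepts), scores the corpus, and returns
    the top-k excluding the selections themselves.
    """
    selected = set(_validate_interest(index, interest))
    key_concepts = extract_key_concepts(index, interest, m=m)
    expansion = [
        WeightedConcept(cui=cui, ppv=0.0, idf=0.0, weight=weight)
        for cui, weight in key_concepts
    ]
    if expander is not None:
        extra = expander([cui for cui, _ in key_concepts])
        known = {w.cui for w in expansion}
        expansion.extend(w for w in extra if w.cui not in known)
    query = ExpandedQuery(text_terms=[], original_cuis=[],
                          expansion=expansion)
    results = search(index, query, k=k + len(selected))
    results = [r for r in results if r.pmid not in selected]
    return results[:k]
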