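"""Text normalization and dictionary-based concept mapping.

Queries and documents pass through one shared analyzer: lowercase,
split on non-alphanumeric characters, drop stop words, Porter-stem.
Concept mapping then runs a greedy longest-match scan of the normalized
token stream against a dictionary built from the ontology's synonym
terms, emitting the CUI(s) of each matched term.

This dictionary mapper is a deterministic stand-in for a full
text-to-concept annotator (MetaMap-style): it performs no word-sense
disambiguation — an ambiguous term yields all its candidate CUIs, and
the downstream Personalized PageRank stage acts as a soft disambiguator
through graph structure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._stopwords import DEFAULT_STOPWORDS, load_stoplist  # noqa: F401
from .ontology import ConceptEntry
from .stem import stem

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def normalize_text(
    text: str, stoplist: Iterable[str] | None = None
) -> list[str]:
    """Lowercase, tokenize on non-alphanumerics, drop stop words, stem."""
    stop = DEFAULT_STOPWORDS if stoplist is None else set(stoplist)
    return [stem(t) for t in _TOKEN_RE.findall(text.lower()) if t not in stop]


@dataclass(frozen=True)
class MappedConcept:
    """A concept hit in a normalized token stream.

    ``span`` is a half-open (start, end) token range; several CUIs that
    share one ambiguous surface term share one span.
    """

    cui: str
    span: tuple[int, int]
    surface: str


@dataclass
class ConceptDictionary:
    """Normalized synonym term -> CUI set lookup table."""

    entries: dict[str, frozenset[str]]
    max_term_tokens: int
    stoplist: frozenset[str]

    def __len__(self) -> int:
        return len(self.entries)

    def all_cuis(self) -> set[str]:
        out: set[str] = set()
        for cuis in self.entries.values():
            out |= cuis
        return out

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#stoplist\t%s\n" % ",".join(sorted(self.stoplist)))
            for term in sorted(self.entries):
                fh.write(f"{term}\t{','.join(sorted(self.entries[term]))}\n")

    @classmethod
    def load(cls, path) -> "ConceptDictionary":
        entries: dict[str, frozenset[str]] = {}
        stoplist = DEFAULT_STOPWORDS
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#stoplist\t"):
                    words = line.split("\t", 1)[1]
                    stoplist = frozenset(w for w in words.split(",") if w)
                    continue
                term, _, cuis = line.partition("\t")
                entries[term] = frozenset(c for c in cuis.split(",") if c)
        max_tokens = max((t.count(" ") + 1 for t in entries), default=0)
        return cls(entries=entries, max_term_tokens=max_tokens,
                   stoplist=frozenset(stoplist))


def build_dictionary(
    entries: Sequence[ConceptEntry] | Mapping[str, Iterable[str]],
    stoplist: Iterable[str] | None = None,
) -> ConceptDictionary:
    """Build the term->CUI dictionary from ontology concept entries.

    Each synonym term is normalized with the shared analyzer; terms that
    normalize to nothing (e.g. pure stop words) are skipped.  Identical
    normalized terms from different CUIs accumulate all CUIs.

    ``entries`` may be a list of :class:`ConceptEntry` or a mapping
    ``cui -> iterable of terms``.
    """
    stop = frozenset(DEFAULT_STOPWORDS if stoplist is None else stoplist)
    pairs: list[tuple[str, str]]
    if isinstance(entries, Mapping):
        pairs = [(cui, t) for cui, terms in entries.items() for t in terms]
    else:
        pairs = [(e.cui, e.term) for e in entries]
    if not pairs:
        raise ValueError("cannot build a dictionary from zero entries")
    table: dict[str, set[str]] = {}
    for cui, term in pairs:
        tokens = normalize_text(term, stop)
        if not tokens:
            continue
        table.setdefault(" ".join(tokens), set()).add(cui)
    if not table:
        raise ValueError(
            "unusable dictionary: every synonym term normalized to nothing"
        )
    return ConceptDictionary(
        entries={t: frozenset(c) for t, c in table.items()},
        max_term_tokens=max(t.count(" ") + 1 for t in table),
        stoplist=stop,
    )


def map_text(text: str, dictionary: ConceptDictionary) -> list[MappedConcept]:
    """Map free text to concepts by greedy longest-match lookup.

    Scans the normalized token stream left to right; at each position
    the longest dictionary term wins and the scan advances past it, so
    matched spans never overlap.  Duplicate CUIs keep their first
    occurrence only.
    """
    tokens = normalize_text(text, dictionary.stoplist)
    results: list[MappedConcept] = []
    seen: set[str] = set()
    i = 0
    n = len(tokens)
    while i < n:
        hit_len = 0
        for length in range(min(dictionary.max_term_tokens, n - i), 0, -1):
            key = " ".join(tokens[i : i + length])
            if key in dictionary.entries:
                for cui in sorted(dictionary.entries[key]):
                    if cui not in seen:
                        seen.add(cui)
                        results.append(
                            MappedConcept(cui=cui, span=(i, i + length),
                                          surface=key)
                        )
                hit_len = length
                break
        i += hit_len if hit_len else 1
    return results


def map_cuis(text: str, dictionary: ConceptDictionary) -> list[str]:
    """Ordered, deduplicated CUI list for ``text`` (convenience wrapper)."""
    return [m.cui for m in map_text(text, dictionary)]
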