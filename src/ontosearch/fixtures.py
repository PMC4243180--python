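"""Synthetic ontologies, corpora and query sets.

Real inputs for this pipeline (a licensed vocabulary database and a
multi-gigabyte citation corpus) cannot ship with the package, so this
module generates structurally faithful miniatures:

* an ontology whose concept graph has a small core of *hub* concepts —
  general terms with high degree, attached to everything — and a large
  majority of *specific* concepts with few links.  This reproduces the
  asymmetry that motivates idf re-ranking of Personalized PageRank
  scores: random walks pile probability onto hubs because more links
  point at them;
* a citation corpus in both the TSV and MEDLINE-XML dialects, where
  each document embeds the synonym strings of its planted concepts
  (hubs appear in most documents, specifics in few), together with a
  ground-truth sidecar mapping each PMID to its planted CUIs;
* a query set of 1-3 specific concepts per query with the planted
  documents as the relevance judgments.

Everything is a pure function of the spec and its seed: the same spec
yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

from .mapper import build_dictionary, normalize_text

#: Digit -> syllable map for pronounceable, stem-stable synthetic terms.
_SYLLABLES = ("ba", "de", "fi", "go", "hu", "ki", "lo", "mu", "ne", "po")
_SYNONYM_SUFFIXES = ("ra", "ste", "tu", "ve", "wi", "xa", "yo", "zu")

_FILLER_WORDS = (
    "study", "analysis", "patients", "clinical", "results", "effect",
    "response", "treatment", "evaluation", "method", "findings", "cases",
    "role", "association", "outcome", "levels",
)

_AUTHOR_NAMES = (
    "Adams, J", "Baker, L", "Chen, W", "Diaz, M", "Evans, R", "Fischer, K",
    "Garcia, P", "Hansen, O", "Ito, S", "Jones, T",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape of the generated world.

    ``hub_fraction`` of the concepts are general hubs: they get far
    higher graph degree (every specific concept links to a hub) and far
    higher corpus frequency (most documents mention one).  Each
    document plants one hub (usually) plus a Poisson-distributed number
    of specific concepts, and embeds one synonym string of each.
    """

    n_concepts: int = 400
    hub_fraction: float = 0.0075
    n_docs: int = 240
    terms_per_concept: int = 2
    doc_concepts_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hub_fraction <= 1.0:
            raise ValueError("hub_fraction must lie in [0, 1]")
        if self.n_concepts < 1 or self.terms_per_concept < 1:
            raise ValueError("counts must be positive")
        if self.n_docs < 0 or self.doc_concepts_mean <= 0:
            raise ValueError("n_docs must be >= 0, doc_concepts_mean > 0")


@dataclass
class SyntheticOntology:
    """Generated ontology: RRF texts plus the structures behind them."""

    mrconso: str
    mrrel: str
    cuis: list[str]
    hub_cuis: list[str]
    synonyms: dict[str, list[str]]
    edges: list[tuple[str, str]]

    @property
    def specific_cuis(self) -> list[str]:
        hubs = set(self.hub_cuis)
        return [c for c in self.cuis if c not in hubs]


def _word(i: int) -> str:
    return "".join(_SYLLABLES[int(d)] for d in f"{i:04d}")


def _synonyms_for(i: int, terms_per_concept: int) -> list[str]:
    base = _word(i)
    out = [base]
    for j in range(terms_per_concept - 1):
        out.append(base + _SYNONYM_SUFFIXES[j % len(_SYNONYM_SUFFIXES)])
    return out


def generate_ontology(spec: SyntheticSpec) -> SyntheticOntology:
    """Emit MRCONSO/MRREL-dialect texts with a hub-structured graph.

    Hubs form a connected ring and every specific concept attaches to a
    uniformly random hub plus, with probability 1/2, one extra
    preferential-attachment edge; with ``hub_fraction=0`` attachment is
    uniform over earlier concepts, giving a near-degree-uniform graph.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_concepts
    n_hubs = int(round(spec.hub_fraction * n))
    if spec.hub_fraction > 0:
        n_hubs = max(1, n_hubs)
    cuis = [f"C{i:07d}" for i in range(1, n + 1)]
    hub_cuis = cuis[:n_hubs]
    synonyms = {
        cui: _synonyms_for(i + 1, spec.terms_per_concept)
        for i, cui in enumerate(cuis)
    }

    edge_set: set[tuple[str, str]] = set()
    targets: list[int] = []  # endpoint multiset for preferential attachment

    def add_edge(a: int, b: int) -> None:
        if a == b:
            return
        key = (cuis[min(a, b)], cuis[max(a, b)])
        if key not in edge_set:
            edge_set.add(key)
            targets.extend((a, b))

    for h in range(n_hubs):
        add_edge(h, (h + 1) % n_hubs)
    for i in range(n_hubs, n):
        if n_hubs:
            add_edge(i, int(rng.integers(n_hubs)))
        elif i > 0:
            add_edge(i, int(rng.integers(i)))
        if targets and rng.random() < 0.5:
            add_edge(i, targets[int(rng.integers(len(targets)))])

    edges = sorted(edge_set)

    sabs = ("MSH", "SNOMEDCT", "CSP", "AOD")
    conso_lines = []
    k = 0
    for i, cui in enumerate(cuis):
        for term in synonyms[cui]:
            sab = sabs[k % len(sabs)]
            k += 1
            conso_lines.append(
                f"{cui}|ENG|P|L{k:07d}|PF|S{k:07d}|Y|A{k:07d}|||"
                f"D{i + 1:06d}|{sab}|MH|D{i + 1:06d}|{term}|0|N||"
            )
    rels = ("PAR", "CHD", "RO", "SIB")
    rel_lines = []
    for j, (a, b) in enumerate(edges):
        sab = sabs[j % len(sabs)]
        rel_lines.append(
            f"{a}|A{j:07d}|CUI|{rels[j % len(rels)]}|{b}|A{j:07d}|CUI||"
            f"R{j:07d}||{sab}|{sab}|||N||"
        )
    return SyntheticOntology(
        mrconso="\n".join(conso_lines) + "\n" if conso_lines else "",
        mrrel="\n".join(rel_lines) + "\n" if rel_lines else "",
        cuis=cuis,
        hub_cuis=hub_cuis,
        synonyms=synonyms,
        edges=edges,
    )


@dataclass
class SyntheticCorpus:
    """Generated corpus: TSV and XML dialects plus ground truth."""

    tsv: str
    xml: str
    truth: dict[int, list[str]]  # pmid -> planted CUIs

    def truth_tsv(self) -> str:
        lines = [
            f"{pmid}\t{','.join(cuis)}"
            for pmid, cuis in sorted(self.truth.items())
        ]
        return "\n".join(lines) + "\n" if lines else ""


#: Probability that a document mentions general (hub) concepts at all.
HUB_DOC_RATE = 0.9
#: How many distinct hubs a hub-mentioning document carries.
HUBS_PER_DOC = 2
#: Consecutive documents sharing one planted topic concept.
TOPIC_SIZE = 6


def generate_corpus(
    spec: SyntheticSpec, ontology: SyntheticOntology
) -> SyntheticCorpus:
    """Plant concepts into documents and render both citation dialects.

    Documents are organized into topics of ``TOPIC_SIZE`` consecutive
    PMIDs; a block of specific concepts is reserved as topic concepts
    and each document carries its topic's concept.  On top of that each
    document carries ``HUBS_PER_DOC`` distinct hub concepts with
    probability ``HUB_DOC_RATE`` — making hubs present in well over
    half the corpus, the regime the clamped idf zeroes out — plus a
    truncated-Poisson number of rare pool concepts dealt from a
    shuffled deck, which keeps pool document frequencies in a narrow
    low band.  The title embeds the first two planted synonyms and the
    abstract embeds the rest, so the dictionary mapper recovers exactly
    the planted concepts.
    """
    rng = np.random.default_rng(spec.seed + 1)
    specifics = ontology.specific_cuis
    hubs = ontology.hub_cuis
    n_topics = max(1, -(-spec.n_docs // TOPIC_SIZE)) if spec.n_docs else 0
    n_topics = min(n_topics, len(specifics))
    topic_cuis = specifics[:n_topics]
    pool = specifics[n_topics:] or list(specifics)
    k_pool_cap = max(1, int(round(2 * max(spec.doc_concepts_mean - 1, 0.5))))

    deck: list[str] = []

    def deal_pool(k: int, exclude: set[str]) -> list[str]:
        out: list[str] = []
        while len(out) < k:
            if not deck:
                order = rng.permutation(len(pool))
                deck.extend(pool[int(i)] for i in order)
            c = deck.pop()
            if c not in exclude and c not in out:
                out.append(c)
        return out

    tsv_rows = []
    xml_records = []
    truth: dict[int, list[str]] = {}
    for d in range(spec.n_docs):
        pmid = 1000001 + d
        concepts: list[str] = []
        if hubs and rng.random() < HUB_DOC_RATE:
            n_hub = min(HUBS_PER_DOC, len(hubs))
            picks = rng.choice(len(hubs), size=n_hub, replace=False)
            concepts.extend(hubs[int(i)] for i in sorted(picks))
        topic_cui = topic_cuis[(d // TOPIC_SIZE) % n_topics]
        concepts.append(topic_cui)
        k_pool = min(int(rng.poisson(max(spec.doc_concepts_mean - 1, 0.5))),
                     k_pool_cap, len(pool))
        concepts.extend(deal_pool(k_pool, {topic_cui}))

        # rare pool concepts are mentioned by their preferred term;
        # general and topic concepts vary their surface form
        pool_set = set(pool)
        mentions = [
            ontology.synonyms[c][0]
            if c in pool_set
            else ontology.synonyms[c][
                int(rng.integers(len(ontology.synonyms[c])))
            ]
            for c in concepts
        ]
        fillers = [
            _FILLER_WORDS[int(rng.integers(len(_FILLER_WORDS)))]
            for _ in range(3)
        ]
        title_terms = mentions[:2]
        title = f"{fillers[0].capitalize()} of {' and '.join(title_terms)}."
        body = []
        for term in mentions[2:]:
            body.append(f"The {fillers[1]} of {term} was assessed.")
        body.append(f"We report {fillers[2]} in this population.")
        abstract = " ".join(body)

        year = 1995 + int(rng.integers(25))
        month = 1 + int(rng.integers(12))
        day = 1 + int(rng.integers(28))
        date = f"{year}-{month:02d}-{day:02d}"
        n_auth = 1 + int(rng.integers(3))
        author_picks = rng.choice(len(_AUTHOR_NAMES), size=n_auth,
                                  replace=False)
        authors = [_AUTHOR_NAMES[int(i)] for i in author_picks]

        truth[pmid] = concepts
        tsv_rows.append(
            "\t".join((str(pmid), title, abstract, date, ";".join(authors)))
        )
        author_xml = "".join(
            "<Author><LastName>{}</LastName><ForeName>{}</ForeName></Author>"
            .format(escape(a.split(", ")[0]), escape(a.split(", ")[1]))
            for a in authors
        )
        xml_records.append(
            "<MedlineCitation>"
            f"<PMID>{pmid}</PMID>"
            "<Article>"
            f"<ArticleTitle>{escape(title)}</ArticleTitle>"
            f"<Abstract><AbstractText>{escape(abstract)}</AbstractText>"
            "</Abstract>"
            f"<AuthorList>{author_xml}</AuthorList>"
            "</Article>"
            f"<PubDate><Year>{year}</Year><Month>{month:02d}</Month>"
            f"<Day>{day:02d}</Day></PubDate>"
            "</MedlineCitation>"
        )
    xml = (
        "<MedlineCitationSet>" + "".join(xml_records) + "</MedlineCitationSet>"
    )
    tsv = "\n".join(tsv_rows) + "\n" if tsv_rows else ""
    return SyntheticCorpus(tsv=tsv, xml=xml + "\n", truth=truth)


def generate_query_set(
    spec: SyntheticSpec,
    ontology: SyntheticOntology,
    corpus: SyntheticCorpus,
    n_queries: int = 20,
) -> list[tuple[str, set[int]]]:
    """Queries over 1-3 rare specific concepts with their relevant docs.

    Query text joins one synonym of each chosen concept; the relevant
    set is every document planted with at least one of them.  Eligible
    concepts are the rare specifics (planted in at most 3 documents,
    never a hub), so queries probe the specific end of the concept
    frequency spectrum and every relevant set is non-empty.
    """
    rng = np.random.default_rng(spec.seed + 2)
    planted: dict[str, set[int]] = {}
    for pmid, cuis in corpus.truth.items():
        for cui in cuis:
            planted.setdefault(cui, set()).add(pmid)
    eligible = [
        c for c in ontology.specific_cuis
        if c in planted and len(planted[c]) <= 3
    ]
    if not eligible:
        raise ValueError("corpus plants no specific concepts")
    n_eligible = len(eligible)
    max_combos = (
        n_eligible
        + n_eligible * (n_eligible - 1) // 2
        + n_eligible * (n_eligible - 1) * (n_eligible - 2) // 6
    )
    if n_queries > max_combos:
        raise ValueError(
            f"cannot form {n_queries} distinct queries from "
            f"{n_eligible} eligible concepts"
        )
    queries: list[tuple[str, set[int]]] = []
    used: set[tuple[str, ...]] = set()
    attempts = 0
    while len(queries) < n_queries:
        attempts += 1
        if attempts > 50 * n_queries:
            raise ValueError(
                f"cannot form {n_queries} distinct queries from "
                f"{len(eligible)} eligible concepts"
            )
        size = 1 + int(rng.integers(3))
        size = min(size, len(eligible))
        picks = rng.choice(len(eligible), size=size, replace=False)
        combo = tuple(sorted(eligible[int(i)] for i in picks))
        if combo in used:
            continue
        used.add(combo)
        # queries use the preferred term, the form documents use for
        # rare concepts
        words = [ontology.synonyms[c][0] for c in combo]
        relevant: set[int] = set()
        for c in combo:
            relevant |= planted[c]
        queries.append((" ".join(words), relevant))
    return queries


def validate_ontology(
    ontology: SyntheticOntology, stoplist=None
) -> None:
    """Generator self-check: synonym terms stay distinct after analysis."""
    dictionary = build_dictionary(ontology.synonyms, stoplist)
    n_terms = sum(len(v) for v in ontology.synonyms.values())
    if len(dictionary.entries) != n_terms:
        raise AssertionError(
            "synthetic synonym terms collide after normalization"
        )
    for cui, terms in ontology.synonyms.items():
        for term in terms:
            if not normalize_text(term, dictionary.stoplist):
                raise AssertionError(f"term {term!r} normalizes to nothing")


def make_fixtures(spec: SyntheticSpec, out_dir, n_queries: int = 20) -> dict:
    """Write the full fixture set to ``out_dir``; returns file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ontology = generate_ontology(spec)
    corpus = generate_corpus(spec, ontology)
    queries = generate_query_set(spec, ontology, corpus, n_queries)
    paths = {
        "mrconso": out / "mrconso.rrf",
        "mrrel": out / "mrrel.rrf",
        "corpus_tsv": out / "corpus.tsv",
        "corpus_xml": out / "corpus.xml",
        "queries": out / "queries.tsv",
        "truth": out / "truth.tsv",
    }
    paths["mrconso"].write_text(ontology.mrconso, encoding="utf-8")
    paths["mrrel"].write_text(ontology.mrrel, encoding="utf-8")
    paths["corpus_tsv"].write_text(corpus.tsv, encoding="utf-8")
    paths["corpus_xml"].write_text(corpus.xml, encoding="utf-8")
    query_lines = [
        f"{text}\t{','.join(str(p) for p in sorted(relevant))}"
        for text, relevant in queries
    ]
    paths["queries"].write_text(
        "\n".join(query_lines) + "\n" if query_lines else "",
        encoding="utf-8",
    )
    paths["truth"].write_text(corpus.truth_tsv(), encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}


def scaled(spec: SyntheticSpec, **overrides) -> SyntheticSpec:
    """Convenience copy-with-overrides for tests and scripts."""
    return replace(spec, **overrides)
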