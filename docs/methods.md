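# Methods

This note documents the models, parameters, numerical choices and
synthetic-data design behind `ontosearch`.

## Concept graph

The graph is undirected and unweighted. Concept rows are kept when
their source vocabulary is one of {MSH, SNOMEDCT, CSP, AOD}
(configurable), the language is English and the row is not suppressed.
All relation codes (PAR, CHD, SIB, RO, …) contribute edges by default,
with an optional restriction; parent/child direction is deliberately
discarded. Treating every inter-concept relationship as a symmetric
association is standard practice for random walks over UMLS-style
graphs and keeps the Personalized PageRank well defined without
relation-specific semantics. Duplicate and reverse relation rows
collapse to one edge; self-relations are dropped at parse time;
relations naming a concept absent from the concept table are dropped
and counted in the build summary rather than failing the build, since
real vocabulary subsets routinely cross-reference concepts outside the
selected sources.

## Concept mapping

Text-to-concept mapping is a deterministic greedy longest-match scan
over the normalized token stream against the ontology's synonym
dictionary. The normalizer — lowercase, split on non-alphanumerics,
stop-word removal, Porter (1980) stemming — is shared verbatim by
dictionary construction, document analysis and query analysis; this
sharing, not the particular normalizer, is what makes the mapping
sound. The mapper performs no word-sense disambiguation: an ambiguous
surface term emits all its candidate CUIs (sharing one match span),
and the graph walk downstream acts as a soft disambiguator because
senses unrelated to the other query concepts receive little
probability. The default stop list is the classic 33-word English
analyzer list; any list can be substituted, and the list used at
dictionary-build time is persisted with the dictionary so queries and
documents can never disagree.

A full-scale concept annotator does more (variant generation,
abbreviation expansion, scoring); the dictionary mapper is pluggable
behind the same text→CUIs interface if one is available.

## Personalized PageRank

The walk solves p = (1−d)·v + d·(Mᵀp + m_dangling·v) by power
iteration, where M spreads each node's mass uniformly over its
neighbors, v is the teleport (restart) distribution — uniform over the
query's mapped CUIs — and the mass of degree-zero nodes returns to v.
Redistributing dangling mass to the *teleport* vector rather than
uniformly preserves Σp = 1 and keeps the restart personalized; it also
gives the intuitive limit p_seed = 1 for an isolated seed.

Numerical choices:

* damping d = 0.85, the canonical value; configurable.
* L1 stopping tolerance 1e-9. Iteration error contracts at rate ≤ d
  per sweep, so the L1 distance to the fixed point at stop is at most
  tol·d/(1−d) ≈ 5.7e-9.
* max_iter = 200. The contraction bound means k iterations guarantee
  error ≤ 0.85^k; 100 iterations (≈ 9e-8) cannot reach tol = 1e-9 on
  slowly mixing graphs (e.g. even cycles), while 200 (≈ 8e-15) can.
  Tests compare the iteration against a dense direct solve of the
  stationary equations; the two agree to L1 < 1e-8 on random graphs.
* the result is L1-renormalized once at the end, making Σp = 1 exact
  to machine precision; nodes unreachable from the teleport support
  receive exactly 0.0 (never touched by a sparse matvec).
* determinism: the node order backing the sparse adjacency is the
  sorted CUI list, so repeated runs are bit-identical.

Teleport CUIs absent from the graph are dropped with a warning; an
empty remainder is an error (the caller then falls back to pure-text
retrieval).

## Specificity re-ranking

The top 500 concepts by PPV are re-weighted with
w_i = p_i^γ · idf_i, idf_i = max(0, log((N − n_i + 0.5)/(n_i + 0.5))).
The idf is the Robertson–Sparck-Jones form with the conventional
natural logarithm (the base is configurable; it only rescales w).
The clamp zeroes every concept present in at least half the reference
corpus — exactly the "general concept" regime the re-ranking exists to
suppress. γ defaults to 0.5, the midpoint of its meaningful range:
γ = 1 ranks by the plain p·idf product, γ → 0 by pure idf; lowering γ
flattens the graph-relevance factor and favors specific concepts.
Original query CUIs are excluded from the expansion list (they would
trivially top any PPV ranking, carrying no new information) but remain
in the query at weight 1. Ties in w break by higher PPV, then CUI,
for determinism. The reference corpus for idf is whatever corpus the
index was built from (a stand-in for a large clinically oriented
citation collection); the repository is a plain N + per-CUI
document-frequency table and can be swapped.

## Indexing

Three fields are indexed: `title` and `abstract` (stemmed tokens, term
frequencies) and `concept` (each mapped CUI once per document), so
expanded queries match concepts directly regardless of surface
wording. Postings are pmid-ascending; document frequency is posting
length; per-field lengths are stored with the document metadata.

The grouped parallel build mirrors a production bounded thread pool: a
core pool (default 4 threads) grows to a maximum (5) when the task
queue (capacity 18) is full, and submission blocks on a full queue.
Files are partitioned round-robin by position into groups (default 8),
one task per group, and partial indices are merged in group order.
Because merging is pure bookkeeping over disjoint PMID sets, the final
index — and its serialized bytes, via canonical JSON-manifest +
sorted-postings serialization — is independent of worker count and
scheduling; the same merge implements incremental updates. Build
reports record per-group durations T_i and the merge duration, with
T_p = Σ T_i + T_merge by construction; wall-clock values are
informational only. Thread-level parallelism mainly models the
concurrency contract; CPython's interpreter lock limits actual speedup
for this pure-Python analyzer, and no timing claim is tested.

## Retrieval and intention discovery

Queries are disjunctive (OR) over weighted units — the deliberate
opposite of the implicit-AND reading that returns zero results when
one query word appears nowhere. A conjunctive mode exists solely to
demonstrate that failure mode. The scorer is a tf-idf practical
scoring function: a unit u matching field f of document D adds
weight(u) · √tf · (1 + ln(doc_count/(df+1)))² / √(field length).
Text tokens and original CUIs weigh 1; expansion weights are scaled so
their maximum is 1. The scorer is pluggable; any monotone-in-tf,
idf-damped alternative slots in without touching search semantics.
Result ties break by ascending PMID. Display re-ranking by date,
first author or title is a stable re-sort with missing-key documents
last.

Intention discovery concretizes "key concepts of the selected
articles" minimally: concept weight = (number of selected documents
containing it) × (1 + ln(doc_count/(df+1))), top m = 10 concepts form
a concept-only query, selections themselves are excluded from the
results. The selection-support factor is what pulls the shared topic
concept above each article's incidental concepts. Optionally the key
concepts can be enriched through the graph-expansion module
(`expander` hook); the default uses them directly.

## Synthetic data

The generator emulates the two structural asymmetries the method is
built around, at desk scale:

* **General vs specific concepts.** A small set of hubs (default 3 of
  400 concepts) forms a connected core; every specific concept links
  to a random hub plus, with probability 1/2, one
  preferential-attachment edge. Hubs also appear in most documents
  (two distinct hubs in 90 % of documents), putting them over the
  idf clamp threshold — random walks favor them, idf re-ranking
  suppresses them. With hub_fraction = 0 attachment is uniform and
  degrees stay near-uniform.
* **Topic structure.** Every 6 consecutive documents share a planted
  topic concept (document frequency 6); remaining specific concepts
  are dealt from a shuffled deck, keeping their document frequencies
  in a narrow 1–2 band. Topic clusters are what intention discovery
  recovers; the narrow pool band keeps chance concept co-occurrence
  from swamping the planted signal at this corpus size (240
  documents — large enough for stable idf contrast, small enough for
  hundred-trial test budgets).
* **Surface forms.** Each concept gets ≥ 1 pronounceable synthetic
  synonym (syllable-coded, collision-checked after normalization).
  Documents mention rare concepts by their preferred term and
  general/topic concepts by a random synonym; queries use preferred
  terms. Titles embed two mentions, abstracts the rest, so document
  analysis recovers the planted concepts exactly.

Defaults (n_concepts = 400, hub_fraction = 0.0075, n_docs = 240,
terms_per_concept = 2, doc_concepts_mean = 3) were fixed once during
design; every test and the acceptance script run against them.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: natural-language morphology and true
synonym variety, query-side vocabulary gaps (every query term is in
the dictionary, so expansion can widen but rarely needs to rescue
retrieval; on real corpora with human relevance judgments the
expansion's recall contribution is the point), realistic
concept-frequency power laws between the hub and pool extremes, and
noisy concept mapping. Relevance ground truth is "document was
planted with a query concept", not human judgment.

## Known limitations

* The concept mapper is exact-match after normalization; misspellings
  and unseen variants map to nothing (queries then fall back to text).
* The PPV is computed on the full graph per query; for
  million-concept graphs a cached or truncated walk would be needed.
* The inverted index lives in memory and serializes to flat text;
  there is no deletion or compaction.
* Scores are not calibrated across queries; they order documents
  within one result list only.
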