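# ontosearch

Ontology-graph based biomedical literature retrieval.

Keyword interfaces to citation databases fail novice users in two
characteristic ways: they implicitly AND every query word (one word
absent from the corpus yields zero results), and they index documents
with only a small controlled vocabulary, so queries phrased with a
synonym the indexer did not use miss relevant articles. `ontosearch`
implements a retrieval method that attacks both problems with a
concept graph built from UMLS-style vocabulary tables: queries are
mapped to Concept Unique Identifiers (CUIs), expanded with related
concepts found by a random walk over the graph, and matched
disjunctively against an inverted index that carries a concept field
alongside the title/abstract text fields.

## The method

**Concept graph.** MRCONSO-dialect concept rows (filtered to the MSH,
SNOMEDCT, CSP and AOD source vocabularies, English, non-suppressed)
define the vertices — one per CUI, carrying its merged synonym list —
and MRREL-dialect relation rows define undirected, unweighted edges.

**Query expansion.** The query's mapped CUIs form the teleport vector
*v* of a Personalized PageRank: the walk follows a random edge with
probability *d* = 0.85 and restarts at *v* otherwise. Its stationary
distribution *p* (the PPV — Personalized PageRank Value) measures each
concept's relevance to the query. Because the walk restarts at the
seeds and piles probability onto highly connected general concepts,
raw PPV ranking is dominated by the seeds themselves and by hubs. The
top candidates are therefore re-weighted by corpus specificity:

    idf_i = max(0, ln((N − n_i + 0.5) / (n_i + 0.5)))
    w_i   = p_i^γ · idf_i ,   γ ∈ [0, 1]  (default 0.5)

where *N* is the size of a reference corpus and *n_i* the number of
its documents containing concept *i* (the clamped log-odds idf used by
BM25: concepts in more than half the corpus get weight zero). The
top-ranked concepts by *w*, minus the original CUIs, expand the query.

**Indexing.** Citations (MEDLINE-XML subset or TSV) are analyzed with
a shared pipeline — lowercase, split on non-alphanumerics, stop-word
removal, Porter stemming — into `title` and `abstract` token fields
plus a `concept` field of mapped CUIs. Large corpora are built the
way the original system indexed MEDLINE: files partitioned round-robin
into groups, each group indexed by a bounded worker pool, partial
indices merged (total time T_p = Σ T_i + T_merge). The merged content
is bit-identical regardless of worker count, and merging an index of
new documents with an existing index equals rebuilding — giving
incremental weekly updates.

**Retrieval.** Queries are disjunctive over weighted units (text
tokens, original CUIs at weight 1, expansion CUIs normalized to max
weight 1) under a tf-idf practical scoring function. After the user
marks articles of interest, the *search intention* — the key concepts
of all selected articles, weighted by selection support × idf — forms
a new concept query whose results are ranked by relevance to the whole
selection.

## Worked example

No licensed vocabulary or citation download is needed: the fixtures
module generates a structurally faithful miniature world (hub-shaped
concept graph, topic-clustered corpus in both file dialects).

```sh
ontosearch make-fixtures --seed 3 --out fx
ontosearch build-graph --mrconso fx/mrconso.rrf --mrrel fx/mrrel.rrf --out graph
# {"dropped_relations": 0, "edges": 558, "nodes": 400}
ontosearch build-index --corpus "fx/corpus.tsv" --dict graph/dictionary.tsv --groups 4 --out idx
```

Expanding a single-concept query prints each expansion concept's PPV
`p`, its `idf` in the indexed corpus, and the weight `w = p^0.5 · idf`:

```
$ ontosearch expand --graph graph --dict graph/dictionary.tsv --idf idx/idf.tsv "babakifi"
C0000052        original                1.0
C0000387        0.0791244       4.55808 1.28214
C0000102        0.00336667      5.07309 0.294356
C0000069        0.00321739      5.07309 0.287756
...
```

C0000387 is a direct graph neighbor of the seed (high PPV) that is
rare in the corpus (high idf), so it tops the expansion; the three
general hub concepts, although their raw PPV is higher, have idf 0 and
are excluded in effect. Searching with the expanded query returns
documents that match the query words or the expansion concepts:

```
$ ontosearch search --index idx --graph graph --dict graph/dictionary.tsv -k 3 "babakifi bagofipo bagogofi"
1       1000221 27.4453 Clinical of bababafi and bababago.
2       1000031 20.9879 Outcome of bababafi and bababagora.
3       1000046 20.3442 Levels of bababadera and bababafi.
```

(rank, PMID, relevance score, title; the planted-relevant documents
for the query are all retrieved — several match in the abstract and
concept fields, which the title column does not show). Marking two
articles as interesting retrieves articles related to *all* of them:

```
$ ontosearch related --index idx --like 1000001 --like 1000002 -k 3
1       1000006 10.2819 Effect of bababadera and bababafira.
2       1000004 9.1964  Levels of bababahu and badebalo.
3       1000005 9.1964  Analysis of bababade and bababago.
```

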