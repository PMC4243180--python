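"""Shared fixtures: a small synthetic world built once per session."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from ontosearch import (
    ConceptDictionary,
    IdfRepository,
    InvertedIndex,
    OntologyGraph,
    SyntheticCorpus,
    SyntheticOntology,
    SyntheticSpec,
    analyze,
    build_dictionary,
    build_graph,
    build_idf_repository,
    generate_corpus,
    generate_ontology,
    index_documents,
    read_citations,
    read_concept_table,
    read_relation_table,
)


@dataclass
class World:
    """Everything the pipeline produces for one synthetic spec."""

    spec: SyntheticSpec
    ontology: SyntheticOntology
    corpus: SyntheticCorpus
    graph: OntologyGraph
    dictionary: ConceptDictionary
    index: InvertedIndex
    repo: IdfRepository
    docs: list
    paths: dict


def build_world(spec: SyntheticSpec, tmp: Path) -> World:
    tmp.mkdir(parents=True, exist_ok=True)
    ontology = generate_ontology(spec)
    corpus = generate_corpus(spec, ontology)
    paths = {
        "mrconso": tmp / "mrconso.rrf",
        "mrrel": tmp / "mrrel.rrf",
        "corpus_tsv": tmp / "corpus.tsv",
        "corpus_xml": tmp / "corpus.xml",
    }
    paths["mrconso"].write_text(ontology.mrconso, encoding="utf-8")
    paths["mrrel"].write_text(ontology.mrrel, encoding="utf-8")
    paths["corpus_tsv"].write_text(corpus.tsv, encoding="utf-8")
    paths["corpus_xml"].write_text(corpus.xml, encoding="utf-8")
    entries = read_concept_table(paths["mrconso"])
    relations = read_relation_table(paths["mrrel"])
    graph = build_graph(entries, relations)
    dictionary = build_dictionary(entries)
    citations = read_citations(paths["corpus_tsv"])
    docs = [analyze(c, None, dictionary) for c in citations]
    index = index_documents(docs)
    repo = build_idf_repository(
        rec.concepts for rec in index.doc_table.values()
    )
    return World(
        spec=spec, ontology=ontology, corpus=corpus, graph=graph,
        dictionary=dictionary, index=index, repo=repo, docs=docs,
        paths=paths,
    )


@pytest.fixture(scope="session")
def world(tmp_path_factory) -> World:
    """Default synthetic world (seed 7), shared read-only by tests."""
    return build_world(SyntheticSpec(seed=7),
                       tmp_path_factory.mktemp("world"))
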