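"""Citation parsing, inverted-index construction, merging, parallel build."""

import gzip
from collections import Counter

import numpy as np
import pytest

from ontosearch import (
    Citation,
    WorkerPoolConfig,
    analyze,
    build_dictionary,
    build_index_parallel,
    index_documents,
    merge_indices,
    read_citations,
)
from ontosearch.index import (
    AnalyzedDocument,
    DuplicatePmidError,
    InvertedIndex,
)

# Printed result titles for the implicit-AND failure-mode query; used
# throughout as a tiny realistic corpus.
RH_TITLES = [
    (3021092, "A review of 58 Rh-isoimmunized cases."),
    (101918, "Suppression of Rh isoimmunization. A review."),
    (15145363, "Isoimmunization in pregnancy."),
    (6433714, "Rhesus isoimmunization in twin gestation."),
    (6716502, "Isoimmunization with anti-U antibody."),
]


@pytest.fixture()
def tiny_dict():
    return build_dictionary({"C0035399": ["Rh isoimmunization"],
                             "C0035450": ["review"]})


def _doc(pmid, title_tokens, abstract_tokens=(), concepts=(), **meta):
    citation = Citation(pmid=pmid, title=" ".join(title_tokens) or "t",
                        abstract=" ".join(abstract_tokens), **meta)
    return AnalyzedDocument(
        pmid=pmid,
        field_terms={"title": Counter(title_tokens),
                     "abstract": Counter(abstract_tokens)},
        concepts=set(concepts),
        citation=citation,
    )


class TestReadCitations:
    def test_tsv_row(self, tmp_path):
        path = tmp_path / "corpus.tsv"
        path.write_text(
            "3021092\tA review of 58 Rh-isoimmunized cases.\t\n",
            encoding="utf-8",
        )
        (c,) = read_citations(path)
        assert c.pmid == 3021092
        assert c.title == "A review of 58 Rh-isoimmunized cases."
        assert c.abstract == ""

    def test_xml_equivalent_to_tsv(self, tmp_path):
        xml = (
            "<MedlineCitationSet><MedlineCitation>"
            "<PMID>101918</PMID><Article>"
            "<ArticleTitle>Suppression of Rh isoimmunization. A review."
            "</ArticleTitle></Article>"
            "</MedlineCitation></MedlineCitationSet>"
        )
        tsv = "101918\tSuppression of Rh isoimmunization. A review.\t\n"
        (tmp_path / "c.xml").write_text(xml, encoding="utf-8")
        (tmp_path / "c.tsv").write_text(tsv, encoding="utf-8")
        (from_xml,) = read_citations(tmp_path / "c.xml")
        (from_tsv,) = read_citations(tmp_path / "c.tsv")
        assert from_xml.pmid == from_tsv.pmid
        assert from_xml.title == from_tsv.title
        assert from_xml.abstract == from_tsv.abstract

    def test_xml_metadata_fields(self, tmp_path):
        xml = (
            "<MedlineCitationSet><MedlineCitation>"
            "<PMID>7</PMID><Article>"
            "<ArticleTitle>T.</ArticleTitle>"
            "<Abstract><AbstractText>Body text.</AbstractText></Abstract>"
            "<AuthorList><Author><LastName>Chen</LastName>"
            "<ForeName>W</ForeName></Author></AuthorList>"
            "</Article><PubDate><Year>2001</Year><Month>02</Month>"
            "<Day>03</Day></PubDate>"
            "</MedlineCitation></MedlineCitationSet>"
        )
        (tmp_path / "c.xml").write_text(xml, encoding="utf-8")
        (c,) = read_citations(tmp_path / "c.xml")
        assert c.abstract == "Body text."
        assert c.date == "2001-02-03"
        assert c.authors == ("Chen, W",)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("", encoding="utf-8")
        assert read_citations(path) == []

    def test_duplicate_pmid_is_error(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("1\ta\t\n1\tb\t\n", encoding="utf-8")
        with pytest.raises(DuplicatePmidError):
            read_citations(path)

    def test_malformed_record_names_index(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("1\tok\t\nnot-a-pmid\tx\t\n", encoding="utf-8")
        with pytest.raises(ValueError, match="record 2"):
            read_citations(path)

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "c.tsv.gz"
        with gzip.open(path, "wt", encoding="utf-8") as fh:
            fh.write("5\ttitle here\tabstract here\n")
        (c,) = read_citations(path)
        assert c.pmid == 5 and c.abstract == "abstract here"


class TestAnalyze:
    def test_fields_and_concepts(self, tiny_dict):
        c = Citation(pmid=1, title="Rh isoimmunization review",
                     abstract="Suppression of Rh isoimmunization.")
        doc = analyze(c, None, tiny_dict)
        assert doc.field_terms["title"] == Counter(
            ["rh", "isoimmun", "review"]
        )
        assert doc.field_terms["abstract"] == Counter(
            ["suppress", "rh", "isoimmun"]
        )
        assert doc.concepts == {"C0035399", "C0035450"}

    def test_title_only_citation(self, tiny_dict):
        doc = analyze(Citation(pmid=2, title="Isoimmunization in pregnancy."),
                      None, tiny_dict)
        assert doc.field_terms["abstract"] == Counter()

    def test_stopword_only_abstract(self, tiny_dict):
        doc = analyze(Citation(pmid=3, title="x", abstract="of the and"),
                      None, tiny_dict)
        assert doc.field_terms["abstract"] == Counter()


class TestIndexDocuments:
    def test_term_frequencies_and_df(self):
        index = index_documents([
            _doc(1, ["x", "x", "y"]),
            _doc(2, ["x"], concepts=["C1"]),
        ])
        assert index.postings[("title", "x")] == [(1, 2), (2, 1)]
        assert index.postings[("title", "y")] == [(1, 1)]
        assert index.df("title", "x") == 2
        assert index.tf("title", "x", 1) == 2
        assert index.postings[("concept", "C1")] == [(2, 1)]

    def test_empty_corpus(self):
        index = index_documents([])
        assert index.doc_count == 0 and index.postings == {}

    def test_duplicate_pmid_rejected(self):
        with pytest.raises(DuplicatePmidError):
            index_documents([_doc(1, ["a"]), _doc(1, ["b"])])

    def test_field_length_bookkeeping(self):
        index = index_documents([_doc(1, ["x", "x", "y"], ["z"], ["C1"])])
        for field in ("title", "abstract", "concept"):
            posted = sum(
                tf
                for (f, _), plist in index.postings.items()
                if f == field
                for pmid, tf in plist
                if pmid == 1
            )
            assert posted == index.field_length(field, 1)

    def test_save_load_round_trip(self, tmp_path):
        index = index_documents([
            _doc(1, ["x", "y"], ["z"], ["C1"], date="1999-01-02",
                 authors=("Chen, W",)),
            _doc(2, ["x"]),
        ])
        index.save(tmp_path / "idx")
        loaded = InvertedIndex.load(tmp_path / "idx")
        assert loaded == index


class TestMergeIndices:
    def test_identity_and_commutativity(self):
        a = index_documents([_doc(1, ["x"]), _doc(3, ["y"], concepts=["C1"])])
        b = index_documents([_doc(2, ["x", "z"])])
        assert merge_indices([a]) == a
        assert merge_indices([a, b]) == merge_indices([b, a])

    def test_equals_monolithic_build(self):
        rng = np.random.default_rng(5)
        docs = [
            _doc(
                pmid,
                [f"t{rng.integers(6)}" for _ in range(3)],
                [f"a{rng.integers(6)}" for _ in range(4)],
                [f"C{rng.integers(4)}"],
            )
            for pmid in range(1, 41)
        ]
        whole = index_documents(docs)
        for split in (10, 20, 35):
            merged = merge_indices(
                [index_documents(docs[:split]),
                 index_documents(docs[split:])]
            )
            assert merged == whole

    def test_overlapping_pmids_rejected(self):
        a = index_documents([_doc(1, ["x"])])
        b = index_documents([_doc(1, ["y"])])
        with pytest.raises(DuplicatePmidError, match="1"):
            merge_indices([a, b])

    def test_postings_stay_sorted_after_merge(self):
        a = index_documents([_doc(5, ["x"]), _doc(1, ["x"])])
        b = index_documents([_doc(3, ["x"])])
        merged = merge_indices([a, b])
        plist = merged.postings[("title", "x")]
        assert plist == sorted(plist)


def _write_corpus_files(tmp_path, n_docs, n_files, rng):
    rows = []
    for pmid in range(1, n_docs + 1):
        words = " ".join(f"w{rng.integers(30)}" for _ in range(5))
        rows.append(f"{pmid}\tTitle {words}\tAbstract about {words}\n")
    files = []
    for i in range(n_files):
        path = tmp_path / f"part{i}.tsv"
        path.write_text("".join(rows[i::n_files]), encoding="utf-8")
        files.append(path)
    return files


def _index_bytes(index, tmp_path, tag):
    out = tmp_path / f"serialized-{tag}"
    index.save(out)
    return ((out / "manifest.json").read_bytes(),
            (out / "postings.tsv").read_bytes())


class TestParallelBuild:
    @pytest.fixture()
    def corpus_files(self, tmp_path):
        rng = np.random.default_rng(11)
        return _write_corpus_files(tmp_path, 60, 12, rng)

    def test_single_group_single_worker_equals_monolithic(
        self, corpus_files, tiny_dict
    ):
        docs = [
            analyze(c, None, tiny_dict)
            for path in corpus_files
            for c in read_citations(path)
        ]
        mono = index_documents(docs)
        built, _ = build_index_parallel(
            corpus_files, tiny_dict, groups=1,
            pool=WorkerPoolConfig(core_workers=1, max_workers=1),
        )
        assert built == mono

    def test_content_independent_of_workers_and_groups(
        self, corpus_files, tiny_dict, tmp_path
    ):
        reference = None
        for groups in (1, 8):
            for workers in (1, 4):
                index, _ = build_index_parallel(
                    corpus_files, tiny_dict, groups=groups,
                    pool=WorkerPoolConfig(core_workers=workers,
                                          max_workers=workers + 1),
                )
                blob = _index_bytes(index, tmp_path, f"{groups}-{workers}")
                if reference is None:
                    reference = blob
                else:
                    assert blob == reference

    def test_report_time_identity(self, corpus_files, tiny_dict):
        _, report = build_index_parallel(corpus_files, tiny_dict, groups=4)
        assert report.groups == 4
        assert len(report.group_durations) == 4
        assert report.total == pytest.approx(
            sum(report.group_durations) + report.merge_duration
        )

    def test_group_failure_aborts_build(self, corpus_files, tiny_dict,
                                        tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("oops\tno pmid\t\n", encoding="utf-8")
        with pytest.raises(ValueError):
            build_index_parallel(
                list(corpus_files) + [bad], tiny_dict, groups=4
            )

    def test_incremental_update_equals_rebuild(self, tiny_dict, tmp_path):
        rng = np.random.default_rng(23)
        files = _write_corpus_files(tmp_path, 40, 8, rng)
        existing, _ = build_index_parallel(files[:6], tiny_dict, groups=2)
        fresh, _ = build_index_parallel(files[6:], tiny_dict, groups=2)
        rebuilt, _ = build_index_parallel(files, tiny_dict, groups=2)
        assert merge_indices([existing, fresh]) == rebuilt


class TestWorkerPoolConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(core_workers=0), dict(core_workers=3, max_workers=2),
         dict(queue_capacity=0)],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WorkerPoolConfig(**kwargs)

    def test_defaults_mirror_production_settings(self):
        cfg = WorkerPoolConfig()
        assert (cfg.core_workers, cfg.max_workers, cfg.queue_capacity) == (
            4, 5, 18,
        )
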