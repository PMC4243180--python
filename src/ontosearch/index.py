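"""Citation parsing and inverted-index construction.

Citations (PMID, title, abstract, optional date and authors) are read
from either a minimal MEDLINE-XML subset or a TSV dialect, analyzed
with the shared normalization pipeline into per-field token multisets
plus a mapped concept set, and indexed into a bespoke inverted index
with three fields: ``title`` and ``abstract`` hold stemmed text tokens,
``concept`` holds CUIs so expanded queries can match concepts directly.

Large corpora are indexed the way production MEDLINE-scale indexers
work: input files are partitioned round-robin into groups,
each group is indexed independently by a bounded worker pool (a core
pool that grows to a maximum, with a bounded task queue whose
submission blocks when full), and the partial indices are merged into
the final index.  The merge is pure bookkeeping, so the final index
content is identical regardless of worker count or scheduling — which
also gives incremental updates for free: merging an index of newly
added documents with an existing index equals rebuilding over the
union.

Build wall-clock accounting follows T_p = sum_i T_i + T_merge, where
T_i is the build time of group i.
"""

from __future__ import annotations

import bisect
import gzip
import json
import queue
import threading
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .mapper import ConceptDictionary, map_cuis, normalize_text

FIELDS = ("title", "abstract", "concept")


@dataclass(frozen=True)
class Citation:
    """One bibliographic record; only title and abstract are indexed."""

    pmid: int
    title: str
    abstract: str = ""
    date: str | None = None  # ISO "YYYY-MM-DD" (or "YYYY")
    authors: tuple[str, ...] = ()


@dataclass
class AnalyzedDocument:
    """A citation after normalization and concept mapping."""

    pmid: int
    field_terms: dict[str, Counter]
    concepts: set[str]
    citation: Citation


@dataclass
class DocRecord:
    """Stored per-document metadata inside the index."""

    title: str
    date: str | None
    authors: tuple[str, ...]
    field_lengths: dict[str, int]
    concepts: tuple[str, ...]


class DuplicatePmidError(ValueError):
    pass


# ---------------------------------------------------------------------------
# citation parsing


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


def _parse_tsv(fh, path) -> list[Citation]:
    citations = []
    for lineno, line in enumerate(fh, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}: record {lineno}: expected at least 3 tab-separated "
                f"columns (pmid, title, abstract), got {len(parts)}"
            )
        try:
            pmid = int(parts[0])
        except ValueError as exc:
            raise ValueError(f"{path}: record {lineno}: bad PMID "
                             f"{parts[0]!r}") from exc
        title = parts[1].strip()
        if not title:
            raise ValueError(f"{path}: record {lineno}: empty title")
        abstract = parts[2] if len(parts) > 2 else ""
        date = parts[3] or None if len(parts) > 3 else None
        authors = (
            tuple(a for a in parts[4].split(";") if a)
            if len(parts) > 4
            else ()
        )
        citations.append(
            Citation(pmid=pmid, title=title, abstract=abstract, date=date,
                     authors=authors)
        )
    return citations


def _text(elem) -> str:
    return "".join(elem.itertext()).strip() if elem is not None else ""


def _parse_xml(raw: bytes, path) -> list[Citation]:
    root = etree.fromstring(raw)
    citations = []
    records = root.iter("MedlineCitation")
    for i, rec in enumerate(records, start=1):
        pmid_el = rec.find("PMID")
        title_el = rec.find(".//ArticleTitle")
        if pmid_el is None or title_el is None or not _text(title_el):
            raise ValueError(f"{path}: record {i}: missing PMID or "
                             f"ArticleTitle")
        try:
            pmid = int(_text(pmid_el))
        except ValueError as exc:
            raise ValueError(f"{path}: record {i}: bad PMID") from exc
        abstract = " ".join(
            _text(a) for a in rec.findall(".//Abstract/AbstractText")
        ).strip()
        date = None
        date_el = rec.find(".//PubDate")
        if date_el is not None:
            year = _text(date_el.find("Year"))
            month = _text(date_el.find("Month")) or "01"
            day = _text(date_el.find("Day")) or "01"
            if year:
                date = f"{year}-{month.zfill(2)}-{day.zfill(2)}"
        authors = []
        for author in rec.findall(".//AuthorList/Author"):
            last = _text(author.find("LastName"))
            fore = _text(author.find("ForeName"))
            name = ", ".join(x for x in (last, fore) if x)
            if name:
                authors.append(name)
        citations.append(
            Citation(pmid=pmid, title=_text(title_el), abstract=abstract,
                     date=date, authors=tuple(authors))
        )
    return citations


def read_citations(path) -> list[Citation]:
    """Read citations from MEDLINE-XML-subset or TSV, in file order.

    The format is sniffed from the first non-blank character (``<`` for
    XML); ``.gz`` files are decompressed transparently.  Duplicate
    PMIDs within one file are an error.
    """
    with _open_maybe_gzip(path) as fh:
        content = fh.read()
    stripped = content.lstrip()
    if not stripped:
        return []
    if stripped.startswith("<"):
        citations = _parse_xml(stripped.encode("utf-8"), path)
    else:
        import io

        citations = _parse_tsv(io.StringIO(content), path)
    seen: set[int] = set()
    for c in citations:
        if c.pmid in seen:
            raise DuplicatePmidError(f"{path}: duplicate PMID {c.pmid}")
        seen.add(c.pmid)
    return citations


# ---------------------------------------------------------------------------
# analysis


def analyze(
    citation: Citation,
    stoplist: Iterable[str] | None,
    dictionary: ConceptDictionary,
) -> AnalyzedDocument:
    """Normalize title/abstract and map their concepts.

    Field tokens use the same pipeline as query analysis; the concept
    set is the union of the mapped concepts of title and abstract.
    """
    stop = dictionary.stoplist if stoplist is None else stoplist
    field_terms = {
        "title": Counter(normalize_text(citation.title, stop)),
        "abstract": Counter(normalize_text(citation.abstract, stop)),
    }
    concepts = set(map_cuis(citation.title, dictionary))
    concepts |= set(map_cuis(citation.abstract, dictionary))
    return AnalyzedDocument(
        pmid=citation.pmid,
        field_terms=field_terms,
        concepts=concepts,
        citation=citation,
    )


# ---------------------------------------------------------------------------
# the inverted index


@dataclass
class InvertedIndex:
    """Per-field postings with document frequencies and stored metadata.

    ``postings`` maps (field, term) to a pmid-ascending list of
    (pmid, term-frequency) pairs; df of a term is the length of its
    posting list.
    """

    doc_count: int = 0
    postings: dict[tuple[str, str], list[tuple[int, int]]] = field(
        default_factory=dict
    )
    doc_table: dict[int, DocRecord] = field(default_factory=dict)

    def df(self, field_name: str, term: str) -> int:
        return len(self.postings.get((field_name, term), ()))

    def tf(self, field_name: str, term: str, pmid: int) -> int:
        plist = self.postings.get((field_name, term))
        if not plist:
            return 0
        i = bisect.bisect_left(plist, (pmid, 0))
        if i < len(plist) and plist[i][0] == pmid:
            return plist[i][1]
        return 0

    def pmids(self, field_name: str, term: str) -> list[int]:
        return [p for p, _ in self.postings.get((field_name, term), ())]

    def field_length(self, field_name: str, pmid: int) -> int:
        return self.doc_table[pmid].field_lengths.get(field_name, 0)

    # -- serialization: JSON manifest + sorted postings file ----------

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "doc_count": self.doc_count,
            "fields": list(FIELDS),
            "docs": {
                str(pmid): {
                    "title": rec.title,
                    "date": rec.date,
                    "authors": list(rec.authors),
                    "field_lengths": rec.field_lengths,
                    "concepts": list(rec.concepts),
                }
                for pmid, rec in self.doc_table.items()
            },
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True,
                      ensure_ascii=False)
            fh.write("\n")
        with open(out / "postings.tsv", "w", encoding="utf-8") as fh:
            for (field_name, term) in sorted(self.postings):
                plist = self.postings[(field_name, term)]
                cells = " ".join(f"{p}:{tf}" for p, tf in plist)
                fh.write(f"{field_name}\t{term}\t{cells}\n")

    @classmethod
    def load(cls, in_dir) -> "InvertedIndex":
        in_dir = Path(in_dir)
        with open(in_dir / "manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        doc_table = {}
        for pmid_str, rec in manifest["docs"].items():
            doc_table[int(pmid_str)] = DocRecord(
                title=rec["title"],
                date=rec["date"],
                authors=tuple(rec["authors"]),
                field_lengths=dict(rec["field_lengths"]),
                concepts=tuple(rec["concepts"]),
            )
        postings: dict[tuple[str, str], list[tuple[int, int]]] = {}
        with open(in_dir / "postings.tsv", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                field_name, term, cells = line.split("\t")
                plist = []
                for cell in cells.split():
                    pmid, _, tf = cell.partition(":")
                    plist.append((int(pmid), int(tf)))
                postings[(field_name, term)] = plist
        return cls(doc_count=manifest["doc_count"], postings=postings,
                   doc_table=doc_table)


def index_documents(docs: Sequence[AnalyzedDocument]) -> InvertedIndex:
    """Single-pass build of an inverted index from analyzed documents."""
    index = InvertedIndex()
    for doc in sorted(docs, key=lambda d: d.pmid):
        if doc.pmid in index.doc_table:
            raise DuplicatePmidError(f"duplicate PMID {doc.pmid}")
        lengths = {}
        for field_name in ("title", "abstract"):
            counts = doc.field_terms.get(field_name, Counter())
            lengths[field_name] = sum(counts.values())
            for term, tf in counts.items():
                index.postings.setdefault((field_name, term), []).append(
                    (doc.pmid, tf)
                )
        concepts = tuple(sorted(doc.concepts))
        lengths["concept"] = len(concepts)
        for cui in concepts:
            index.postings.setdefault(("concept", cui), []).append(
                (doc.pmid, 1)
            )
        index.doc_table[doc.pmid] = DocRecord(
            title=doc.citation.title,
            date=doc.citation.date,
            authors=doc.citation.authors,
            field_lengths=lengths,
            concepts=concepts,
        )
        index.doc_count += 1
    return index


def merge_indices(parts: Sequence[InvertedIndex]) -> InvertedIndex:
    """Merge partial indices with pairwise-disjoint PMID sets.

    Posting lists concatenate in PMID order; the merge is associative
    and its content does not depend on the order of ``parts``.
    """
    merged = InvertedIndex()
    for part in parts:
        for pmid, rec in part.doc_table.items():
            if pmid in merged.doc_table:
                raise DuplicatePmidError(
                    f"PMID {pmid} appears in more than one partial index"
                )
            merged.doc_table[pmid] = rec
        merged.doc_count += part.doc_count
    for part in parts:
        for key, plist in part.postings.items():
            merged.postings.setdefault(key, []).extend(plist)
    for plist in merged.postings.values():
        plist.sort()
    return merged


# ---------------------------------------------------------------------------
# bounded worker pool + grouped parallel build


@dataclass
class WorkerPoolConfig:
    """Bounded thread-pool settings for the grouped build.

    A core pool of ``core_workers`` threads grows up to ``max_workers``
    when the task queue (capacity ``queue_capacity``) is full; further
    submissions block until a slot frees up.
    """

    core_workers: int = 4
    max_workers: int = 5
    queue_capacity: int = 18

    def __post_init__(self) -> None:
        if not 1 <= self.core_workers <= self.max_workers:
            raise ValueError("need 1 <= core_workers <= max_workers")
        if self.queue_capacity < 1:
            raise ValueError("queue_capacity must be >= 1")


class _BoundedPool:
    """Minimal bounded executor: blocking submission, ordered results."""

    def __init__(self, cfg: WorkerPoolConfig):
        self._cfg = cfg
        self._queue: queue.Queue = queue.Queue(maxsize=cfg.queue_capacity)
        self._threads: list[threading.Thread] = []
        self._lock = threading.Lock()
        self.results: dict[int, object] = {}
        self.errors: dict[int, BaseException] = {}
        for _ in range(cfg.core_workers):
            self._spawn()

    def _spawn(self) -> None:
        t = threading.Thread(target=self._worker, daemon=True)
        t.start()
        self._threads.append(t)

    def _worker(self) -> None:
        while True:
            item = self._queue.get()
            if item is None:
                self._queue.task_done()
                return
            task_id, fn = item
            try:
                out = fn()
            except BaseException as exc:  # propagated after join
                with self._lock:
                    self.errors[task_id] = exc
            else:
                with self._lock:
                    self.results[task_id] = out
            self._queue.task_done()

    def submit(self, task_id: int, fn) -> None:
        if self._queue.full() and len(self._threads) < self._cfg.max_workers:
            self._spawn()
        self._queue.put((task_id, fn))  # blocks while the queue is full

    def join(self) -> None:
        for _ in self._threads:
            self._queue.put(None)
        for t in self._threads:
            t.join()


@dataclass
class IndexBuildReport:
    """Wall-clock accounting of a grouped build: T_p = sum T_i + T_merge."""

    group_durations: list[float]
    merge_duration: float
    groups: int

    @property
    def total(self) -> float:
        return sum(self.group_durations) + self.merge_duration

    def as_dict(self) -> dict:
        return {
            "groups": self.groups,
            "group_durations_s": self.group_durations,
            "merge_duration_s": self.merge_duration,
            "total_s": self.total,
        }


def _build_group(
    files: Sequence, stoplist, dictionary: ConceptDictionary
) -> tuple[InvertedIndex, float]:
    start = time.perf_counter()
    docs: list[AnalyzedDocument] = []
    for path in files:
        for citation in read_citations(path):
            docs.append(analyze(citation, stoplist, dictionary))
    part = index_documents(docs)
    return part, time.perf_counter() - start


def build_index_parallel(
    files: Sequence,
    dictionary: ConceptDictionary,
    stoplist: Iterable[str] | None = None,
    groups: int = 8,
    pool: WorkerPoolConfig | None = None,
) -> tuple[InvertedIndex, IndexBuildReport]:
    """Grouped parallel index build with deterministic content.

    Files are partitioned round-robin into ``groups`` groups; each
    group is read, analyzed and indexed as one task on the bounded
    pool; the partial indices are then merged in group order.  The
    merged content is independent of worker count and scheduling.

    Any group failure aborts the whole build with the underlying error.
    """
    if groups < 1:
        raise ValueError("groups must be >= 1")
    pool_cfg = pool or WorkerPoolConfig()
    group_files = [list(files[g::groups]) for g in range(groups)]

    executor = _BoundedPool(pool_cfg)
    for g, paths in enumerate(group_files):
        executor.submit(g, lambda paths=paths: _build_group(
            paths, stoplist, dictionary))
    executor.join()
    if executor.errors:
        first = min(executor.errors)
        raise executor.errors[first]

    parts: list[InvertedIndex] = []
    durations: list[float] = []
    for g in range(groups):
        part, duration = executor.results[g]  # type: ignore[misc]
        parts.append(part)
        durations.append(duration)

    merge_start = time.perf_counter()
    merged = merge_indices(parts)
    merge_duration = time.perf_counter() - merge_start
    report = IndexBuildReport(
        group_durations=durations, merge_duration=merge_duration,
        groups=groups,
    )
    return merged, report
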