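"""Concept-graph construction from UMLS-style RRF tables.

The Metathesaurus distributes concept names in a pipe-delimited table
(MRCONSO) and inter-concept relations (parent/child, sibling, other) in
a second table (MRREL).  This module parses both dialects, filters rows
to a chosen set of source vocabularies (by default MeSH, SNOMED CT, CSP
and AOD, which together cover the concept senses used in the target
corpus), and assembles an undirected concept graph: one vertex per CUI
with its merged synonym list, one edge per related concept pair.

Edges are undirected and unweighted; duplicate and reverse relations
collapse to a single edge, self-relations are dropped, and relations
pointing at unknown concepts are dropped but counted in the build
summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

#: Source vocabularies merged into the default graph.
DEFAULT_SOURCES = frozenset({"MSH", "SNOMEDCT", "CSP", "AOD"})

# Minimum column counts: the full layouts have 18 (MRCONSO) and 16
# (MRREL) columns, but a trailing empty CVF merges into the optional
# trailing pipe, so one less is accepted.
_MRCONSO_FIELDS = 17
_MRREL_FIELDS = 15


@dataclass(frozen=True)
class ConceptEntry:
    """One row of the concept table: a (CUI, synonym term) pair."""

    cui: str
    term: str
    source: str
    language: str = "ENG"
    suppressed: bool = False


@dataclass(frozen=True)
class ConceptRelation:
    """One row of the relation table: an undirected concept association."""

    cui1: str
    cui2: str
    rel: str
    source: str


class RRFFormatError(ValueError):
    """Raised for a malformed pipe-delimited row (wrong field count)."""


def _split_rrf(line: str, expected: int, path, lineno: int) -> list[str]:
    # optional trailing pipe: "a|b|" splits to ["a","b",""]
    fields = line.rstrip("\n").split("|")
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) < expected:
        raise RRFFormatError(
            f"{path}: line {lineno}: expected {expected} pipe-delimited "
            f"fields, got {len(fields)}"
        )
    return fields


def read_concept_table(
    path, sources: Iterable[str] = DEFAULT_SOURCES
) -> list[ConceptEntry]:
    """Parse an MRCONSO-dialect file into concept entries.

    Keeps English, non-suppressed rows whose source vocabulary (SAB) is
    in ``sources``; file order is preserved.  Column order is the
    standard MRCONSO layout (CUI|LAT|TS|LUI|STT|SUI|ISPREF|AUI|SAUI|
    SCUI|SDUI|SAB|TTY|CODE|STR|SRL|SUPPRESS|CVF).
    """
    sources = set(sources)
    entries: list[ConceptEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split_rrf(line, _MRCONSO_FIELDS, path, lineno)
            cui, lat, sab, term, suppress = f[0], f[1], f[11], f[14], f[16]
            if lat != "ENG" or suppress == "O" or sab not in sources:
                continue
            term = term.strip()
            if not term:
                continue
            entries.append(
                ConceptEntry(cui=cui, term=term, source=sab, language=lat,
                             suppressed=False)
            )
    if not entries:
        warnings.warn(f"{path}: no concept rows matched sources {sorted(sources)}")
    return entries


def read_relation_table(
    path,
    sources: Iterable[str] = DEFAULT_SOURCES,
    rel_codes: Iterable[str] | None = None,
) -> list[ConceptRelation]:
    """Parse an MRREL-dialect file into concept relations.

    Keeps rows whose SAB is in ``sources`` and whose endpoints differ
    (self-relations are dropped).  All REL codes are retained unless
    ``rel_codes`` restricts them.  Column order is the standard MRREL
    layout (CUI1|AUI1|STYPE1|REL|CUI2|AUI2|STYPE2|RELA|RUI|SRUI|SAB|SL|
    RG|DIR|SUPPRESS|CVF).
    """
    sources = set(sources)
    keep_rel = set(rel_codes) if rel_codes is not None else None
    relations: list[ConceptRelation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split_rrf(line, _MRREL_FIELDS, path, lineno)
            cui1, rel, cui2, sab = f[0], f[3], f[4], f[10]
            if sab not in sources or cui1 == cui2:
                continue
            if keep_rel is not None and rel not in keep_rel:
                continue
            relations.append(
                ConceptRelation(cui1=cui1, cui2=cui2, rel=rel, source=sab)
            )
    return relations


@dataclass
class OntologyGraph:
    """Undirected concept graph: CUIs with synonym lists and relations.

    Wraps a :class:`networkx.Graph` whose nodes carry a ``synonyms``
    attribute (ordered, deduplicated term list).  A fixed, sorted node
    order is cached for reproducible linear-algebra views.
    """

    graph: nx.Graph
    dropped_relations: int = 0
    _order: list[str] | None = field(default=None, repr=False)
    _csr: sp.csr_array | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, cui: str) -> bool:
        return cui in self.graph

    def nodes(self) -> Iterable[str]:
        return self.graph.nodes()

    def neighbors(self, cui: str) -> set[str]:
        return set(self.graph.neighbors(cui))

    def synonyms(self, cui: str) -> list[str]:
        return list(self.graph.nodes[cui]["synonyms"])

    def node_order(self) -> list[str]:
        """Sorted CUI list defining row/column order of the adjacency."""
        if self._order is None:
            self._order = sorted(self.graph.nodes())
        return self._order

    def adjacency(self) -> sp.csr_array:
        """Symmetric 0/1 adjacency in ``node_order`` ordering."""
        if self._csr is None:
            mat = nx.to_scipy_sparse_array(
                self.graph, nodelist=self.node_order(), dtype=np.float64,
                format="csr",
            )
            mat.data[:] = 1.0  # unweighted
            self._csr = mat
        return self._csr

    def summary(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "dropped_relations": self.dropped_relations,
        }

    # -- serialization: nodes TSV + edges TSV + JSON summary -----------

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "nodes.tsv", "w", encoding="utf-8") as fh:
            for cui in self.node_order():
                fh.write(f"{cui}\t{';'.join(self.synonyms(cui))}\n")
        with open(out / "edges.tsv", "w", encoding="utf-8") as fh:
            for u, v in sorted(
                (min(a, b), max(a, b)) for a, b in self.graph.edges()
            ):
                fh.write(f"{u}\t{v}\n")
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, in_dir) -> "OntologyGraph":
        in_dir = Path(in_dir)
        g = nx.Graph()
        with open(in_dir / "nodes.tsv", encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                cui, _, syns = line.rstrip("\n").partition("\t")
                g.add_node(cui, synonyms=[s for s in syns.split(";") if s])
        with open(in_dir / "edges.tsv", encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                u, _, v = line.rstrip("\n").partition("\t")
                g.add_edge(u, v)
        dropped = 0
        summary_path = in_dir / "summary.json"
        if summary_path.exists():
            with open(summary_path, encoding="utf-8") as fh:
                dropped = json.load(fh).get("dropped_relations", 0)
        return cls(graph=g, dropped_relations=dropped)


def build_graph(
    entries: Sequence[ConceptEntry], relations: Sequence[ConceptRelation]
) -> OntologyGraph:
    """Assemble the concept graph from parsed table rows.

    Nodes are the distinct CUIs among ``entries`` with synonym lists
    merged across sources (first occurrence order, deduplicated).
    Each relation adds one undirected edge; duplicates and reverses
    collapse.  Relations with an endpoint not present among the entries
    are dropped and counted in ``dropped_relations``.
    """
    g = nx.Graph()
    for e in entries:
        if e.cui in g:
            syns = g.nodes[e.cui]["synonyms"]
            if e.term not in syns:
                syns.append(e.term)
        else:
            g.add_node(e.cui, synonyms=[e.term])
    dropped = 0
    for r in relations:
        if r.cui1 == r.cui2:
            continue
        if r.cui1 not in g or r.cui2 not in g:
            dropped += 1
            continue
        g.add_edge(r.cui1, r.cui2)
    return OntologyGraph(graph=g, dropped_relations=dropped)
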