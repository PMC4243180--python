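"""Ontology-graph query expansion.

A query's mapped CUIs seed a Personalized PageRank (random walk with
restart) over the concept graph.  The stationary distribution p — the
PPV, Personalized PageRank Value, of every concept — measures graph
relevance to the query.  Because the walk restarts at the seeds, seed
concepts always top the raw PPV ranking, and highly connected general
concepts (hubs) rank above more specific ones.  To recover specificity
the top candidates are re-weighted with a clamped log-odds inverse
document frequency from a reference corpus:

    idf_i = max(0, log((N - n_i + 0.5) / (n_i + 0.5)))
    w_i   = p_i^gamma * idf_i,   gamma in [0, 1]

where N is the reference corpus size and n_i the number of its
documents containing concept i.  Decreasing gamma flattens the PPV
factor, shifting the ranking toward rare (specific) concepts.  The
re-ranked concepts, minus the seeds themselves, become the expansion
terms of the query.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mapper import ConceptDictionary, map_cuis, normalize_text
from .ontology import OntologyGraph


@dataclass
class ExpansionConfig:
    """Tunables of the expansion stage.

    damping
        Restart-complement of the random walk (probability of following
        an edge rather than teleporting back to the seeds).
    tol, max_iter
        L1 stopping threshold and iteration cap of the power iteration.
    gamma
        Exponent on the PPV in the re-weighting; 0 ranks purely by idf,
        1 by the p*idf product.
    top_candidates
        How many top-PPV concepts enter the re-ranking.
    top_expansion
        How many re-ranked concepts expand the query.
    log_base
        Base of the idf logarithm; ``None`` means natural log.
    """

    damping: float = 0.85
    tol: float = 1e-9
    max_iter: int = 200
    gamma: float = 0.5
    top_candidates: int = 500
    top_expansion: int = 20
    log_base: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must lie in (0, 1)")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.top_expansion > self.top_candidates:
            raise ValueError("top_expansion must not exceed top_candidates")


@dataclass
class PPVVector:
    """L1-normalized Personalized PageRank scores over graph concepts."""

    scores: dict[str, float]
    iterations_used: int
    converged: bool

    def top(self, k: int) -> list[tuple[str, float]]:
        """Top-k concepts by score, ties broken by CUI."""
        ranked = sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:k]


@dataclass
class IdfRepository:
    """Per-concept document frequencies of a reference corpus."""

    total_docs: int
    df: dict[str, int] = field(default_factory=dict)

    def n(self, cui: str) -> int:
        return self.df.get(cui, 0)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#N\t{self.total_docs}\n")
            for cui in sorted(self.df):
                fh.write(f"{cui}\t{self.df[cui]}\n")

    @classmethod
    def load(cls, path) -> "IdfRepository":
        total = None
        df: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                key, _, value = line.partition("\t")
                if key == "#N":
                    total = int(value)
                else:
                    df[key] = int(value)
        if total is None:
            raise ValueError(f"{path}: missing #N header row")
        return cls(total_docs=total, df=df)


def build_idf_repository(
    corpus_concepts: Iterable[Iterable[str]],
) -> IdfRepository:
    """Count per-concept document frequencies over per-document sets."""
    df: dict[str, int] = {}
    n_docs = 0
    for concepts in corpus_concepts:
        n_docs += 1
        for cui in set(concepts):
            df[cui] = df.get(cui, 0) + 1
    if n_docs == 0:
        raise ValueError("idf repository needs at least one document")
    return IdfRepository(total_docs=n_docs, df=df)


def idf(repo: IdfRepository, cui: str, log_base: float | None = None) -> float:
    """Clamped log-odds inverse document frequency of a concept.

    max(0, log((N - n + 0.5) / (n + 0.5))); concepts unseen in the
    repository get n = 0 and hence the maximal idf.
    """
    n_i = repo.n(cui)
    value = math.log((repo.total_docs - n_i + 0.5) / (n_i + 0.5))
    if log_base is not None:
        value /= math.log(log_base)
    return max(0.0, value)


def uniform_teleport(
    cuis: Sequence[str], graph: OntologyGraph
) -> dict[str, float]:
    """Uniform restart distribution over the seed CUIs present in the graph.

    Seeds missing from the graph are dropped with a warning; an empty
    remainder is an error.
    """
    present = [c for c in dict.fromkeys(cuis) if c in graph]
    missing = [c for c in dict.fromkeys(cuis) if c not in graph]
    if missing:
        warnings.warn(f"teleport CUIs absent from graph: {missing}")
    if not present:
        raise ValueError("no teleport CUI is present in the graph")
    p = 1.0 / len(present)
    return {c: p for c in present}


def personalized_pagerank(
    graph: OntologyGraph,
    teleport: Mapping[str, float],
    cfg: ExpansionConfig | None = None,
) -> PPVVector:
    """Power-iterate the restart-biased random walk to its fixed point.

    Solves p = (1-d) v + d (M^T p + m_dangling v), where M spreads each
    node's mass uniformly over its neighbors, v is the teleport vector
    and the mass of degree-zero nodes returns to v (personalized restart
    semantics, preserving sum(p) = 1).  Iteration stops when the L1
    change drops below ``cfg.tol`` or after ``cfg.max_iter`` sweeps; the
    result is L1-normalized.
    """
    cfg = cfg or ExpansionConfig()
    order = graph.node_order()
    if not order:
        raise ValueError("empty graph")
    index = {c: i for i, c in enumerate(order)}
    support = {c: w for c, w in teleport.items() if c in index and w > 0}
    dropped = [c for c in teleport if c not in index]
    if dropped:
        warnings.warn(f"teleport CUIs absent from graph: {sorted(dropped)}")
    if not support:
        raise ValueError("teleport support is empty on this graph")

    n = len(order)
    v = np.zeros(n)
    for c, w in support.items():
        v[index[c]] = w
    v /= v.sum()

    adj = graph.adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    nonzero = deg > 0
    d = cfg.damping

    p = v.copy()
    converged = False
    iterations = 0
    share = np.zeros(n)
    for iterations in range(1, cfg.max_iter + 1):
        share[:] = 0.0
        share[nonzero] = p[nonzero] / deg[nonzero]
        dangling_mass = p[~nonzero].sum()
        p_next = d * (adj @ share) + (d * dangling_mass + (1.0 - d)) * v
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < cfg.tol:
            converged = True
            break
    p = p / p.sum()
    return PPVVector(
        scores={c: float(p[index[c]]) for c in order},
        iterations_used=iterations,
        converged=converged,
    )


@dataclass(frozen=True)
class WeightedConcept:
    """A candidate expansion concept with its re-ranking ingredients."""

    cui: str
    ppv: float
    idf: float
    weight: float


def weight_concepts(
    ppv: PPVVector,
    repo: IdfRepository,
    cfg: ExpansionConfig | None = None,
) -> list[WeightedConcept]:
    """Re-rank the top-PPV candidates by w = p^gamma * idf.

    Takes the ``top_candidates`` concepts by PPV and returns them sorted
    by weight descending; ties break by higher PPV, then CUI.
    """
    cfg = cfg or ExpansionConfig()
    out = []
    for cui, p in ppv.top(cfg.top_candidates):
        concept_idf = idf(repo, cui, cfg.log_base)
        weight = (p ** cfg.gamma) * concept_idf
        out.append(WeightedConcept(cui=cui, ppv=p, idf=concept_idf,
                                   weight=weight))
    out.sort(key=lambda w: (-w.weight, -w.ppv, w.cui))
    return out


@dataclass
class ExpandedQuery:
    """Normalized query text plus original and expansion concepts.

    Original CUIs carry an implicit weight of 1.0; expansion concepts
    carry their re-ranking weight and never include an original CUI.
    ``mapped`` is False when no CUI could be mapped from the text, in
    which case retrieval falls back to pure text matching.
    """

    text_terms: list[str]
    original_cuis: list[str]
    expansion: list[WeightedConcept]
    mapped: bool = True


def expand(
    query_text: str,
    graph: OntologyGraph,
    dictionary: ConceptDictionary,
    repo: IdfRepository,
    cfg: ExpansionConfig | None = None,
) -> ExpandedQuery:
    """Full expansion pipeline for a free-text query.

    normalize -> map to CUIs -> uniform teleport -> Personalized
    PageRank -> idf re-weighting -> drop the original CUIs -> keep the
    ``top_expansion`` concepts.
    """
    cfg = cfg or ExpansionConfig()
    terms = normalize_text(query_text, dictionary.stoplist)
    cuis = map_cuis(query_text, dictionary)
    seeds = [c for c in cuis if c in graph]
    if not seeds:
        return ExpandedQuery(text_terms=terms, original_cuis=[],
                             expansion=[], mapped=False)
    teleport = uniform_teleport(seeds, graph)
    ppv = personalized_pagerank(graph, teleport, cfg)
    weighted = weight_concepts(ppv, repo, cfg)
    seed_set = set(seeds)
    expansion = [w for w in weighted if w.cui not in seed_set]
    return ExpandedQuery(
        text_terms=terms,
        original_cuis=seeds,
        expansion=expansion[: cfg.top_expansion],
        mapped=True,
    )
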