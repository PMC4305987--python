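"""Candidate gene-pair similarity measures.

Seven established measures span the main families in the GO literature:
annotation-set overlap (SimUI, TO), information content of the most
informative common ancestor (Resnik, Schlicker, SimGIC), graph topology
(Wang) and IC-weighted path structure (HRSS).  A deliberately bad
``fake`` measure is also provided to probe the robustness of the
downstream integration.

Term-level measures are lifted to gene level by the best-match average
(BMA) over each gene's direct annotation sets.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .ontology import AnnotationCorpus, ICTable, OntologyDAG

log = logging.getLogger(__name__)

#: the candidate measure pool
S_ALL = ("simui", "to", "simgic", "resnik", "schlicker", "wang", "hrss")

TERM_MEASURES = ("resnik", "schlicker", "wang", "hrss")
SET_MEASURES = ("simui", "to", "simgic")

#: Wang semantic-contribution weights per edge relation
WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def pair_key(g1: str, g2: str) -> tuple:
    """Canonical (sorted) key for an unordered gene pair."""
    return (g1, g2) if g1 <= g2 else (g2, g1)


@dataclass
class SimilarityMatrix:
    """Raw similarity scores over all unordered pairs of a gene set."""

    measure: str
    scores: dict
    gene_set: frozenset

    def get(self, g1: str, g2: str) -> float:
        return self.scores[pair_key(g1, g2)]

    def pairs(self) -> list:
        return sorted(self.scores)

    def subset(self, genes) -> "SimilarityMatrix":
        """Restrict to pairs with both genes in *genes* (raw scores are
        per-pair, so subsetting never changes a retained value)."""
        genes = frozenset(genes)
        missing = genes - self.gene_set
        if missing:
            raise KeyError(f"genes not covered by matrix: {sorted(missing)}")
        scores = {p: s for p, s in self.scores.items() if p[0] in genes and p[1] in genes}
        return SimilarityMatrix(self.measure, scores, genes)


# ---------------------------------------------------------------------------
# term-level similarity


def mica(dag: OntologyDAG, ic: ICTable, t1: str, t2: str) -> str:
    """Most informative common ancestor (highest IC; ties by term id)."""
    common = dag.ancestors(t1) & dag.ancestors(t2)
    candidates = [t for t in common if ic.defined(t)]
    if not candidates:
        raise ValueError(f"no IC-defined common ancestor of {t1} and {t2}")
    return max(candidates, key=lambda t: (ic.ic[t], t))


def _wang_svalues(dag: OntologyDAG, term: str, weights=WANG_WEIGHTS) -> dict:
    """Wang S-values of *term*'s ancestor subgraph.

    S(term) = 1; S(t) = max over child edges within the subgraph of
    w(relation) * S(child), propagated from *term* up to the root.
    """
    cache = getattr(dag, "_wang_cache", None)
    if cache is None:
        cache = dag._wang_cache = {}
    cached = cache.get(term)
    if cached is not None:
        return cached
    anc = dag.ancestors(term)
    sub = dag.graph.subgraph(anc)
    svals = {term: 1.0}
    # topological order of child->parent edges visits children first
    import networkx as nx

    for node in nx.topological_sort(sub):
        s_node = svals.get(node)
        if s_node is None:
            continue
        for parent in sub.successors(node):
            w = weights[sub.edges[node, parent]["relation"]]
            cand = w * s_node
            if cand > svals.get(parent, 0.0):
                svals[parent] = cand
    cache[term] = svals
    return svals


def _most_informative_leaf(dag: OntologyDAG, ic: ICTable, term: str) -> float:
    """IC of the most informative IC-defined leaf descendant of *term*.

    A leaf term is its own MIL.  Falls back to ic(term) when no leaf
    descendant carries a defined IC.
    """
    cached = ic._mil.get(term)
    if cached is not None:
        return cached
    if dag.is_leaf(term):
        val = ic.ic[term]
    else:
        leaf_ics = [
            ic.ic[t]
            for t in dag.descendants(term)
            if dag.is_leaf(t) and ic.defined(t)
        ]
        val = max(leaf_ics, default=ic.ic[term])
    ic._mil[term] = val
    return val


def term_similarity(
    dag: OntologyDAG, ic: ICTable, t1: str, t2: str, measure: str
) -> float:
    """Similarity of two GO terms under one of the term-level measures.

    ``resnik``
        ic(MICA), un-normalised (only ranks are used downstream).
    ``schlicker``
        2·ic(MICA)/(ic(t1)+ic(t2)) · (1 − p(MICA)); 0 when both terms
        are the root.
    ``wang``
        overlap of Wang S-values relative to the semantic values of the
        two ancestor subgraphs.
    ``hrss``
        1/(1+γ) · α/(α+β) with α = ic(MICA), γ the IC distance of both
        terms to the MICA, and β the mean IC distance to each term's
        most informative leaf; 0 when α = β = 0.
    """
    if measure not in TERM_MEASURES:
        raise ValueError(f"unknown term measure {measure!r}")
    for t in (t1, t2):
        if not ic.defined(t):
            raise ValueError(f"term {t!r} has undefined IC")

    if measure == "wang":
        s1 = _wang_svalues(dag, t1)
        s2 = _wang_svalues(dag, t2)
        common = set(s1) & set(s2)
        sv1 = sum(s1.values())
        sv2 = sum(s2.values())
        return sum(s1[t] + s2[t] for t in common) / (sv1 + sv2)

    anc = mica(dag, ic, t1, t2)
    alpha = ic.ic[anc]
    if measure == "resnik":
        return alpha
    if measure == "schlicker":
        denom = ic.ic[t1] + ic.ic[t2]
        if denom == 0.0:
            return 0.0
        return (2.0 * alpha / denom) * (1.0 - ic.p[anc])
    # hrss
    gamma = (ic.ic[t1] - alpha) + (ic.ic[t2] - alpha)
    beta = (
        (_most_informative_leaf(dag, ic, t1) - ic.ic[t1])
        + (_most_informative_leaf(dag, ic, t2) - ic.ic[t2])
    ) / 2.0
    if alpha + beta == 0.0:
        return 0.0
    return (1.0 / (1.0 + gamma)) * (alpha / (alpha + beta))


# ---------------------------------------------------------------------------
# gene-level similarity


def _bma(dag, ic, terms1, terms2, measure, cache) -> float:
    """Best-match average of a term measure over two direct term sets."""
    def s(u, v):
        k = (u, v) if u <= v else (v, u)
        val = cache.get(k)
        if val is None:
            val = cache[k] = term_similarity(dag, ic, u, v, measure)
        return val

    fwd = sum(max(s(t, u) for u in terms2) for t in terms1)
    rev = sum(max(s(t, u) for t in terms1) for u in terms2)
    return (fwd + rev) / (len(terms1) + len(terms2))


def gene_similarity(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    ic: ICTable,
    g1: str,
    g2: str,
    measure: str,
    _cache: dict | None = None,
) -> float:
    """Similarity of two annotated genes under a candidate measure.

    Set measures work on the ancestor-closed annotation sets; term
    measures are lifted by best-match average over the direct sets.
    """
    for g in (g1, g2):
        if g not in corpus.gene_universe:
            raise KeyError(f"gene {g!r} is not annotated")
    if measure in SET_MEASURES:
        c1, c2 = corpus.closed[g1], corpus.closed[g2]
        inter = c1 & c2
        if measure == "simui":
            return len(inter) / len(c1 | c2)
        if measure == "to":
            return len(inter) / min(len(c1), len(c2))
        union = c1 | c2
        denom = sum(ic.ic[t] for t in union)
        if denom == 0.0:
            # every shared term is uninformative; the closed sets carry the
            # same (zero) information content
            return 1.0
        return sum(ic.ic[t] for t in inter) / denom
    if measure not in TERM_MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    cache = {} if _cache is None else _cache
    return _bma(dag, ic, corpus.direct[g1], corpus.direct[g2], measure, cache)


def similarity_matrices(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    ic: ICTable,
    gene_set,
    measures=S_ALL,
) -> list:
    """One :class:`SimilarityMatrix` per measure over all unordered pairs."""
    genes = sorted(set(gene_set))
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    unknown = [g for g in genes if g not in corpus.gene_universe]
    if unknown:
        raise KeyError(f"unannotated genes: {unknown}")
    out = []
    for measure in measures:
        cache: dict = {}
        scores = {}
        for g1, g2 in itertools.combinations(genes, 2):
            try:
                scores[pair_key(g1, g2)] = gene_similarity(
                    corpus, dag, ic, g1, g2, measure, _cache=cache
                )
            except Exception as exc:  # pragma: no cover - context re-raise
                raise type(exc)(f"pair ({g1}, {g2}), measure {measure}: {exc}") from exc
        out.append(SimilarityMatrix(measure, scores, frozenset(genes)))
    return out


def fake_measure(resnik_matrix: SimilarityMatrix, grouping, seed: int) -> SimilarityMatrix:
    """Deliberately low-quality measure used to probe integration robustness.

    A uniformly random half of the pairs (⌈n/2⌉, seeded) copy the Resnik
    score; every remaining pair scores 0 when the genes share a group
    (same EC) and 1 otherwise — the reversal is what makes it bad.
    Pairs with no group assignment fall on the "different group" side.
    """
    pairs = resnik_matrix.pairs()
    n = len(pairs)
    rng = np.random.default_rng(seed)
    copy_idx = set(rng.choice(n, size=math.ceil(n / 2), replace=False).tolist())
    membership: dict = {}
    for gid, genes in grouping.groups.items():
        for g in genes:
            membership.setdefault(g, set()).add(gid)
    scores = {}
    for i, (g1, g2) in enumerate(pairs):
        if i in copy_idx:
            scores[(g1, g2)] = resnik_matrix.scores[(g1, g2)]
            continue
        m1 = membership.get(g1)
        m2 = membership.get(g2)
        if m1 is None or m2 is None:
            log.info("fake measure: pair (%s, %s) has no group assignment", g1, g2)
            scores[(g1, g2)] = 1.0
        else:
            scores[(g1, g2)] = 0.0 if m1 & m2 else 1.0
    return SimilarityMatrix("fake", scores, resnik_matrix.gene_set)


# ---------------------------------------------------------------------------
# matrix TSV round trip


def write_matrix_tsv(matrix: SimilarityMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tscore\n")
        for g1, g2 in matrix.pairs():
            fh.write(f"{g1}\t{g2}\t{matrix.scores[(g1, g2)]!r}\n")


def read_matrix_tsv(path, measure: str) -> SimilarityMatrix:
    scores = {}
    genes = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene1\tgene2\tscore"):
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            g1, g2, score = line.rstrip("\n").split("\t")
            scores[pair_key(g1, g2)] = float(score)
            genes.update((g1, g2))
    return SimilarityMatrix(measure, scores, frozenset(genes))
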