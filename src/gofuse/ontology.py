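"""Gene Ontology structure and annotation handling.

Reads OBO term graphs (restricted to one aspect), GAF 2.x annotation
files, and derives an annotation-frequency information-content (IC)
table.  These are the inputs shared by every IC-based similarity
measure downstream.

The term graph is held as a :class:`networkx.DiGraph` whose edges point
from child to parent and carry a ``relation`` attribute.  Only ``is_a``
and ``part_of`` edges are retained; these are the relations the source
definitions of the integrated measures traverse.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import obonet

log = logging.getLogger(__name__)

#: aspect code -> OBO namespace string
ASPECT_NAMESPACE = {
    "MF": "molecular_function",
    "BP": "biological_process",
    "CC": "cellular_component",
}

#: GAF aspect column letter -> aspect code
GAF_ASPECT_CODE = {"F": "MF", "P": "BP", "C": "CC"}

#: edge relations that are traversed
RELATIONS = ("is_a", "part_of")


class OntologyStructureError(ValueError):
    """The term graph violates acyclicity or single-rootedness."""


@dataclass
class OntologyDAG:
    """Rooted acyclic term graph for a single GO aspect.

    Parameters
    ----------
    graph:
        Directed graph with child -> parent edges; each edge carries a
        ``relation`` attribute in :data:`RELATIONS`.
    aspect:
        One of ``MF``, ``BP``, ``CC``.
    root:
        The unique term with no outgoing ``is_a``/``part_of`` edge.
    """

    graph: nx.DiGraph
    aspect: str
    root: str
    _anc: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def terms(self) -> frozenset:
        return frozenset(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def parents(self, term: str) -> dict:
        """Direct parents of *term* mapped to the edge relation."""
        return {
            p: self.graph.edges[term, p]["relation"]
            for p in self.graph.successors(term)
        }

    def children(self, term: str) -> list:
        return sorted(self.graph.predecessors(term))

    def is_leaf(self, term: str) -> bool:
        return self.graph.in_degree(term) == 0

    def leaves(self) -> list:
        return sorted(t for t in self.graph if self.graph.in_degree(t) == 0)

    def ancestors(self, term: str) -> frozenset:
        """Reflexive transitive ancestor closure of *term*.

        Includes *term* itself, so identical annotation sets give
        similarity 1 under the set-overlap measures.  Memoised.
        """
        if term not in self.graph:
            raise KeyError(f"unknown term: {term!r}")
        cached = self._anc.get(term)
        if cached is None:
            acc = {term}
            for p in self.graph.successors(term):
                acc |= self.ancestors(p)
            cached = self._anc[term] = frozenset(acc)
        return cached

    def descendants(self, term: str) -> frozenset:
        """Reflexive descendant closure (terms whose closure contains *term*)."""
        if term not in self.graph:
            raise KeyError(f"unknown term: {term!r}")
        # edges run child -> parent, so graph-ancestors are term descendants
        return frozenset(nx.ancestors(self.graph, term)) | {term}

    def close(self, terms) -> frozenset:
        """Union of reflexive ancestor closures over *terms*."""
        acc: set = set()
        for t in terms:
            acc |= self.ancestors(t)
        return frozenset(acc)


@dataclass
class AnnotationCorpus:
    """Gene -> GO term assignments with ancestor closure.

    ``closed[g]`` is ``direct[g]`` unioned with every ancestor of every
    directly annotated term (including the aspect root).
    """

    direct: dict
    closed: dict
    gene_universe: frozenset

    def __len__(self) -> int:
        return len(self.gene_universe)


@dataclass
class ICTable:
    """Annotation probability and information content per term.

    ``p[t]`` is the fraction of annotated genes whose closed set
    contains ``t``; ``ic[t] = -ln p[t]`` (nats) is defined only where
    ``p[t] > 0``.  Terms with undefined IC are excluded from MICA
    candidacy.
    """

    p: dict
    ic: dict
    _mil: dict = field(default_factory=dict, repr=False, compare=False)

    def defined(self, term: str) -> bool:
        return term in self.ic


def _validate_structure(graph: nx.DiGraph, aspect: str) -> str:
    if graph.number_of_nodes() == 0:
        raise OntologyStructureError(f"no terms for aspect {aspect}")
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyStructureError(f"term graph contains a cycle: {cycle}")
    roots = [t for t in graph if graph.out_degree(t) == 0]
    if len(roots) != 1:
        raise OntologyStructureError(
            f"expected exactly one root for aspect {aspect}, found {sorted(roots)}"
        )
    return roots[0]


def parse_obo(path, aspect: str) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    Terms are restricted to the namespace of *aspect* (terms without a
    namespace line are kept, which covers minimal hand-written files).
    Obsolete terms are dropped, and only ``is_a`` / ``part_of`` edges
    between retained terms survive.

    Raises
    ------
    OntologyStructureError
        If the filtered graph is cyclic or does not have exactly one root.
    """
    if aspect not in ASPECT_NAMESPACE:
        raise ValueError(f"unknown aspect {aspect!r}")
    multi = obonet.read_obo(path, ignore_obsolete=True)
    namespace = ASPECT_NAMESPACE[aspect]

    keep = set()
    for term, data in multi.nodes(data=True):
        if not data:
            # node implied only by a dangling edge (e.g. to an obsolete term)
            continue
        ns = data.get("namespace")
        if ns is None or ns == namespace:
            keep.add(term)

    graph = nx.DiGraph()
    graph.add_nodes_from(keep)
    for child, parent, relation in multi.edges(keys=True):
        if relation not in RELATIONS:
            continue
        if child not in keep or parent not in keep:
            continue
        if graph.has_edge(child, parent):
            # duplicate typed edge between the same terms: is_a wins
            if graph.edges[child, parent]["relation"] == "is_a":
                continue
        graph.add_edge(child, parent, relation=relation)

    root = _validate_structure(graph, aspect)
    return OntologyDAG(graph=graph, aspect=aspect, root=root)


def corpus_from_direct(dag: OntologyDAG, direct) -> AnnotationCorpus:
    """Build a corpus (with ancestor closure) from gene -> term-set pairs.

    Genes whose term set is empty after filtering are dropped.
    """
    clean_direct = {}
    closed = {}
    for gene, terms in direct.items():
        terms = frozenset(t for t in terms if t in dag)
        if not terms:
            continue
        clean_direct[gene] = terms
        closed[gene] = dag.close(terms)
    return AnnotationCorpus(
        direct=clean_direct,
        closed=closed,
        gene_universe=frozenset(clean_direct),
    )


def parse_gaf(
    path,
    dag: OntologyDAG,
    *,
    evidence_codes=None,
    strict: bool = False,
) -> AnnotationCorpus:
    """Parse a GAF 2.1/2.2 file against *dag*.

    Rows are skipped when the aspect column disagrees with
    ``dag.aspect``, when the qualifier contains ``NOT``, or (with a
    warning) when the annotated term is unknown.  *evidence_codes*, if
    given, is an allowlist applied to column 7.

    Parameters
    ----------
    strict:
        Turn unknown-term rows into a hard error instead of a warning.
    """
    direct: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise ValueError(f"{path}:{lineno}: GAF row has {len(cols)} columns")
            gene = cols[1]
            qualifier = cols[3]
            term = cols[4]
            evidence = cols[6]
            aspect_code = cols[8]
            if "NOT" in qualifier.split("|"):
                continue
            if GAF_ASPECT_CODE.get(aspect_code) != dag.aspect:
                continue
            if evidence_codes is not None and evidence not in evidence_codes:
                continue
            if term not in dag:
                msg = f"{path}:{lineno}: annotation to unknown term {term!r}"
                if strict:
                    raise ValueError(msg)
                log.warning("%s (skipped)", msg)
                continue
            direct.setdefault(gene, set()).add(term)
    return corpus_from_direct(dag, direct)


def compute_ic(dag: OntologyDAG, corpus: AnnotationCorpus) -> ICTable:
    """Annotation-frequency information content over the closed corpus.

    ``p(t)`` is the number of genes whose closed annotation set contains
    ``t`` divided by the number of annotated genes; ``ic = -ln p`` where
    ``p > 0``.  The root has ``p = 1`` and ``ic = 0`` by construction.
    """
    n = len(corpus.gene_universe)
    if n == 0:
        raise ValueError("empty annotation corpus")
    counts: dict = {}
    for terms in corpus.closed.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    p = {t: counts.get(t, 0) / n for t in dag.terms}
    ic = {t: -math.log(pt) for t, pt in p.items() if pt > 0}
    return ICTable(p=p, ic=ic)
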