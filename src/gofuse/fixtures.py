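"""Seeded synthetic ontologies, annotation corpora and gene groupings.

Every stage of the pipeline is testable offline on toy data generated
here: a rooted term DAG of configurable depth and branching (with a
sprinkling of ``part_of`` cross-edges), plus an annotation corpus with
*planted functional signal* — genes are partitioned into disjoint
groups, each group owns a disjoint pool of leaf terms, and a gene draws
each in-pool leaf with probability ``p_in`` and each off-pool leaf with
``p_out`` (``p_out < p_in``), so genes within a group share terms more
often than genes across groups.

All output (OBO, GAF 2.2, grouping TSV) is byte-identical across runs
for the same seed.  The files are explicitly synthetic; they emulate the
shape of real GO inputs, not their topology statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .objective import ECGrouping
from .ontology import (
    ASPECT_NAMESPACE,
    AnnotationCorpus,
    OntologyDAG,
    corpus_from_direct,
)

GAF_CODE = {"MF": "F", "BP": "P", "CC": "C"}


@dataclass
class FixtureSpec:
    """Shape and signal parameters of one synthetic data set."""

    depth: int = 3
    branching: int = 3
    n_groups: int = 5
    genes_per_group: int = 6
    p_in: float = 0.8
    p_out: float = 0.1
    seed: int = 0
    aspect: str = "MF"
    part_of_fraction: float = 0.1

    def __post_init__(self):
        if self.depth < 1 or self.branching < 1:
            raise ValueError("depth and branching must be positive")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_groups < 1 or self.genes_per_group < 1:
            raise ValueError("group shape parameters must be positive")

    @property
    def n_terms(self) -> int:
        """Tree size before cross-edges: sum of branching**level."""
        return sum(self.branching**level for level in range(self.depth + 1))


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def make_toy_ontology(spec: FixtureSpec, obo_path=None) -> OntologyDAG:
    """Build a rooted DAG: a complete tree of ``is_a`` edges plus ~10%
    extra ``part_of`` cross-edges to strictly shallower terms (which
    keeps the graph acyclic and the root unique).

    If *obo_path* is given, a valid OBO 1.2 file is written;
    :func:`~gofuse.ontology.parse_obo` round-trips it.
    """
    rng = np.random.default_rng(spec.seed)
    graph = nx.DiGraph()
    levels = [[0]]
    next_id = 1
    graph.add_node(_term_id(0))
    for depth in range(1, spec.depth + 1):
        level = []
        for parent in levels[depth - 1]:
            for _ in range(spec.branching):
                graph.add_edge(_term_id(next_id), _term_id(parent), relation="is_a")
                level.append(next_id)
                next_id += 1
        levels.append(level)
    depth_of = {
        _term_id(i): d for d, level in enumerate(levels) for i in level
    }
    non_root = sorted(t for t in graph if t != _term_id(0))
    n_cross = int(round(spec.part_of_fraction * len(non_root)))
    for term in rng.choice(non_root, size=n_cross, replace=False):
        shallower = [
            t for t in graph if depth_of[t] < depth_of[term] and not graph.has_edge(term, t)
        ]
        if not shallower:
            continue
        target = sorted(shallower)[rng.integers(len(shallower))]
        graph.add_edge(term, target, relation="part_of")

    dag = OntologyDAG(graph=graph, aspect=spec.aspect, root=_term_id(0))
    if obo_path is not None:
        write_obo(dag, obo_path)
    return dag


def write_obo(dag: OntologyDAG, path) -> None:
    """Deterministic minimal OBO 1.2 serialisation of *dag*."""
    namespace = ASPECT_NAMESPACE[dag.aspect]
    lines = ["format-version: 1.2", "ontology: gofuse-synthetic", ""]
    for term in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: synthetic term {term}")
        lines.append(f"namespace: {namespace}")
        for parent, relation in sorted(dag.parents(term).items()):
            if relation == "is_a":
                lines.append(f"is_a: {parent} ! synthetic term {parent}")
            else:
                lines.append(f"relationship: part_of {parent} ! synthetic term {parent}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def write_gaf(corpus: AnnotationCorpus, aspect: str, path) -> None:
    """Deterministic GAF 2.2 serialisation of the direct annotations."""
    code = GAF_CODE[aspect]
    rows = []
    for gene in sorted(corpus.direct):
        for term in sorted(corpus.direct[gene]):
            rows.append(
                "\t".join(
                    [
                        "SYNT",  # DB
                        gene,  # DB object id
                        gene,  # symbol
                        "enables",  # qualifier
                        term,  # GO id
                        "SYNT:0000001",  # reference
                        "IEA",  # evidence
                        "",  # with/from
                        code,  # aspect
                        f"synthetic gene {gene}",
                        "",  # synonym
                        "protein",
                        "taxon:0000",
                        "20200101",
                        "SYNT",
                        "",
                        "",
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        fh.write("\n".join(rows) + "\n")


def make_annotated_groups(
    dag: OntologyDAG,
    spec: FixtureSpec,
    gaf_path=None,
    grouping_path=None,
):
    """Planted-signal corpus and grouping over *dag*.

    Leaf terms are shuffled (seeded) and split into ``n_groups``
    disjoint pools; leftover leaves act as background only.  Each gene
    draws every in-pool leaf with ``p_in`` and every off-pool leaf with
    ``p_out``; empty draws are retried a bounded number of times.
    Returns ``(corpus, grouping)`` and optionally writes GAF 2.2 and the
    2-column grouping TSV.
    """
    rng = np.random.default_rng(spec.seed + 1)
    leaves = dag.leaves()
    pool_size = len(leaves) // spec.n_groups
    if pool_size < 1:
        raise ValueError(
            f"{len(leaves)} leaves cannot support {spec.n_groups} disjoint pools"
        )
    shuffled = list(rng.permutation(leaves))
    pools = [
        shuffled[g * pool_size : (g + 1) * pool_size] for g in range(spec.n_groups)
    ]
    direct: dict = {}
    groups: dict = {}
    for g, pool in enumerate(pools):
        gid = f"1.1.1.{g + 1}"
        pool_set = set(pool)
        background = [t for t in leaves if t not in pool_set]
        members = set()
        for i in range(spec.genes_per_group):
            gene = f"g{g:02d}_{i:02d}"
            for _ in range(100):
                terms = {t for t in pool if rng.random() < spec.p_in}
                terms |= {t for t in background if rng.random() < spec.p_out}
                if terms:
                    break
            else:
                raise RuntimeError(f"gene {gene} drew no terms after 100 retries")
            direct[gene] = terms
            members.add(gene)
        groups[gid] = members
    corpus = corpus_from_direct(dag, direct)
    grouping = ECGrouping(groups)
    if gaf_path is not None:
        write_gaf(corpus, dag.aspect, gaf_path)
    if grouping_path is not None:
        grouping.to_tsv(grouping_path)
    return corpus, grouping
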