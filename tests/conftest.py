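"""Shared fixtures: hand-built micro-DAGs and a seeded planted-signal corpus."""

import networkx as nx
import pytest

from gofuse.fixtures import FixtureSpec, make_annotated_groups, make_toy_ontology
from gofuse.measures import S_ALL, similarity_matrices
from gofuse.ontology import OntologyDAG, compute_ic, corpus_from_direct


def build_dag(edges, aspect="MF", extra_terms=()):
    """OntologyDAG from (child, parent, relation) triples."""
    graph = nx.DiGraph()
    for child, parent, relation in edges:
        graph.add_edge(child, parent, relation=relation)
    graph.add_nodes_from(extra_terms)
    roots = [t for t in graph if graph.out_degree(t) == 0]
    assert len(roots) == 1, roots
    return OntologyDAG(graph=graph, aspect=aspect, root=roots[0])


@pytest.fixture
def chain_dag():
    """A <- B <- C plus A <- B <- D (closed sets {A,B,C} / {A,B,D})."""
    return build_dag(
        [("B", "A", "is_a"), ("C", "B", "is_a"), ("D", "B", "is_a")]
    )


@pytest.fixture
def diamond_dag():
    """Diamond: D below both B and C, which sit below root A."""
    return build_dag(
        [
            ("B", "A", "is_a"),
            ("C", "A", "part_of"),
            ("D", "B", "is_a"),
            ("D", "C", "is_a"),
        ]
    )


@pytest.fixture(scope="session")
def planted():
    """Planted-signal study corpus: 5 groups x 6 genes, p_in=0.8, p_out=0.1."""
    spec = FixtureSpec(
        depth=3, branching=3, n_groups=5, genes_per_group=6,
        p_in=0.8, p_out=0.1, seed=11,
    )
    dag = make_toy_ontology(spec)
    corpus, grouping = make_annotated_groups(dag, spec)
    ic = compute_ic(dag, corpus)
    return dag, corpus, ic, grouping


@pytest.fixture(scope="session")
def planted_matrices(planted):
    dag, corpus, ic, grouping = planted
    return similarity_matrices(corpus, dag, ic, sorted(corpus.gene_universe), S_ALL)


@pytest.fixture
def small_corpus(chain_dag):
    """Four genes on the chain DAG; p(B)=1, p(C)=p(D)=0.5."""
    direct = {
        "g1": {"C"},
        "g2": {"C"},
        "g3": {"D"},
        "g4": {"D"},
    }
    corpus = corpus_from_direct(chain_dag, direct)
    return corpus, compute_ic(chain_dag, corpus)
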