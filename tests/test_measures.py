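"""Candidate similarity measures: hand-computed values and brute-force oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from conftest import build_dag
from gofuse.fixtures import FixtureSpec, make_annotated_groups, make_toy_ontology
from gofuse.measures import (
    S_ALL,
    WANG_WEIGHTS,
    _wang_svalues,
    fake_measure,
    gene_similarity,
    mica,
    pair_key,
    read_matrix_tsv,
    similarity_matrices,
    term_similarity,
    write_matrix_tsv,
)
from gofuse.objective import ECGrouping
from gofuse.ontology import compute_ic, corpus_from_direct


class TestTermSimilarity:
    def test_resnik_root_only_ancestor(self, chain_dag, small_corpus):
        corpus, ic = small_corpus
        dag = build_dag([("B", "A", "is_a"), ("C", "A", "is_a")])
        corpus2 = corpus_from_direct(dag, {"g1": {"B"}, "g2": {"C"}})
        ic2 = compute_ic(dag, corpus2)
        assert term_similarity(dag, ic2, "B", "C", "resnik") == 0.0

    def test_schlicker_self_similarity(self, chain_dag):
        # p(C) = 0.25 -> schlicker(C, C) = 1 * (1 - 0.25)
        corpus = corpus_from_direct(
            chain_dag, {"g1": {"C"}, "g2": {"B"}, "g3": {"B"}, "g4": {"B"}}
        )
        ic = compute_ic(chain_dag, corpus)
        assert ic.p["C"] == 0.25
        assert term_similarity(chain_dag, ic, "C", "C", "schlicker") == pytest.approx(0.75)

    def test_schlicker_root_pair_is_zero(self, small_corpus, chain_dag):
        _, ic = small_corpus
        assert term_similarity(chain_dag, ic, "A", "A", "schlicker") == 0.0

    def test_wang_single_edge(self, small_corpus, chain_dag):
        # S_B = {B:1, A:0.8}; S_A = {A:1}; common {A} -> (0.8+1)/(1.8+1)
        _, ic = small_corpus
        value = term_similarity(chain_dag, ic, "B", "A", "wang")
        assert value == pytest.approx((0.8 + 1.0) / (1.8 + 1.0))

    def test_hrss_leaf_self_similarity(self, small_corpus, chain_dag):
        corpus, ic = small_corpus
        assert chain_dag.is_leaf("C")
        assert ic.ic["C"] > 0
        assert term_similarity(chain_dag, ic, "C", "C", "hrss") == pytest.approx(1.0)

    def test_hrss_degenerate_root_pair(self, small_corpus, chain_dag):
        _, ic = small_corpus
        # alpha = ic(root) = 0 and beta averages leaf distances; finite result
        value = term_similarity(chain_dag, ic, "A", "A", "hrss")
        assert value == 0.0

    def test_undefined_ic_errors(self, chain_dag):
        corpus = corpus_from_direct(chain_dag, {"g": {"C"}})
        ic = compute_ic(chain_dag, corpus)
        with pytest.raises(ValueError, match="undefined IC"):
            term_similarity(chain_dag, ic, "C", "D", "resnik")


def random_dag(rng, n_terms):
    """Random rooted DAG with <= n_terms terms and mixed relations."""
    graph = nx.DiGraph()
    terms = [f"T{i}" for i in range(n_terms)]
    graph.add_node(terms[0])
    for i in range(1, n_terms):
        n_parents = 1 + (rng.random() < 0.3)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            graph.add_edge(terms[i], terms[p], relation=rel)
    from gofuse.ontology import OntologyDAG, _validate_structure

    # may create several roots: hang extras under T0
    for t in list(graph.nodes):
        if t != terms[0] and graph.out_degree(t) == 0:
            graph.add_edge(t, terms[0], relation="is_a")
    root = _validate_structure(graph, "MF")
    return OntologyDAG(graph=graph, aspect="MF", root=root)


class TestBruteForceOracles:
    @pytest.mark.parametrize("seed", range(10))
    def test_wang_svalues_match_path_products(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, 8)
        for term in dag.terms:
            svals = _wang_svalues(dag, term)
            for anc in dag.ancestors(term):
                best = 1.0 if anc == term else 0.0
                for path in nx.all_simple_paths(dag.graph, term, anc):
                    prod = 1.0
                    for u, v in zip(path, path[1:]):
                        prod *= WANG_WEIGHTS[dag.graph.edges[u, v]["relation"]]
                    best = max(best, prod)
                assert svals[anc] == pytest.approx(best)

    @pytest.mark.parametrize("seed", range(10))
    def test_mica_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed + 100)
        dag = random_dag(rng, 8)
        terms = sorted(dag.terms)
        direct = {f"g{i}": {rng.choice(terms)} for i in range(6)}
        corpus = corpus_from_direct(dag, direct)
        ic = compute_ic(dag, corpus)
        defined = [t for t in terms if ic.defined(t)]
        for t1, t2 in itertools.combinations(defined, 2):
            common = [
                t for t in dag.ancestors(t1) & dag.ancestors(t2) if ic.defined(t)
            ]
            assert ic.ic[mica(dag, ic, t1, t2)] == pytest.approx(
                max(ic.ic[t] for t in common)
            )


class TestGeneSimilarity:
    def test_simui_is_jaccard(self, chain_dag):
        corpus = corpus_from_direct(chain_dag, {"g1": {"C"}, "g2": {"D"}})
        ic = compute_ic(chain_dag, corpus)
        # closed sets {A,B,C} and {A,B,D}
        assert gene_similarity(corpus, chain_dag, ic, "g1", "g2", "simui") == 0.5

    def test_identical_annotations_scores_one(self, chain_dag):
        corpus = corpus_from_direct(chain_dag, {"g1": {"C", "D"}, "g2": {"C", "D"}})
        ic = compute_ic(chain_dag, corpus)
        for m in ("simui", "to", "simgic", "wang"):
            assert gene_similarity(corpus, chain_dag, ic, "g1", "g2", m) == pytest.approx(1.0)

    def test_root_only_overlap_ic_measures_zero(self):
        dag = build_dag([("B", "A", "is_a"), ("C", "A", "is_a")])
        corpus = corpus_from_direct(dag, {"g1": {"B"}, "g2": {"C"}})
        ic = compute_ic(dag, corpus)
        for m in ("resnik", "schlicker", "hrss"):
            assert gene_similarity(corpus, dag, ic, "g1", "g2", m) == 0.0

    def test_unannotated_gene_named_in_error(self, chain_dag):
        corpus = corpus_from_direct(chain_dag, {"g1": {"C"}, "g2": {"D"}})
        ic = compute_ic(chain_dag, corpus)
        with pytest.raises(KeyError, match="ghost"):
            gene_similarity(corpus, chain_dag, ic, "g1", "ghost", "simui")


class TestSimilarityMatrices:
    def test_cardinality(self, planted, planted_matrices):
        assert len(planted_matrices) == len(S_ALL)
        n = len(planted[1].gene_universe)
        for m in planted_matrices:
            assert len(m.scores) == n * (n - 1) // 2

    def test_matches_per_pair_recomputation(self, planted, planted_matrices):
        dag, corpus, ic, _ = planted
        rng = np.random.default_rng(0)
        genes = sorted(corpus.gene_universe)
        for matrix in planted_matrices:
            for _ in range(5):
                g1, g2 = rng.choice(genes, size=2, replace=False)
                assert matrix.get(g1, g2) == pytest.approx(
                    gene_similarity(corpus, dag, ic, g1, g2, matrix.measure)
                )

    def test_gene_order_invariance(self, planted):
        dag, corpus, ic, _ = planted
        genes = sorted(corpus.gene_universe)[:6]
        a = similarity_matrices(corpus, dag, ic, genes, ["simui"])[0]
        b = similarity_matrices(corpus, dag, ic, genes[::-1], ["simui"])[0]
        assert a.scores == b.scores

    def test_bounded_measures_stay_in_unit_interval(self, planted_matrices):
        for matrix in planted_matrices:
            values = np.array(list(matrix.scores.values()))
            assert (values >= 0).all()
            if matrix.measure != "resnik":
                assert (values <= 1 + 1e-12).all()

    def test_matrix_tsv_roundtrip(self, planted_matrices, tmp_path):
        matrix = planted_matrices[0]
        write_matrix_tsv(matrix, tmp_path / "m.tsv")
        again = read_matrix_tsv(tmp_path / "m.tsv", matrix.measure)
        assert again.scores == matrix.scores


class TestFakeMeasure:
    @pytest.fixture
    def resnik_and_grouping(self, planted, planted_matrices):
        resnik = next(m for m in planted_matrices if m.measure == "resnik")
        return resnik, planted[3]

    def test_same_seed_is_deterministic(self, resnik_and_grouping):
        resnik, grouping = resnik_and_grouping
        a = fake_measure(resnik, grouping, seed=3)
        b = fake_measure(resnik, grouping, seed=3)
        assert a.scores == b.scores

    def test_half_copy_resnik_half_reversed(self, resnik_and_grouping):
        resnik, grouping = resnik_and_grouping
        fake = fake_measure(resnik, grouping, seed=3)
        membership = {}
        for gid, genes in grouping.groups.items():
            for g in genes:
                membership.setdefault(g, set()).add(gid)
        n = len(fake.scores)
        n_not01 = 0
        n_not_resnik = 0
        for pair, score in fake.scores.items():
            same = bool(membership[pair[0]] & membership[pair[1]])
            reversed01 = 0.0 if same else 1.0
            assert score in (resnik.scores[pair], reversed01)
            n_not01 += score != reversed01
            n_not_resnik += score != resnik.scores[pair]
        assert n_not01 <= math.ceil(n / 2)
        assert n_not_resnik <= n - math.ceil(n / 2)

    def test_exact_half_carries_resnik(self):
        # scores chosen away from 0/1 so the two halves are unambiguous
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(8)]
        scores = {
            pair_key(a, b): float(rng.uniform(0.2, 0.8))
            for a, b in itertools.combinations(genes, 2)
        }
        from gofuse.measures import SimilarityMatrix

        resnik = SimilarityMatrix("resnik", scores, frozenset(genes))
        grouping = ECGrouping({"e1": set(genes[:4]), "e2": set(genes[4:])})
        fake = fake_measure(resnik, grouping, seed=5)
        copied = sum(fake.scores[p] == scores[p] for p in scores)
        assert copied == math.ceil(len(scores) / 2)

    def test_ungrouped_pair_counts_as_cross_group(self, resnik_and_grouping):
        resnik, _ = resnik_and_grouping
        empty = ECGrouping({})
        fake = fake_measure(resnik, empty, seed=3)
        non_copied = [s for s in fake.scores.values() if s == 1.0]
        assert len(non_copied) >= len(fake.scores) // 2


class TestSymmetryAndSelfSimilarity:
    def test_pair_key_symmetry(self):
        assert pair_key("b", "a") == pair_key("a", "b") == ("a", "b")

    def test_self_similarity_is_one_where_defined(self, planted):
        dag, corpus, ic, _ = planted
        genes = sorted(corpus.gene_universe)[:4]
        for g in genes:
            for m in ("simui", "to", "simgic", "wang"):
                assert gene_similarity(corpus, dag, ic, g, g, m) == pytest.approx(1.0)
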