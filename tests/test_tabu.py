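"""Tabu-search trainer: neighbourhood moves, determinism, monotone progress."""

import itertools

import numpy as np
import pytest

from gofuse.integrate import GROUP_TYPES, ParameterSet
from gofuse.measures import SimilarityMatrix, pair_key
from gofuse.objective import ECGrouping
from gofuse.ranks import build_rank_matrix
from gofuse.seeds import SeedGroup, seed_groups_for
from gofuse.tabu import TrainConfig, _neighbor_vectors, neighborhood, tabu_train

MEASURES = ("m1", "m2")


class TestNeighborhood:
    def test_simplex_boundary_single_transfer(self):
        # all mass on one parameter: only it can donate
        vecs = _neighbor_vectors(np.array([1.0, 0.0]), [0.05])
        assert len(vecs) == 1
        assert np.allclose(vecs[0], [0.95, 0.05])

    def test_every_neighbor_conserves_mass(self):
        rng = np.random.default_rng(0)
        theta = rng.dirichlet(np.ones(6))
        for v in _neighbor_vectors(theta, [0.05, 0.01]):
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
            assert (v >= -1e-12).all()

    def test_count_is_steps_times_ordered_pairs(self):
        # interior point: every ordered pair valid for both step sizes
        theta = np.array([0.4, 0.3, 0.2, 0.1])
        vecs = _neighbor_vectors(theta, [0.05, 0.01])
        assert len(vecs) == 2 * 4 * 3

    def test_public_neighborhood_varies_one_type_only(self):
        rng = np.random.default_rng(1)
        params = ParameterSet.random(MEASURES, rng)
        for n in neighborhood(params, "low", [0.05]):
            n.validate()
            assert np.allclose(n.values["high"], params.values["high"])
            assert np.allclose(n.values["mix"], params.values["mix"])
            assert not np.allclose(n.values["low"], params.values["low"])


def toy_training_problem(seed=0, n_noise=1):
    """Two 3-gene groups; m1 separates them, extra measures are noise."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(6)]
    grouping = ECGrouping({"e1": set(genes[:3]), "e2": set(genes[3:])})
    pairs = [pair_key(x, y) for x, y in itertools.combinations(genes, 2)]
    intra = {p for p in pairs if (p[0] in grouping.groups["e1"]) == (p[1] in grouping.groups["e1"])}
    mats = [
        SimilarityMatrix(
            "m1",
            {p: (0.8 + 0.1 * rng.random() if p in intra else 0.1 * rng.random()) for p in pairs},
            frozenset(genes),
        )
    ]
    for j in range(n_noise):
        mats.append(
            SimilarityMatrix(
                f"n{j}", {p: float(rng.random()) for p in pairs}, frozenset(genes)
            )
        )
    rank_matrix = build_rank_matrix(mats)
    seed_groups = seed_groups_for(rank_matrix, c=2, d_prime=0.2)
    return rank_matrix, seed_groups, grouping


class TestTabuTrain:
    def test_identical_seeds_identical_parameters(self):
        rank_matrix, seed_groups, grouping = toy_training_problem()
        config = TrainConfig(seed=5, restarts=2, stability_patience=5)
        a = tabu_train(rank_matrix, seed_groups, grouping, config)
        b = tabu_train(rank_matrix, seed_groups, grouping, config)
        for t in GROUP_TYPES:
            assert np.array_equal(a.values[t], b.values[t])

    def test_best_objective_sequence_non_decreasing(self):
        rank_matrix, seed_groups, grouping = toy_training_problem()
        log = []
        config = TrainConfig(seed=3, restarts=2, stability_patience=8)
        tabu_train(rank_matrix, seed_groups, grouping, config, log=log)
        assert log, "search made no moves"
        for restart in {r["restart"] for r in log}:
            best = [r["optf_best"] for r in log if r["restart"] == restart]
            assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))
            cands = [r["optf_candidate"] for r in log if r["restart"] == restart]
            assert all(b >= c - 1e-12 for b, c in zip(best, cands))

    def test_zero_patience_returns_initial_solution(self):
        rank_matrix, seed_groups, grouping = toy_training_problem()
        config = TrainConfig(seed=9, restarts=1, stability_patience=0)
        log = []
        params = tabu_train(rank_matrix, seed_groups, grouping, config, log=log)
        params.validate()
        assert log == []  # no moves taken

    def test_degenerate_grouping_rejected(self):
        rank_matrix, seed_groups, _ = toy_training_problem()
        overlapping = ECGrouping({"e1": {"g0", "g1"}, "e2": {"g1", "g2"}})
        with pytest.raises(ValueError):
            tabu_train(
                rank_matrix, seed_groups, overlapping, TrainConfig(restarts=1)
            )

    def test_trained_beats_noise_only_weighting(self):
        rank_matrix, seed_groups, grouping = toy_training_problem(n_noise=3)
        from gofuse.objective import LogFCEvaluator

        config = TrainConfig(seed=2, restarts=2, stability_patience=10)
        params = tabu_train(rank_matrix, seed_groups, grouping, config)
        pair_index = {p: i for i, p in enumerate(rank_matrix.pairs)}
        evaluator = LogFCEvaluator(grouping, pair_index, 0.01)
        from gofuse.pipeline import integrated_sims

        sims = integrated_sims(rank_matrix, seed_groups, params)
        trained = evaluator.optf(np.array([sims[p] for p in rank_matrix.pairs]))
        noise_col = rank_matrix.ranksim["n0"].to_numpy()
        assert trained > evaluator.optf(noise_col)


class TestParameterRecovery:
    def test_planted_max_structure_favours_alpha(self):
        """When the max of the member RankSims is by construction the only
        clean separator for high-type pairs, the trained high-type vector
        puts its largest mass on alpha."""
        genes = [f"g{i}" for i in range(8)]
        grouping = ECGrouping({"e1": set(genes[:4]), "e2": set(genes[4:])})
        pairs = [pair_key(x, y) for x, y in itertools.combinations(genes, 2)]
        intra = {
            p
            for p in pairs
            if (p[0] in grouping.groups["e1"]) == (p[1] in grouping.groups["e1"])
        }
        values = {}
        flip = False
        for p in pairs:
            if p in intra:
                values[p] = (0.95, 0.2) if flip else (0.2, 0.95)
            else:
                values[p] = (0.3, 0.05) if flip else (0.05, 0.3)
            flip = not flip
        mats = [
            SimilarityMatrix("m1", {p: values[p][0] for p in pairs}, frozenset(genes)),
            SimilarityMatrix("m2", {p: values[p][1] for p in pairs}, frozenset(genes)),
        ]
        rank_matrix = build_rank_matrix(mats)
        # force every pair into the high-type branch with both members
        seed_groups = {
            p: SeedGroup(("m1", "m2"), "high", False, 1, 0, pair=p) for p in pairs
        }
        config = TrainConfig(seed=1, restarts=3, stability_patience=15)
        params = tabu_train(rank_matrix, seed_groups, grouping, config)
        high = params.values["high"]
        alpha_idx = len(params.measures)
        assert high[alpha_idx] == max(high)
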