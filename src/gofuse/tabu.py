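"""Tabu-search estimation of the addition-model parameters.

The search maximises OptF on a training grouping.  Each group type's
parameter vector lives on a probability simplex; a move transfers mass
``min(delta, donor)`` from one parameter to another within a single
type, so every neighbour stays on the simplex.  A bounded tabu list of
recently visited solutions (fingerprinted by rounding) blocks short
cycles, with the usual aspiration exception: a neighbour beating the
best solution so far is always accepted.  Types are optimised one at a
time (high, then low, then mix), cycling until a full cycle brings no
improvement, and the whole search restarts from fresh random points,
returning the best solution over all restarts.

RankSim values and seed groups are computed once and frozen before the
search; only the addition-model parameters vary.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np

from .integrate import GROUP_TYPES, ParameterSet
from .objective import ECGrouping, LogFCEvaluator


@dataclass
class TrainConfig:
    """Search hyper-parameters (none is prescribed by the method itself;
    these defaults trade runtime against search quality on small sets)."""

    step_sizes: tuple = (0.05, 0.01)
    tabu_capacity: int = 50
    stability_patience: int = 25
    restarts: int = 5
    c_smooth: float = 0.01
    divisor: str = "ej"
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.step_sizes):
            raise ValueError("step sizes must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class TrainState:
    """Mutable state of one restart (exposed mainly for introspection)."""

    current: dict
    best: dict
    best_objective: float
    tabu_list: deque
    no_improve: int = 0
    rng_seed: int = 0


class _TabuList:
    """Bounded FIFO of solution fingerprints with O(1) membership."""

    def __init__(self, capacity: int):
        self.queue: deque = deque(maxlen=max(capacity, 1))
        self.counts: Counter = Counter()

    def add(self, fp) -> None:
        if len(self.queue) == self.queue.maxlen:
            old = self.queue[0]
            self.counts[old] -= 1
            if self.counts[old] == 0:
                del self.counts[old]
        self.queue.append(fp)
        self.counts[fp] += 1

    def __contains__(self, fp) -> bool:
        return self.counts.get(fp, 0) > 0


def _fingerprint(thetas: dict) -> tuple:
    return tuple(
        np.round(np.concatenate([thetas[t] for t in GROUP_TYPES]), 4).tolist()
    )


def _neighbor_vectors(theta: np.ndarray, step_sizes) -> list:
    """Mass transfers between ordered parameter pairs, one vector each.

    Empty donors are skipped; duplicate vectors (a donor smaller than
    two different step sizes) are deduplicated.
    """
    out = []
    seen = set()
    k = len(theta)
    for donor in range(k):
        if theta[donor] <= 0.0:
            continue
        for receiver in range(k):
            if receiver == donor:
                continue
            for delta in step_sizes:
                step = min(delta, theta[donor])
                v = theta.copy()
                v[donor] -= step
                v[receiver] += step
                key = tuple(np.round(v, 12).tolist())
                if key in seen:
                    continue
                seen.add(key)
                out.append(v)
    return out


def neighborhood(params: ParameterSet, group_type: str, step_sizes) -> list:
    """Neighbour :class:`ParameterSet`\\ s varying only *group_type*."""
    params.validate()
    out = []
    for vec in _neighbor_vectors(params.values[group_type], step_sizes):
        values = {t: params.values[t].copy() for t in GROUP_TYPES}
        values[group_type] = vec
        out.append(ParameterSet(params.measures, values))
    return out


def _pair_features(rank_matrix, seed_groups, measures):
    """Per-pair feature matrix so Sim(pair) = features @ theta[type]."""
    k = len(measures)
    m_index = {m: i for i, m in enumerate(measures)}
    n = len(rank_matrix.pairs)
    features = np.zeros((n, k + 3))
    type_idx = np.zeros(n, dtype=int)
    for i, pair in enumerate(rank_matrix.pairs):
        group = seed_groups[pair]
        row = rank_matrix.ranksim_row(pair)
        vals = np.array([row[m] for m in group.members])
        for m, v in zip(group.members, vals):
            features[i, m_index[m]] = v
        features[i, k] = vals.max()
        features[i, k + 1] = vals.min()
        features[i, k + 2] = vals.mean()
        type_idx[i] = GROUP_TYPES.index(group.group_type)
    return features, type_idx


def tabu_train(
    rank_matrix,
    seed_groups: dict,
    grouping: ECGrouping,
    config: TrainConfig,
    log: list | None = None,
) -> ParameterSet:
    """Fit addition-model parameters by tabu search.

    *log*, if given, collects one record per accepted move
    (restart, iteration, type, candidate and best OptF, tabu-hit flag);
    the best-OptF column is non-decreasing within each restart.
    """
    missing = grouping.gene_universe() - rank_matrix.genes
    if missing:
        raise ValueError(f"grouping genes absent from rank matrix: {sorted(missing)}")
    measures = tuple(rank_matrix.measures)
    pair_index = {p: i for i, p in enumerate(rank_matrix.pairs)}
    evaluator = LogFCEvaluator(
        grouping, pair_index, c_smooth=config.c_smooth, divisor=config.divisor
    )
    if len(evaluator.group_ids) < 2:
        raise ValueError("need at least two groups with disjoint partners")
    features, type_idx = _pair_features(rank_matrix, seed_groups, measures)
    type_masks = [type_idx == i for i in range(len(GROUP_TYPES))]

    def sims_from(thetas: dict) -> np.ndarray:
        s = np.empty(len(type_idx))
        for i, t in enumerate(GROUP_TYPES):
            mask = type_masks[i]
            if mask.any():
                s[mask] = features[mask] @ thetas[t]
        return s

    def objective(thetas: dict) -> float:
        return evaluator.optf(sims_from(thetas))

    k = len(measures) + 3
    master = np.random.default_rng(config.seed)
    overall_best = None
    overall_best_optf = -np.inf

    for restart in range(config.restarts):
        sub_seed = int(master.integers(2**31))
        rng = np.random.default_rng(sub_seed)
        thetas = {t: rng.dirichlet(np.ones(k)) for t in GROUP_TYPES}
        state = TrainState(
            current={t: v.copy() for t, v in thetas.items()},
            best={t: v.copy() for t, v in thetas.items()},
            best_objective=objective(thetas),
            tabu_list=deque(),
            rng_seed=sub_seed,
        )
        tabu = _TabuList(config.tabu_capacity)
        tabu.add(_fingerprint(state.current))
        iteration = 0

        improved_cycle = True
        while improved_cycle:
            improved_cycle = False
            for t in GROUP_TYPES:
                t_mask = type_masks[GROUP_TYPES.index(t)]
                t_features = features[t_mask]
                no_improve = 0
                while no_improve < config.stability_patience:
                    base = sims_from(state.current)
                    candidates = []
                    for vec in _neighbor_vectors(state.current[t], config.step_sizes):
                        s = base.copy()
                        if t_mask.any():
                            s[t_mask] = t_features @ vec
                        candidates.append((evaluator.optf(s), vec))
                    if not candidates:
                        break
                    # stable sort: ties broken by enumeration order
                    order = sorted(
                        range(len(candidates)),
                        key=lambda i: -candidates[i][0],
                    )
                    accepted = None
                    tabu_hit = False
                    for i in order:
                        cand_optf, vec = candidates[i]
                        trial = dict(state.current)
                        trial[t] = vec
                        fp = _fingerprint(trial)
                        if cand_optf > state.best_objective:
                            accepted = (cand_optf, vec, fp)
                            tabu_hit = fp in tabu
                            break
                        if fp not in tabu:
                            accepted = (cand_optf, vec, fp)
                            break
                        # tabu-listed non-improving neighbour: delete and retry
                    if accepted is None:
                        break
                    cand_optf, vec, fp = accepted
                    state.current[t] = vec
                    tabu.add(fp)
                    iteration += 1
                    if cand_optf > state.best_objective:
                        state.best = {u: v.copy() for u, v in state.current.items()}
                        state.best_objective = cand_optf
                        no_improve = 0
                        improved_cycle = True
                    else:
                        no_improve += 1
                    if log is not None:
                        log.append(
                            {
                                "restart": restart,
                                "iteration": iteration,
                                "type": t,
                                "optf_candidate": cand_optf,
                                "optf_best": state.best_objective,
                                "tabu_hit": tabu_hit,
                            }
                        )
        if state.best_objective > overall_best_optf:
            overall_best_optf = state.best_objective
            overall_best = state.best

    result = ParameterSet(measures, overall_best)
    result.validate()
    return result
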