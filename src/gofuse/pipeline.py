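"""Workflow orchestration: train, score, evaluate, robustness, network.

Two entry paths mirror the method's design: a *training* path that fits
the addition-model parameters on a grouped training gene set, and a
*scoring* path that, given a trained parameter file and an arbitrary
input gene set, rank-normalises within that set, selects seed measures
per pair and applies the model.

All functions here operate on in-memory objects; :mod:`gofuse.cli`
wraps them with file I/O for shell use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from . import measures as ms
from .integrate import ParameterSet, integrate
from .objective import ECGrouping, LogFCEvaluator, logfc_summary, logfc_table, optf
from .ontology import compute_ic, parse_gaf, parse_obo
from .ranks import RankMatrix, build_rank_matrix
from .seeds import seed_groups_for
from .tabu import TrainConfig, tabu_train

log = logging.getLogger(__name__)

#: default group-size filters per aspect (EC groups need >= 3 genes,
#: pathway groups >= 2)
MIN_GROUP_SIZE = {"MF": 3, "BP": 2}


@dataclass
class RunConfig:
    """File-level configuration shared by the CLI workflows."""

    obo: str
    gaf: str
    grouping: str
    aspect: str = "MF"
    measures: tuple = ms.S_ALL
    include_fake: bool = False
    seed_min_size: int = 3
    d_prime: float = 0.10
    c_smooth: float = 0.01
    min_group_size: int | None = None
    train: TrainConfig = dataclass_field(default_factory=TrainConfig)
    params_path: str | None = None

    def group_filter(self) -> int:
        if self.min_group_size is not None:
            return self.min_group_size
        return MIN_GROUP_SIZE.get(self.aspect, 2)


@dataclass
class TrainResult:
    params: ParameterSet
    rank_matrix: RankMatrix
    seed_groups: dict
    sims: dict
    optf: float
    report: pd.DataFrame
    log: list


def load_inputs(config: RunConfig):
    dag = parse_obo(config.obo, config.aspect)
    corpus = parse_gaf(config.gaf, dag)
    ic = compute_ic(dag, corpus)
    grouping = ECGrouping.from_tsv(config.grouping, min_size=config.group_filter())
    return dag, corpus, ic, grouping


def compute_matrices(
    corpus, dag, ic, genes, measure_names=ms.S_ALL, grouping=None, fake_seed=0
):
    """Raw similarity matrices, optionally appending the fake measure
    (which needs the grouping and a seed)."""
    names = [m for m in measure_names if m != "fake"]
    matrices = ms.similarity_matrices(corpus, dag, ic, genes, names)
    if "fake" in measure_names:
        if grouping is None:
            raise ValueError("fake measure requires a grouping")
        resnik = next(m for m in matrices if m.measure == "resnik")
        matrices.append(ms.fake_measure(resnik, grouping, fake_seed))
    return matrices


# ---------------------------------------------------------------------------
# similarity functions over a rank matrix


def integrated_sims(rank_matrix: RankMatrix, seed_groups: dict, params: ParameterSet) -> dict:
    """pair -> trained addition-model similarity."""
    params.validate()
    return {
        pair: integrate(rank_matrix.ranksim_row(pair), seed_groups[pair], params)
        for pair in rank_matrix.pairs
    }


def mean_baseline_sims(rank_matrix: RankMatrix) -> dict:
    """pair -> plain average of all candidate RankSims (the "average"
    integration baseline)."""
    means = rank_matrix.ranksim.mean(axis=1)
    return {pair: float(means.loc[pair]) for pair in rank_matrix.pairs}


# ---------------------------------------------------------------------------
# training


def train_model(
    matrices,
    grouping: ECGrouping,
    *,
    seed_min_size: int = 3,
    d_prime: float = 0.10,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Full training path on precomputed raw matrices.

    Rank-normalises within the training gene set, selects per-pair seed
    groups, runs the tabu search and evaluates the fitted model.
    """
    config = config or TrainConfig()
    rank_matrix = build_rank_matrix(matrices)
    seed_groups = seed_groups_for(rank_matrix, c=seed_min_size, d_prime=d_prime)
    move_log: list = []
    params = tabu_train(rank_matrix, seed_groups, grouping, config, log=move_log)
    sims = integrated_sims(rank_matrix, seed_groups, params)
    report = logfc_table(grouping, sims, c_smooth=config.c_smooth, divisor=config.divisor)
    score = optf(grouping, sims, c_smooth=config.c_smooth, divisor=config.divisor)
    return TrainResult(params, rank_matrix, seed_groups, sims, score, report, move_log)


def per_measure_optf(
    rank_matrix: RankMatrix, grouping: ECGrouping, c_smooth: float = 0.01,
    divisor: str = "ej",
) -> dict:
    """OptF of each candidate measure's own RankSim column."""
    pair_index = {p: i for i, p in enumerate(rank_matrix.pairs)}
    evaluator = LogFCEvaluator(grouping, pair_index, c_smooth, divisor)
    out = {}
    for m in rank_matrix.measures:
        sims = rank_matrix.ranksim[m].to_numpy()
        out[m] = evaluator.optf(sims)
    return out


# ---------------------------------------------------------------------------
# scoring


def score_table(
    matrices,
    params: ParameterSet,
    *,
    seed_min_size: int = 3,
    d_prime: float = 0.10,
) -> pd.DataFrame:
    """Score every pair of an input gene set with a trained model.

    Ranks are computed *within the input set*; the output similarity is
    therefore relative to that set.
    """
    rank_matrix = build_rank_matrix(matrices)
    seed_groups = seed_groups_for(rank_matrix, c=seed_min_size, d_prime=d_prime)
    sims = integrated_sims(rank_matrix, seed_groups, params)
    rows = [
        {
            "gene1": pair[0],
            "gene2": pair[1],
            "sim": sims[pair],
            "group_type": seed_groups[pair].group_type,
        }
        for pair in rank_matrix.pairs
    ]
    return pd.DataFrame(rows)


def export_network(scores: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Functional-association edge list: pairs with sim >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    edges = scores.loc[scores["sim"] >= threshold, ["gene1", "gene2", "sim"]]
    edges = edges.reset_index(drop=True)
    nodes = pd.unique(edges[["gene1", "gene2"]].to_numpy().ravel())
    log.info("network export: %d nodes, %d edges", len(nodes), len(edges))
    return edges


# ---------------------------------------------------------------------------
# cross-validation harness


def split_grouping(grouping: ECGrouping, test_fraction: float, seed: int):
    """Random group-level split (e.g. 1/5 of groups to the test set)."""
    ids = sorted(grouping.groups)
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(ids))
    n_test = max(1, int(round(test_fraction * len(ids))))
    test_ids = set(perm[:n_test])
    train = ECGrouping({g: grouping.groups[g] for g in ids if g not in test_ids})
    test = ECGrouping({g: grouping.groups[g] for g in test_ids})
    return train, test


def cross_validate(
    matrices,
    grouping: ECGrouping,
    *,
    test_fraction: float = 0.2,
    seed: int = 0,
    seed_min_size: int = 3,
    d_prime: float = 0.10,
    config: TrainConfig | None = None,
) -> dict:
    """Train on 4/5 of the groups, evaluate on the held-out 1/5.

    Test-set similarities are rank-normalised within the test gene set,
    then integrated with the *trained* parameters; the mean-of-measures
    baseline is evaluated on the same ranks.
    """
    config = config or TrainConfig()
    train_grp, test_grp = split_grouping(grouping, test_fraction, seed)
    train_genes = train_grp.gene_universe()
    test_genes = test_grp.gene_universe()
    train_mats = [m.subset(train_genes) for m in matrices]
    result = train_model(
        train_mats,
        train_grp,
        seed_min_size=seed_min_size,
        d_prime=d_prime,
        config=config,
    )
    test_rank = build_rank_matrix([m.subset(test_genes) for m in matrices])
    test_seeds = seed_groups_for(test_rank, c=seed_min_size, d_prime=d_prime)
    model_sims = integrated_sims(test_rank, test_seeds, result.params)
    baseline_sims = mean_baseline_sims(test_rank)
    return {
        "train_optf": result.optf,
        "test_optf_model": optf(test_grp, model_sims, config.c_smooth, config.divisor),
        "test_optf_baseline": optf(
            test_grp, baseline_sims, config.c_smooth, config.divisor
        ),
        "params": result.params,
        "test_groups": sorted(test_grp.groups),
    }


# ---------------------------------------------------------------------------
# robustness


def robustness_report(
    matrices,
    grouping: ECGrouping,
    removal_order,
    *,
    leave_one_out: bool = True,
    seed_min_size: int = 3,
    d_prime: float = 0.10,
    config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Retrain and re-evaluate under measure removal.

    One row per cumulative removal step along *removal_order* (step 0 =
    all measures) and, optionally, one per single-measure leave-one-out.
    Stops cumulative removal once fewer than two measures (or fewer than
    *seed_min_size*) would remain, emitting the partial report.
    """
    config = config or TrainConfig()
    by_name = {m.measure: m for m in matrices}
    unknown = [m for m in removal_order if m not in by_name]
    if unknown:
        raise KeyError(f"removal of unknown measures: {unknown}")

    def evaluate(active_names, mode, removed_label):
        active = [by_name[m] for m in active_names]
        result = train_model(
            active,
            grouping,
            seed_min_size=min(seed_min_size, len(active)),
            d_prime=d_prime,
            config=config,
        )
        summary = logfc_summary(result.report)
        return {
            "mode": mode,
            "removed": removed_label,
            "n_measures": len(active),
            "optf": result.optf,
            "logfc_median": summary["median"],
            "logfc_q25": summary["q25"],
            "logfc_q75": summary["q75"],
        }

    all_names = [m.measure for m in matrices]
    rows = [evaluate(all_names, "cumulative", "")]
    for step in range(1, len(removal_order) + 1):
        removed = set(removal_order[:step])
        remaining = [m for m in all_names if m not in removed]
        if len(remaining) < max(2, seed_min_size):
            log.warning("stopping cumulative removal: %d measures left", len(remaining))
            break
        rows.append(evaluate(remaining, "cumulative", ";".join(removal_order[:step])))
    if leave_one_out:
        for m in all_names:
            remaining = [x for x in all_names if x != m]
            if len(remaining) < 2:
                continue
            rows.append(evaluate(remaining, "leave_one_out", m))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-level wrappers


def run_train(config: RunConfig, out_params=None, out_report=None, out_log=None):
    """Train from files: executes ranking, seed selection and tabu search
    on all genes of the (filtered) training grouping."""
    dag, corpus, ic, grouping = load_inputs(config)
    genes = sorted(grouping.gene_universe() & corpus.gene_universe)
    dropped = grouping.gene_universe() - corpus.gene_universe
    if dropped:
        log.warning("%d grouping genes lack annotations: %s", len(dropped), sorted(dropped))
        grouping = ECGrouping(
            {g: s & corpus.gene_universe for g, s in grouping.groups.items()},
            min_size=config.group_filter(),
        )
    names = list(config.measures) + (["fake"] if config.include_fake else [])
    matrices = compute_matrices(
        corpus, dag, ic, genes, names, grouping=grouping, fake_seed=config.train.seed
    )
    result = train_model(
        matrices,
        grouping,
        seed_min_size=config.seed_min_size,
        d_prime=config.d_prime,
        config=config.train,
    )
    if out_params:
        result.params.save(out_params)
    if out_report:
        result.report.to_csv(out_report, sep="\t", index=False)
    if out_log:
        pd.DataFrame(result.log).to_csv(out_log, sep="\t", index=False)
    return result


def run_score(config: RunConfig, gene_set, *, strict: bool = False) -> pd.DataFrame:
    """Score an input gene set from files with a trained parameter file."""
    if config.params_path is None:
        raise ValueError("config.params_path required for scoring")
    dag = parse_obo(config.obo, config.aspect)
    corpus = parse_gaf(config.gaf, dag)
    ic = compute_ic(dag, corpus)
    params = ParameterSet.load(config.params_path)
    genes = sorted(set(gene_set))
    missing = [g for g in genes if g not in corpus.gene_universe]
    if missing:
        if strict:
            raise KeyError(f"genes absent from corpus: {missing}")
        log.warning("skipping %d unannotated genes: %s", len(missing), missing)
        genes = [g for g in genes if g not in missing]
    names = [m for m in params.measures if m != "fake"]
    matrices = ms.similarity_matrices(corpus, dag, ic, genes, names)
    if "fake" in params.measures:
        # a trained model may carry a fake-measure weight; scoring inputs
        # have no grouping, so the fake column is its Resnik half only
        raise ValueError("cannot score with a parameter set trained on 'fake'")
    return score_table(
        matrices, params, seed_min_size=config.seed_min_size, d_prime=config.d_prime
    )


def run_robustness(config: RunConfig, removal_order) -> pd.DataFrame:
    dag, corpus, ic, grouping = load_inputs(config)
    genes = sorted(grouping.gene_universe() & corpus.gene_universe)
    names = list(config.measures) + (["fake"] if config.include_fake else [])
    matrices = compute_matrices(
        corpus, dag, ic, genes, names, grouping=grouping, fake_seed=config.train.seed
    )
    return robustness_report(
        matrices,
        grouping,
        removal_order,
        seed_min_size=config.seed_min_size,
        d_prime=config.d_prime,
        config=config.train,
    )
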