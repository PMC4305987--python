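"""Enzyme-class / pathway separation objective (LogFC, OptF).

Genes sharing a full EC number (molecular function) or a pathway
(biological process) are treated as functionally similar ground truth.
A good similarity function should then place small distances inside a
group and large distances across disjoint groups.  For gene g in group
e_i against a disjoint group e_j, with I = G(e_i) \\ {g} and J = G(e_j):

    diff_g(e_i, e_j) = ln[ |I| * sum_{g' in J} (1 - sim(g, g') + c) ]
                     - ln[ |J| * sum_{g* in I} (1 - sim(g, g*) + c) ]

where c is a small Laplacian smoothing constant (``c_smooth``; the
seed-selection group-size threshold is a different constant, named
``seed_min_size`` elsewhere).  LogFC of a group averages diff over all
disjoint partner groups and member genes; OptF averages LogFC over all
groups for which it is defined, and is the quantity the tabu trainer
maximises.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .measures import pair_key

log = logging.getLogger(__name__)

DIVISORS = ("ej", "ei")


@dataclass(frozen=True)
class ECGrouping:
    """Gene groups (EC numbers or pathways) used as functional ground truth.

    Groups below *min_size* are dropped at construction (defaults in the
    pipeline: 3 genes for EC groups, 2 for pathways).
    """

    groups: dict
    min_size: int = 1

    def __post_init__(self):
        filtered = {
            gid: frozenset(genes)
            for gid, genes in self.groups.items()
            if len(genes) >= self.min_size
        }
        object.__setattr__(self, "groups", filtered)

    def gene_universe(self) -> frozenset:
        out: set = set()
        for genes in self.groups.values():
            out |= genes
        return frozenset(out)

    def disjoint_partners(self, ei: str) -> list:
        """Group ids sharing no gene with *ei* (the |EC| set of LogFC)."""
        gi = self.groups[ei]
        return sorted(
            ej for ej, gj in self.groups.items() if ej != ei and not (gi & gj)
        )

    @classmethod
    def from_tsv(cls, path, min_size: int = 1) -> "ECGrouping":
        """Read a 2-column group_id<TAB>gene membership file."""
        groups: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                gid, gene = line.split("\t")
                groups.setdefault(gid, set()).add(gene)
        return cls(groups, min_size=min_size)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for gid in sorted(self.groups):
                for gene in sorted(self.groups[gid]):
                    fh.write(f"{gid}\t{gene}\n")


def _as_callable(sim):
    if callable(sim):
        return sim
    return lambda g1, g2: sim[pair_key(g1, g2)]


def diff_gene(
    g: str,
    ei: str,
    ej: str,
    sim,
    grouping: ECGrouping,
    c_smooth: float = 0.01,
) -> float:
    """Log ratio of gene *g*'s inter-group vs intra-group distance."""
    if c_smooth <= 0:
        raise ValueError("c_smooth must be positive")
    gi, gj = grouping.groups[ei], grouping.groups[ej]
    if gi & gj:
        raise ValueError(f"groups {ei!r} and {ej!r} overlap")
    if g not in gi:
        raise ValueError(f"gene {g!r} not in group {ei!r}")
    intra = gi - {g}
    if not intra:
        raise ValueError(f"group {ei!r} is a singleton once {g!r} is removed")
    s = _as_callable(sim)
    inter_sum = sum(1.0 - s(g, gp) + c_smooth for gp in gj)
    intra_sum = sum(1.0 - s(g, gs) + c_smooth for gs in intra)
    return math.log(len(intra) * inter_sum) - math.log(len(gj) * intra_sum)


def logfc(
    ei: str,
    grouping: ECGrouping,
    sim,
    c_smooth: float = 0.01,
    divisor: str = "ej",
) -> float | None:
    """LogFC of group *ei*: mean separation against all disjoint groups.

    Returns ``None`` (undefined) when no disjoint partner group exists;
    such groups are excluded from OptF.  *divisor* selects the inner
    normaliser: the partner group size (``ej``, the printed form) or the
    own group size (``ei``).
    """
    if divisor not in DIVISORS:
        raise ValueError(f"divisor must be one of {DIVISORS}")
    partners = grouping.disjoint_partners(ei)
    if not partners:
        log.info("group %s has no disjoint partner; LogFC undefined", ei)
        return None
    total = 0.0
    for ej in partners:
        div = len(grouping.groups[ej if divisor == "ej" else ei])
        for g in sorted(grouping.groups[ei]):
            total += diff_gene(g, ei, ej, sim, grouping, c_smooth) / div
    return total / len(partners)


def optf(
    grouping: ECGrouping,
    sim,
    c_smooth: float = 0.01,
    divisor: str = "ej",
) -> float:
    """Mean LogFC over all groups for which it is defined."""
    values = []
    for ei in sorted(grouping.groups):
        if len(grouping.groups[ei]) < 2:
            log.info("group %s has fewer than 2 genes; skipped", ei)
            continue
        val = logfc(ei, grouping, sim, c_smooth, divisor)
        if val is not None:
            values.append(val)
    if not values:
        raise ValueError("LogFC undefined for every group")
    return float(np.mean(values))


def logfc_table(
    grouping: ECGrouping,
    sim,
    c_smooth: float = 0.01,
    divisor: str = "ej",
) -> pd.DataFrame:
    """Per-group evaluation report: one LogFC row per retained group."""
    rows = []
    for ei in sorted(grouping.groups):
        size = len(grouping.groups[ei])
        val = logfc(ei, grouping, sim, c_smooth, divisor) if size >= 2 else None
        rows.append({"group_id": ei, "size": size, "logfc": val})
    return pd.DataFrame(rows)


def logfc_summary(table: pd.DataFrame) -> dict:
    """Median and quartiles of the defined LogFC values (boxplot stats)."""
    vals = table["logfc"].dropna().astype(float)
    return {
        "median": float(vals.median()),
        "q25": float(vals.quantile(0.25)),
        "q75": float(vals.quantile(0.75)),
        "n_groups": int(vals.size),
    }


class LogFCEvaluator:
    """Vectorised OptF over a fixed grouping and pair indexing.

    Precomputes, for every (group, disjoint partner, member gene)
    triple, the pair indices feeding the inter and intra sums, so that
    evaluating OptF for a new similarity vector costs two sparse
    mat-vecs.  Used in the tabu search inner loop; agrees with the
    reference :func:`optf` (asserted in the test suite).
    """

    def __init__(
        self,
        grouping: ECGrouping,
        pair_index: dict,
        c_smooth: float = 0.01,
        divisor: str = "ej",
    ):
        if divisor not in DIVISORS:
            raise ValueError(f"divisor must be one of {DIVISORS}")
        self.c_smooth = c_smooth
        self.n_pairs = len(pair_index)
        usable = [
            ei
            for ei in sorted(grouping.groups)
            if len(grouping.groups[ei]) >= 2 and grouping.disjoint_partners(ei)
        ]
        if not usable:
            raise ValueError("no group with >=2 genes and a disjoint partner")
        self.group_ids = usable
        inter_idx: list = []
        intra_idx: list = []
        inter_ptr = [0]
        intra_ptr = [0]
        const = []
        weight = []
        gidx = []
        for a, ei in enumerate(usable):
            partners = grouping.disjoint_partners(ei)
            for ej in partners:
                gj = sorted(grouping.groups[ej])
                div = len(
                    grouping.groups[ej if divisor == "ej" else ei]
                )
                for g in sorted(grouping.groups[ei]):
                    intra = sorted(grouping.groups[ei] - {g})
                    inter_idx.extend(pair_index[pair_key(g, x)] for x in gj)
                    intra_idx.extend(pair_index[pair_key(g, x)] for x in intra)
                    inter_ptr.append(len(inter_idx))
                    intra_ptr.append(len(intra_idx))
                    const.append(math.log(len(intra)) - math.log(len(gj)))
                    weight.append(1.0 / (len(partners) * div))
                    gidx.append(a)
        n_triples = len(const)
        self._inter = sparse.csr_matrix(
            (np.ones(len(inter_idx)), inter_idx, inter_ptr),
            shape=(n_triples, self.n_pairs),
        )
        self._intra = sparse.csr_matrix(
            (np.ones(len(intra_idx)), intra_idx, intra_ptr),
            shape=(n_triples, self.n_pairs),
        )
        self._const = np.array(const)
        self._weight = np.array(weight)
        self._gidx = np.array(gidx)

    def logfc_per_group(self, sims: np.ndarray) -> dict:
        d = 1.0 - np.asarray(sims, dtype=float) + self.c_smooth
        inter = self._inter @ d
        intra = self._intra @ d
        contrib = self._weight * (np.log(inter) - np.log(intra) + self._const)
        per_group = np.bincount(
            self._gidx, weights=contrib, minlength=len(self.group_ids)
        )
        return dict(zip(self.group_ids, per_group.tolist()))

    def optf(self, sims: np.ndarray) -> float:
        return float(np.mean(list(self.logfc_per_group(sims).values())))
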