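"""Rank normalization of raw similarity matrices.

Different measures score on incomparable scales; within a gene set the
within-set rank of each pair is comparable across measures.  Each pair's
raw score is replaced by

    RankSim(g1, g2, m) = 2 * rank / |GS|**2

where pairs are ranked ascending (least similar pair = rank 1, ties get
the fractional average of the tied positions) and |GS| is the number of
genes in the set.  With P = |GS|(|GS|-1)/2 pairs the maximum attainable
value is (|GS|-1)/|GS|, so RankSim lies strictly inside (0, 1).

Scores are therefore *relative to the query set*: the same gene pair
gets a different RankSim inside a different gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class RankMatrix:
    """Gene-pair × measure table of ranks and RankSim values."""

    pairs: list
    measures: list
    rank: pd.DataFrame
    ranksim: pd.DataFrame
    gs_size: int
    genes: frozenset
    _rows: dict = field(default_factory=dict, repr=False, compare=False)

    def ranksim_row(self, pair) -> dict:
        """RankSim values of one pair as a measure -> value dict."""
        row = self._rows.get(pair)
        if row is None:
            row = self._rows[pair] = self.ranksim.loc[[pair]].iloc[0].to_dict()
        return row

    def sim_column(self, measure: str) -> dict:
        """One measure's RankSim values as a pair -> value dict (a valid
        [0,1] similarity function for the LogFC objective)."""
        return self.ranksim[measure].to_dict()


def build_rank_matrix(matrices) -> RankMatrix:
    """Rank every measure's raw scores ascending and apply RankSim.

    All matrices must cover the same gene set.  Ties receive fractional
    (average) ranks, which preserves the rank sum P(P+1)/2 per measure.
    """
    if not matrices:
        raise ValueError("need at least one similarity matrix")
    gene_set = matrices[0].gene_set
    for m in matrices[1:]:
        if m.gene_set != gene_set:
            diff = gene_set.symmetric_difference(m.gene_set)
            raise ValueError(
                f"matrix {m.measure!r} covers a different gene set; "
                f"difference: {sorted(diff)}"
            )
    pairs = matrices[0].pairs()
    measures = [m.measure for m in matrices]
    raw = np.column_stack(
        [np.array([m.scores[p] for p in pairs], dtype=float) for m in matrices]
    )
    ranks = np.column_stack(
        [rankdata(raw[:, j], method="average") for j in range(raw.shape[1])]
    )
    gs = len(gene_set)
    index = pd.MultiIndex.from_tuples(pairs, names=["gene1", "gene2"])
    rank_df = pd.DataFrame(ranks, index=index, columns=measures)
    ranksim_df = 2.0 * rank_df / gs**2
    return RankMatrix(
        pairs=pairs,
        measures=measures,
        rank=rank_df,
        ranksim=ranksim_df,
        gs_size=gs,
        genes=gene_set,
    )


def write_rank_tsv(rank_matrix: RankMatrix, path) -> None:
    rank_matrix.ranksim.to_csv(path, sep="\t")


def read_rank_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=[0, 1])
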