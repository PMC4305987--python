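"""Per-gene-pair seed-measure selection.

For one gene pair the candidate measures' RankSim values sit on a 1-D
axis.  The seed measure group is the largest contiguous run (on the
sorted axis) whose diameter does not exceed ``d_prime`` and that has at
least ``c`` members; measures outside the run are "isolated".  On a
line, iteratively pruning isolated measures from a single-linkage
dendrogram selects the same contiguous core as this maximal-window
search, which is deterministic and order-free.

The group is labelled ``high`` when more isolated measures lie below it
than above (the core sits at the high end of the axis), ``low`` in the
mirror case, and ``mix`` on ties — including the fallback case where no
window of size >= c fits within d_prime and all measures are kept.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass


@dataclass(frozen=True)
class SeedGroup:
    """Selected seed measures for one gene pair."""

    members: tuple
    group_type: str
    fallback: bool
    removed_low: int
    removed_high: int
    pair: tuple | None = None


def _label(fallback: bool, removed_low: int, removed_high: int) -> str:
    if fallback or removed_low == removed_high:
        return "mix"
    return "high" if removed_low > removed_high else "low"


def label_group_type(group: SeedGroup) -> str:
    """Type of a seed group from its isolated-measure counts."""
    return _label(group.fallback, group.removed_low, group.removed_high)


def select_seed_group(
    values: dict, c: int = 3, d_prime: float = 0.10, pair=None
) -> SeedGroup:
    """Select the seed measure group from measure -> RankSim values.

    Among all contiguous runs of the value-sorted measures with diameter
    <= *d_prime*, the run with the most members wins; ties prefer the
    smaller diameter, then the run containing the median value, then the
    lower run.  If the best run has fewer than *c* members, all measures
    are kept and the group is flagged as a fallback.
    """
    if not values:
        raise ValueError("no measure values supplied")
    if c < 1:
        raise ValueError("c must be >= 1")
    if not (0.0 < d_prime < 1.0):
        raise ValueError("d_prime must lie in (0, 1)")

    items = sorted(values.items(), key=lambda kv: (kv[1], kv[0]))
    names = [k for k, _ in items]
    vals = [v for _, v in items]
    n = len(items)
    med = statistics.median(vals)

    # maximal windows: for each start, extend as far as the diameter allows
    windows = []
    j = 0
    for i in range(n):
        if j < i:
            j = i
        while j + 1 < n and vals[j + 1] - vals[i] <= d_prime:
            j += 1
        windows.append((i, j))

    def score(win):
        i, j = win
        size = j - i + 1
        diameter = vals[j] - vals[i]
        has_median = vals[i] <= med <= vals[j]
        return (-size, diameter, not has_median, i)

    best = min(windows, key=score)
    i, j = best
    if j - i + 1 < c:
        return SeedGroup(
            members=tuple(names),
            group_type="mix",
            fallback=True,
            removed_low=0,
            removed_high=0,
            pair=pair,
        )
    removed_low = i
    removed_high = n - 1 - j
    return SeedGroup(
        members=tuple(names[i : j + 1]),
        group_type=_label(False, removed_low, removed_high),
        fallback=False,
        removed_low=removed_low,
        removed_high=removed_high,
        pair=pair,
    )


def seed_groups_for(rank_matrix, c: int = 3, d_prime: float = 0.10) -> dict:
    """Seed group for every pair of a rank matrix."""
    return {
        pair: select_seed_group(rank_matrix.ranksim_row(pair), c, d_prime, pair=pair)
        for pair in rank_matrix.pairs
    }


def write_seed_tsv(seed_groups: dict, path) -> None:
    """Audit dump: one row per pair with type and member list."""
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\ttype\tfallback\tmembers\n")
        for pair in sorted(seed_groups):
            g = seed_groups[pair]
            fh.write(
                f"{pair[0]}\t{pair[1]}\t{g.group_type}\t"
                f"{int(g.fallback)}\t{';'.join(g.members)}\n"
            )
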