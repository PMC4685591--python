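"""Crown-group emergence times and their per-condition summaries.

The crown group of a tree is the clade founded by the most recent common
ancestor of all extant tips.  Under the bifurcation convention the crown
*emerges* at the split of that MRCA lineage into the two oldest surviving
daughter clades, so the crown time is the MRCA lineage's death (speciation)
time; when extant tips descend from both origin lineages the MRCA is the
initial split itself and the crown time is 0.  The headline statistic is
the crown fraction: crown time divided by the total-group duration T, a
dimensionless number in [0, 1] (0 = crown at the total-group origin,
1 = at the present).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import UndefinedCrownError
from .treecore import ORIGIN, PhyloTree


@dataclass(frozen=True)
class CrownRecord:
    """Crown emergence for one surviving tree."""

    tree_id: int
    n_extant: int
    crown_time: float
    fraction: float


@dataclass(frozen=True)
class ConditionSummary:
    """Mean and spread of the crown fraction for one (S, E) condition.

    ``sd_fraction`` is the sample (n-1) standard deviation; ``lo_2sd`` /
    ``hi_2sd`` give the conventional +/-2 s.d. plotting interval.
    """

    S: float
    E: float
    T: float
    n: int
    mean_fraction: float
    sd_fraction: float

    @property
    def D(self) -> float:
        # Rates are grid values with a few decimals; rounding strips float
        # residue (0.7 - 0.5 != 0.2 exactly) so cells aggregate by D cleanly.
        return round(self.S - self.E, 12)

    @property
    def lo_2sd(self) -> float:
        return self.mean_fraction - 2 * self.sd_fraction

    @property
    def hi_2sd(self) -> float:
        return self.mean_fraction + 2 * self.sd_fraction

    @property
    def se_mean(self) -> float:
        """Standard error of the mean fraction."""
        return self.sd_fraction / np.sqrt(self.n)


def crown_node(tree: PhyloTree) -> Union[int, str]:
    """Most recent node ancestral to every extant tip.

    Returns :data:`ORIGIN` when extant tips descend from both origin
    lineages (the MRCA is the initial split at time 0), otherwise the id of
    the MRCA lineage.  Runs in O(n) by counting extant descendants in one
    post-order sweep and descending while a single child holds them all —
    independent of, and checked against, the brute-force path-intersection
    oracle in :mod:`crownsim.treecore`.
    """
    n_total = tree.n_extant
    if n_total < 2:
        raise UndefinedCrownError(
            f"crown group undefined: {n_total} extant tip(s), need >= 2"
        )
    counts: dict[int, int] = {}
    for lid in reversed(tree.toposort()):
        lin = tree.lineages[lid]
        counts[lid] = (1 if lin.extant else 0) + sum(
            counts[c] for c in lin.child_ids
        )
    r1, r2 = tree.origin_ids
    if counts[r1] > 0 and counts[r2] > 0:
        return ORIGIN
    cur = r1 if counts[r1] > 0 else r2
    while True:
        holders = [c for c in tree.lineages[cur].child_ids if counts[c] > 0]
        if len(holders) == 1 and counts[holders[0]] == n_total:
            cur = holders[0]
        else:
            return cur


def crown_time(tree: PhyloTree) -> float:
    """Time of crown emergence: the MRCA lineage's splitting time, or 0 at
    the origin."""
    node = crown_node(tree)
    if node == ORIGIN:
        return 0.0
    return tree.lineages[node].death_time


def crown_fraction(tree: PhyloTree, tree_id: int = 0) -> CrownRecord:
    """Crown emergence as a fraction of the total-group duration.

    Node times come straight from the tree (exact simulator arithmetic when
    the tree was simulated; no re-derivation from serialized output).
    """
    t = crown_time(tree)
    return CrownRecord(
        tree_id=tree_id,
        n_extant=tree.n_extant,
        crown_time=t,
        fraction=t / tree.present_time,
    )


def summarize_condition(
    records: Sequence[CrownRecord], S: float, E: float, T: float
) -> ConditionSummary:
    """Mean +/- sample s.d. of the crown fraction over one condition's trees."""
    if len(records) < 2:
        raise ValueError(f"need >= 2 records to summarize, got {len(records)}")
    fr = np.array([r.fraction for r in records], dtype=float)
    return ConditionSummary(
        S=S,
        E=E,
        T=T,
        n=len(records),
        mean_fraction=float(fr.mean()),
        sd_fraction=float(fr.std(ddof=1)),
    )


#: Canonical column order of the summary CSV emitted by the sweeps.
SUMMARY_COLUMNS = [
    "S", "E", "D", "T", "n",
    "mean_fraction", "sd_fraction", "lo_2sd", "hi_2sd",
]


def summaries_to_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Flatten summaries into the canonical CSV schema (one row per condition)."""
    rows = [
        {
            "S": s.S, "E": s.E, "D": s.D, "T": s.T, "n": s.n,
            "mean_fraction": s.mean_fraction, "sd_fraction": s.sd_fraction,
            "lo_2sd": s.lo_2sd, "hi_2sd": s.hi_2sd,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
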