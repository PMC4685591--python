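"""Parameter sweeps over birth-death conditions and schematic tree figures.

Two study designs are provided:

* ``equal_rates`` — speciation = extinction (critical diversification,
  D = 0) at rates 0.1, 0.3, 0.5, 0.7 and 0.9 over a long window (T = 114
  time units).  The headline result is that the mean crown fraction sits
  near 0.5 regardless of the absolute rate.
* ``diversification`` — extinction rates 0.1 ... 0.9 crossed with
  diversification rates D in {0, 0.2, 0.4, 0.6} (speciation = E + D) over a
  short window (T = 15; strongly supercritical trees grow exponentially, so
  long windows are not tractable).  Cells with speciation above 0.9 are
  skipped, as is the lone D = 0.8 combination (S = 0.9, E = 0.1), whose
  trees blow up against the lineage cap.

Each condition draws survival-conditioned trees (batches of 100, first 50
survivors) and summarizes the crown fraction.  CSV is the canonical output;
plotting is a thin optional layer so nothing downstream depends on
rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bd_sim import BDParams, SurvivalPolicy, simulate_surviving
from .crown_stats import (
    ConditionSummary,
    CrownRecord,
    crown_fraction,
    crown_node,
    crown_time,
    summaries_to_frame,
    summarize_condition,
)
from .errors import CrownsimError
from .treecore import ORIGIN, PhyloTree

logger = logging.getLogger("crownsim")

EQUAL_RATES_GRID: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
DIVERSIFICATION_E_GRID: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
DIVERSIFICATION_D_GRID: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6)
EQUAL_RATES_DURATION = 114.0
DIVERSIFICATION_DURATION = 15.0
#: No conditions with speciation above this are generated.
MAX_SPECIATION = 0.9

_MODE_TAG = {"equal_rates": 0, "diversification": 1}


@dataclass(frozen=True)
class SweepSpec:
    """Grid, batch policy and seed for one whole sweep."""

    mode: str = "equal_rates"
    seed: int = 0
    duration: Optional[float] = None  # default 114 (equal_rates) / 15 (diversification)
    rates: tuple[float, ...] = EQUAL_RATES_GRID
    extinction_rates: tuple[float, ...] = DIVERSIFICATION_E_GRID
    diversification_rates: tuple[float, ...] = DIVERSIFICATION_D_GRID
    policy: SurvivalPolicy = field(default_factory=SurvivalPolicy)
    max_speciation: float = MAX_SPECIATION
    max_lineages: int = 1_000_000
    keep_trees: bool = False  # retain surviving trees on each ConditionResult

    def __post_init__(self) -> None:
        if self.mode not in _MODE_TAG:
            raise ValueError(
                f"unknown mode {self.mode!r}; expected one of {sorted(_MODE_TAG)}"
            )

    @property
    def T(self) -> float:
        if self.duration is not None:
            return self.duration
        return (
            EQUAL_RATES_DURATION
            if self.mode == "equal_rates"
            else DIVERSIFICATION_DURATION
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SweepSpec":
        d = dict(d)
        if "policy" in d and isinstance(d["policy"], dict):
            d["policy"] = SurvivalPolicy(**d["policy"])
        for key in ("rates", "extinction_rates", "diversification_rates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ConditionResult:
    """One grid cell: its summary plus the per-tree records behind it."""

    summary: ConditionSummary
    records: list[CrownRecord]
    acceptance_rate: float
    n_single_survivor: int
    trees: Optional[list[PhyloTree]] = None  # only when SweepSpec.keep_trees


@dataclass
class SweepResult:
    spec: SweepSpec
    conditions: list[ConditionResult]
    skipped: list[dict]  # grid cells excluded by rule, with reasons
    failed: list[dict]  # grid cells aborted by simulator errors

    @property
    def table(self) -> pd.DataFrame:
        df = summaries_to_frame([c.summary for c in self.conditions])
        df["acceptance_rate"] = [c.acceptance_rate for c in self.conditions]
        return df

    def all_records(self) -> list[CrownRecord]:
        return [r for c in self.conditions for r in c.records]

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _condition_seed(spec: SweepSpec, index: int) -> int:
    """Stable per-condition seed; keyed on (sweep seed, mode, cell index)."""
    ss = np.random.SeedSequence([spec.seed, _MODE_TAG[spec.mode], index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _run_condition(
    spec: SweepSpec, index: int, S: float, E: float
) -> ConditionResult:
    params = BDParams(
        speciation_rate=S,
        extinction_rate=E,
        duration=spec.T,
        seed=_condition_seed(spec, index),
        max_lineages=spec.max_lineages,
    )
    sample = simulate_surviving(params, spec.policy)
    records = [crown_fraction(t, tree_id=i) for i, t in enumerate(sample.trees)]
    summary = summarize_condition(records, S=S, E=E, T=spec.T)
    logger.info(
        "condition S=%.2f E=%.2f T=%g: n=%d mean=%.4f sd=%.4f acceptance=%.3f",
        S, E, spec.T, summary.n, summary.mean_fraction, summary.sd_fraction,
        sample.acceptance_rate,
    )
    return ConditionResult(
        summary=summary,
        records=records,
        acceptance_rate=sample.acceptance_rate,
        n_single_survivor=sample.n_single_survivor,
        trees=sample.trees if spec.keep_trees else None,
    )


def run_equal_rates(spec: SweepSpec) -> SweepResult:
    """The critical (S = E) sweep: one row per rate, T = 114 by default.

    A condition aborted by a simulator error (survivor shortfall, lineage
    cap) is logged and dropped; the remaining conditions are unaffected.
    """
    if spec.mode != "equal_rates":
        raise ValueError(f"spec mode is {spec.mode!r}, expected 'equal_rates'")
    logger.info(
        "equal-rates sweep: crownsim %s, seed=%d, rates=%s, T=%g, policy=%s",
        __version__, spec.seed, spec.rates, spec.T, spec.policy,
    )
    conditions, failed = [], []
    for k, r in enumerate(spec.rates):
        try:
            conditions.append(_run_condition(spec, k, S=r, E=r))
        except CrownsimError as exc:
            logger.warning("condition S=E=%.2f aborted: %s", r, exc)
            failed.append({"S": r, "E": r, "error": str(exc)})
    return SweepResult(spec=spec, conditions=conditions, skipped=[], failed=failed)


def run_diversification(spec: SweepSpec) -> SweepResult:
    """The supercritical sweep: E x D grid with S = E + D, T = 15 by default.

    Cells with S above ``max_speciation`` are excluded by rule and reported
    in ``skipped`` (never silently absent).
    """
    if spec.mode != "diversification":
        raise ValueError(f"spec mode is {spec.mode!r}, expected 'diversification'")
    logger.info(
        "diversification sweep: crownsim %s, seed=%d, E=%s, D=%s, T=%g, policy=%s",
        __version__, spec.seed, spec.extinction_rates,
        spec.diversification_rates, spec.T, spec.policy,
    )
    conditions, skipped, failed = [], [], []
    index = 0
    for E in spec.extinction_rates:
        for D in spec.diversification_rates:
            S = E + D
            index += 1
            if S > spec.max_speciation + 1e-12:
                logger.info("cell E=%.2f D=%.2f skipped: S=%.2f > %.2f",
                            E, D, S, spec.max_speciation)
                skipped.append(
                    {"S": S, "E": E, "D": D,
                     "reason": f"S={S:.2f} exceeds max_speciation={spec.max_speciation}"}
                )
                continue
            try:
                conditions.append(_run_condition(spec, index, S=S, E=E))
            except CrownsimError as exc:
                logger.warning("cell E=%.2f D=%.2f aborted: %s", E, D, exc)
                failed.append({"S": S, "E": E, "D": D, "error": str(exc)})
    return SweepResult(spec=spec, conditions=conditions, skipped=skipped, failed=failed)


def run_sweep(spec: SweepSpec) -> SweepResult:
    if spec.mode == "equal_rates":
        return run_equal_rates(spec)
    return run_diversification(spec)


# ---------------------------------------------------------------------------
# Schematic tree figure
# ---------------------------------------------------------------------------


def render_tree_figure(tree: PhyloTree, path: str | Path) -> None:
    """Draw the full tree with the crown clade shaded and the origin marked.

    Schematic: lineages are horizontal segments over their lifespans,
    splits are vertical connectors, extinct tips end with a cross.  The
    crown clade (the MRCA of extant tips plus all its descendants) is
    shaded grey from the crown time to the present.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cn = crown_node(tree)  # raises UndefinedCrownError for < 2 extant tips
    ct = crown_time(tree)
    T = tree.present_time

    # Tip y-positions in left-to-right preorder; internal nodes midway
    # between their children.
    y: dict[int, float] = {}
    order: list[int] = []
    stack = list(reversed(tree.origin_ids))
    while stack:
        lid = stack.pop()
        order.append(lid)
        stack.extend(reversed(tree.lineages[lid].child_ids))
    next_tip = 0.0
    for lid in order:
        if tree.lineages[lid].is_tip:
            y[lid] = next_tip
            next_tip += 1.0
    for lid in reversed(order):
        lin = tree.lineages[lid]
        if not lin.is_tip:
            y[lid] = float(np.mean([y[c] for c in lin.child_ids]))

    # Crown clade extent: every descendant of the crown node (or all, at origin).
    if cn == ORIGIN:
        crown_set = set(tree.lineages)
    else:
        crown_set = set()
        stack = [cn]
        while stack:
            lid = stack.pop()
            crown_set.add(lid)
            stack.extend(tree.lineages[lid].child_ids)

    fig, ax = plt.subplots(figsize=(8, max(3, 0.25 * next_tip)))
    ys = [y[l] for l in crown_set]
    ax.axvspan(ct, T, ymin=0, ymax=1, color="0.92", zorder=0)
    ax.fill_betweenx(
        [min(ys) - 0.4, max(ys) + 0.4], ct, T, color="0.8", zorder=0,
        label="crown group",
    )
    for lin in tree.lineages.values():
        ax.hlines(y[lin.id], lin.birth_time, lin.death_time,
                  color="k", lw=1.0, zorder=2)
        if lin.child_ids:
            cy = [y[c] for c in lin.child_ids]
            ax.vlines(lin.death_time, min(cy), max(cy), color="k", lw=1.0, zorder=2)
        elif not lin.extant:
            ax.plot(lin.death_time, y[lin.id], "x", color="0.4", ms=5, zorder=3)
    oy = float(np.mean([y[r] for r in tree.origin_ids]))
    ax.vlines(0.0, *sorted(y[r] for r in tree.origin_ids), color="k", lw=1.0)
    ax.plot(0.0, oy, "*", color="tab:red", ms=12, zorder=4, label="total-group origin")
    ax.axvline(ct, color="tab:blue", lw=0.8, ls="--", zorder=1)
    ax.set_xlabel("time")
    ax.set_yticks([])
    ax.set_xlim(-0.02 * T, 1.02 * T)
    ax.legend(loc="upper left", frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
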