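"""Continuous-time constant-rate birth-death simulation over a fixed window.

Each lineage, independently, waits an exponential time with total hazard
S + E; the event is a speciation with probability S/(S+E), otherwise an
extinction.  A speciating lineage terminates and is replaced by two
daughters.  Every tree starts from a split into two lineages at time 0 and
runs to a fixed present at time T; lineages alive at T are flagged extant.

Rates are hazard rates per lineage per time unit (so S and E need not sum
to anything in particular), and the diversification rate D = S - E is a
derived quantity.  :func:`simulate_surviving` implements conditioning on
survival by rejection: trees are generated in batches and those that leave
fewer than a minimum number of extant lineages are discarded, keeping the
first ``n_keep`` survivors in generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LineageCapError, SurvivorShortfallError
from .treecore import Lineage, PhyloTree


@dataclass(frozen=True)
class BDParams:
    """Rates and window for one birth-death condition.

    speciation_rate and extinction_rate are per-lineage hazard rates
    (events per lineage per time unit); duration is the span from the
    origin split to the present, in the same time units.  max_lineages
    caps total lineages ever created in one tree: supercritical runs with
    long durations blow up exponentially and are aborted in a controlled
    way rather than exhausting memory.
    """

    speciation_rate: float
    extinction_rate: float
    duration: float
    seed: int | None = None
    max_lineages: int = 1_000_000

    def __post_init__(self) -> None:
        if self.speciation_rate < 0 or self.extinction_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def diversification_rate(self) -> float:
        """D = S - E; derived, never stored."""
        return self.speciation_rate - self.extinction_rate


@dataclass(frozen=True)
class SurvivalPolicy:
    """Rejection policy for conditioning on survival to the present.

    Trees are generated in batches of ``batch_size``; a tree counts as
    surviving when at least ``min_extant_tips`` lineages are alive at the
    present (default 2: the crown group, the MRCA of living members, is
    undefined with fewer).  The first ``n_keep`` survivors in generation
    order are returned.  ``max_batches`` bounds the total effort in
    near-certain-extinction regimes.
    """

    batch_size: int = 100
    n_keep: int = 50
    min_extant_tips: int = 2
    max_batches: int = 400

    def __post_init__(self) -> None:
        if self.n_keep > self.batch_size * self.max_batches:
            raise ValueError("n_keep exceeds batch_size * max_batches")


@dataclass
class SurvivalSample:
    """Survivors plus bookkeeping from one rejection-sampling run."""

    trees: list[PhyloTree]
    n_generated: int
    n_surviving: int
    n_single_survivor: int  # trees alive at T but with exactly 1 extant tip
    params: BDParams
    policy: SurvivalPolicy = field(repr=False, default_factory=SurvivalPolicy)

    @property
    def acceptance_rate(self) -> float:
        return self.n_surviving / self.n_generated


def _tree_rng(seed: int | None, tree_index: int) -> np.random.Generator:
    """Independent substream for tree ``tree_index`` of a run.

    Keyed on (seed, index) so that discarded non-survivors can never
    desynchronize the stream of later trees.
    """
    return np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, tree_index]))


def simulate_tree(params: BDParams, rng: np.random.Generator | None = None) -> PhyloTree:
    """Simulate one tree: origin split at time 0, fixed present at ``duration``.

    Event-driven (Gillespie over independent lineages): because rates are
    constant and lineages do not interact, each lineage's fate can be drawn
    in isolation — an exponential waiting time with rate S+E, then a
    speciation with probability S/(S+E), else an extinction.  Raises
    :class:`LineageCapError` when more than ``max_lineages`` lineages are
    created (expected for strongly supercritical runs over long windows).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    S, E, T = params.speciation_rate, params.extinction_rate, params.duration
    total = S + E
    scale = 1.0 / total if total > 0 else np.inf
    p_spec = S / total if total > 0 else 0.0

    parent: list[int | None] = [None, None]
    birth: list[float] = [0.0, 0.0]
    death: list[float] = [0.0, 0.0]
    extant: list[bool] = [False, False]
    children: list[list[int]] = [[], []]

    # Random draws are consumed from block buffers: one exponential waiting
    # time per lineage, one uniform per realized event.  Buffering changes
    # nothing statistically (consumption order is fixed) but removes the
    # per-draw overhead that dominates large supercritical trees.
    BLOCK = 4096
    ebuf: list[float] = []
    ubuf: list[float] = []
    ei = ui = 0

    i = 0
    while i < len(birth):
        if total == 0:
            death[i], extant[i] = T, True
            i += 1
            continue
        if ei >= len(ebuf):
            ebuf = rng.exponential(scale, BLOCK).tolist()
            ei = 0
        t = birth[i] + ebuf[ei]
        ei += 1
        if t >= T:
            death[i], extant[i] = T, True
        else:
            if ui >= len(ubuf):
                ubuf = rng.random(BLOCK).tolist()
                ui = 0
            u = ubuf[ui]
            ui += 1
            if u < p_spec:
                death[i] = t
                n = len(birth)
                children[i] = [n, n + 1]
                parent += [i, i]
                birth += [t, t]
                death += [0.0, 0.0]
                extant += [False, False]
                children += [[], []]
                if len(birth) > params.max_lineages:
                    raise LineageCapError(
                        f"lineage cap {params.max_lineages} exceeded at "
                        f"t={t:.3f} (S={S}, E={E}, T={T}); supercritical blow-up"
                    )
            else:
                death[i] = t  # extinction; extant stays False
        i += 1

    lineages = {
        j: Lineage(
            id=j,
            parent_id=parent[j],
            birth_time=birth[j],
            death_time=death[j],
            extant=extant[j],
            child_ids=children[j],
        )
        for j in range(len(birth))
    }
    return PhyloTree(lineages=lineages, present_time=T, origin_ids=(0, 1))


def simulate_surviving(params: BDParams, policy: SurvivalPolicy | None = None) -> SurvivalSample:
    """Rejection-sample trees conditioned on survival to the present.

    Generates batches of ``policy.batch_size`` trees and keeps the first
    ``policy.n_keep`` with at least ``policy.min_extant_tips`` extant
    lineages, in generation order.  Batches continue (up to ``max_batches``)
    until enough survivors accumulate, so low-survival regimes still yield a
    full sample; the realized acceptance rate is reported alongside.

    Raises :class:`SurvivorShortfallError` if the batch budget runs out
    first — the signature of a near-certain-extinction regime.
    """
    if policy is None:
        policy = SurvivalPolicy()
    kept: list[PhyloTree] = []
    n_generated = 0
    n_surviving = 0
    n_single = 0
    for b in range(policy.max_batches):
        for j in range(policy.batch_size):
            idx = b * policy.batch_size + j
            tree = simulate_tree(params, _tree_rng(params.seed, idx))
            n_generated += 1
            n_ext = tree.n_extant
            if n_ext == 1:
                n_single += 1
            if n_ext >= policy.min_extant_tips:
                n_surviving += 1
                if len(kept) < policy.n_keep:
                    kept.append(tree)
        if len(kept) >= policy.n_keep:
            return SurvivalSample(
                trees=kept,
                n_generated=n_generated,
                n_surviving=n_surviving,
                n_single_survivor=n_single,
                params=params,
                policy=policy,
            )
    raise SurvivorShortfallError(
        f"only {len(kept)} of {policy.n_keep} survivors after "
        f"{policy.max_batches} batches of {policy.batch_size} "
        f"(S={params.speciation_rate}, E={params.extinction_rate}, "
        f"T={params.duration})",
        survivors_found=len(kept),
    )
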