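# Methods

## The question

A *total group* originates when a lineage splits from its living sister
group; its *crown group* is the clade founded by the most recent common
ancestor (MRCA) of all its extant members. The gap between the two — the
stem — is where a clade's extinct early offshoots live, and its expected
duration controls how literally first fossil appearances can be read as
crown-group ages. `crownsim` asks a purely neutral question: under a
constant-rate birth–death process conditioned on survival to the present,
*when* within its total group's history does the crown group tend to
emerge?

## Model

Trees start at time 0 with a split into two lineages (the total-group
origin) and run to a fixed present at time T. Each living lineage,
independently, speciates at hazard rate S and goes extinct at hazard rate E
(events per lineage per time unit); the diversification rate is D = S − E.
Because rates are constant and lineages independent, each lineage's fate is
drawn in isolation: an exponential waiting time with rate S + E, then a
speciation with probability S/(S+E), else an extinction. A speciating
lineage terminates and is replaced by two daughters (bifurcation, no
budding), so internal lineages die exactly at their daughters' birth.
Lineages alive at T are flagged extant explicitly — never inferred from
floating-point comparison with T.

The rates are hazard rates, not per-step probabilities: the study grid
reaches S = E = 0.9, and probabilities of 0.9 + 0.9 per step could not be
mutually exclusive events. "Duration 114" therefore means 114 time units of
continuous time.

## Conditioning on survival

All real crown groups survive by definition, so trees are conditioned on
survival by rejection: batches of 100 trees are generated and the first 50
with at least two extant tips are kept, drawing further batches when a
batch of 100 yields fewer than 50 survivors (bounded by `max_batches`,
default 400). Trees with exactly one extant tip are counted separately and
excluded: the crown group — the MRCA of at least two living lineages — is
undefined for them. The realized acceptance rate is reported with every
sample. Each tree draws from an independent RNG substream keyed on
(seed, tree index), so discarding non-survivors can never desynchronize
later trees, and the kept sample is invariant to the batch partition.

A safety cap (10⁶ lineages per tree, configurable) aborts strongly
supercritical runs in a controlled way; this is why the supercritical sweep
uses a short window (below), and why the (S = 0.9, E = 0.1) cell is outside
the default grid.

## The crown statistic

The crown node is the most recent node ancestral to every extant tip.
Under the bifurcation convention that is the *split* of the MRCA lineage
into the two oldest surviving daughter clades, so the crown emergence time
is the MRCA lineage's death time; when extant tips descend from both origin
lineages the MRCA is the initial split itself and the crown time is 0.
This convention is forced by the statistic's own boundary behaviour: the
fraction must be exactly 0 precisely when both origin lineages leave
survivors, and strictly positive when one origin subtree is wholly extinct.

The headline statistic is the **crown fraction**: crown time divided by T,
in [0, 1]. It is computed in exact node-time arithmetic on the simulated
tree, never re-derived from serialized output.

Two independent routes compute the crown node: an O(n) sweep that counts
extant descendants per lineage and descends while a single child holds them
all, and a brute-force oracle that materializes every tip's root-ward path
and intersects the sets. The suite requires exact agreement on all fixture
trees and on ≥1000 random trees spanning subcritical, critical and
supercritical regimes.

## Study conditions

Two sweeps, exactly as specified by the study design:

* **equal rates** — S = E ∈ {0.1, 0.3, 0.5, 0.7, 0.9}, T = 114, 50
  survivors per rate (250 trees). Critical diversification (D = 0) over a
  long window.
* **diversification** — E ∈ {0.1, 0.3, 0.5, 0.7, 0.9} × D ∈ {0, 0.2, 0.4,
  0.6}, S = E + D, T = 15, 50 survivors per cell. Cells with S > 0.9 are
  excluded by rule (6 of 20), leaving 14; exclusions are logged, never
  silently absent. The window is short because supercritical trees grow as
  e^(DT): at D = 0.6 and T = 15 a tree already carries ~2·e⁹ ≈ 16,000
  extant tips, and longer windows hit the lineage cap.

The two sweeps deliberately use different T (114 vs 15); the crown fraction
is dimensionless, but the windows are not comparable in absolute time and
no cross-sweep contrast of absolute crown times is drawn.

Per-condition summaries report the mean, the sample (n−1) standard
deviation (n = 50 is small, and ±2 s.d. is the conventional plotting
interval for these summaries), and the standard error of the mean used in
the trend and bound checks.

## Numerical choices

* Waiting times come from numpy's PCG64 generator; draws are consumed from
  block buffers (one exponential per lineage, one uniform per event), which
  changes nothing statistically but removes per-draw overhead on large
  trees.
* Continuous time makes ties probability-zero; the suite asserts distinct
  event times rather than implementing tie-breaking.
* Newick branch lengths are forward durations; extant status rides on a
  tip-label suffix (`|A` alive, `|X` extinct) so files stay readable by any
  Newick parser. Serialization uses the shortest exact float repr, making
  fixed-seed outputs byte-identical. Extant-only export prunes extinct
  lineages and suppresses unary nodes while preserving root-to-tip path
  lengths; a one-sided tree keeps its distance from the origin as a root
  edge length.
* Condition seeds derive from (sweep seed, mode, cell index) through
  `numpy.random.SeedSequence`, so adding or skipping cells never shifts
  other cells' streams.

## What the generator does and does not emulate

The simulator *is* the study system: constant-rate, fully neutral,
fixed-duration birth–death trees. It does not model time-varying
("waxing–waning") diversification, density dependence, taxon-count
conditioning, or any fossilization/sampling process. Passing tests
therefore show what the neutral constant-rate model implies about crown
placement — the 50% expectation at criticality and the pull toward the
origin as D rises — not that real clades obey those rates. In particular,
the "latest at 50%" bound is a statement about constant rates; episodic
diversification can stretch stems beyond it.

## Known limitations

* Near-critical fast-rate conditions (S = E = 0.9, T = 114) accept only
  ~2% of trees; the rejection loop is exact but most of the compute is
  spent on discarded trees.
* The equal-rates design keeps 50 survivors per condition, so per-condition
  means carry standard errors of ~0.04; trends smaller than that are not
  resolvable at this design size.
* The figure renderer is schematic (lineages as horizontal segments,
  crown clade shaded); it is a thin optional layer and nothing downstream
  depends on it.
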