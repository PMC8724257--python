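# Methods

## The quantities computed

**Citation indices.** For a survey of N prescriptions, FC(m) is the number
of prescriptions containing material m and RFC(m) = FC(m) / N ∈ [0, 1].
Counting is *presence-based*: a material listed twice in one prescription
(e.g., two processed forms recorded under one id) counts once, since
occurrence-based counting could push RFC above 1. Duplicate rows therefore
collapse to the first-listed dose with a logged warning. RFC is kept exact
internally and additionally reported rounded to 2 decimals, the precision
survey tables print. The frequent-material filter RFC ≥ t (default t = 0.1)
compares the exact RFC inclusively.

**Property and flavor profiling.** A raw pharmacopeia string such as
"Mild warm; sweet and pungent" is split at the first semicolon into a
property phrase and a flavor phrase. Intensity prefixes (mild, highly)
collapse into the base class — mild warm → warm, highly hot → hot,
mild cold → cold — because the five-way nature classification
(cold / cool / neutral / warm / hot) is what profiling aggregates over;
this collapse is also the only mapping under which the packaged catalog's
property split sums to the printed 45 / 27 / 14 / 9 / 5 percentages.
Flavor phrases split on commas and "and", again dropping intensity
prefixes; a material may carry several flavors, so flavor percentages can
sum above 100. Percentages use the number of materials as denominator and
round to the nearest integer, ties away from zero.

A catalog may list two trade forms of one species (here: red and black
jujube dates, both *Ziziphus jujuba*). The effect breakdown exposes a
`dedup_species` flag that counts such records once per category while
keeping the full material count as denominator; both conventions are
computed, neither is silently imposed.

**Dose summaries.** Per-material daily doses are summarized by mean, sample
SD (n − 1 denominator), and quartiles by linear interpolation between order
statistics — the convention of standard box plots. A single observation
yields SD 0 with an explicit `sd_undefined` flag rather than NaN. Whether a
survey's printed "± " values are sample or population SD is generally not
stated; the sample convention is this package's choice and is what its own
outputs mean.

**Combination mining.** Frequent itemsets are enumerated levelwise with
downward-closure pruning: a size-k candidate is generated from two
size-(k−1) frequent sets sharing a (k−2)-prefix and kept only if all its
(k−1)-subsets are frequent, then counted by a linear scan. At survey scale
(≤ ~100 materials, ~100 transactions) this transparent algorithm is
preferable to FP-growth: it is trivially checkable against the brute-force
subset-scan oracle, which the test suite does on a thousand random
instances. Support defaults to 0.50 of N, compared inclusively; confidence
defaults to 0.95, compared strictly — survey write-ups use both "set as
50%" and "> 50%", and at N = 99 the two readings select identical itemsets
because 49.5 is not an integer (asserted as a test). Rules default to
single-item consequents (the form printed in survey reports); an
`any_split` policy exists for exploration. Only support and confidence are
computed — no lift or leverage. All outputs carry deterministic sort orders
so repeated runs are byte-identical.

**Core network.** The core is the union of items over frequent itemsets of
size ≥ 2. Nodes carry FC and the property bucket (the attributes that drive
circle size and color in survey figures); edges default to frequent pairs
only, with an `all_pairs` policy for exploratory use, and are weighted by
the pair's transaction count. Layout is a rendering concern and out of
scope.

## The synthetic-data generators

**Archetype sampler.** Real prescription collections cluster around
classical formula cores. The sampler draws, per prescription, one archetype
(an item set) by normalized weight, then adds each add-on material
independently with its configured probability, then draws each present
material's dose from a normal distribution clipped below at 0.5 g (doses
are positive; pharmacopeia minima are of that order). The packaged
demonstration model uses archetype weights that follow an explicit feasible
witness of the packaged combination counts (55 of 99 prescriptions carry
the full five-material core, 19 carry just the Dang Gui / Chuan Qiong pair,
and so on), add-on probabilities near printed citation fractions, and dose
models using the three printed mean ± SD values (HP 15.12 ± 7.24 g,
ZJH 25.18 ± 8.48 g, OI 3.09 ± 2.04 g) with midpoint-of-range means and
quarter-range SDs elsewhere. Clipping at 0.5 g biases the mean of the HP
model upward by ≲ 0.1 g at these parameters; recovery tolerances allow for
it.

What the sampler does *not* emulate: the full 77-material frequency
spectrum, regional structure, pharmacy-level dose idiosyncrasies, or any
correlation between doses. Tests passing on sampled data therefore
demonstrate pipeline correctness (counts, thresholds, determinism), not
fidelity of any ecological conclusion about real surveys.

**Exact constraint solver.** Given exact support counts for itemsets over m
distinct items, partition transactions by their *composition cell* — the
subset of the m constrained items they contain. Each constraint (S, k) is a
linear equality over the 2^m cell counts (cells containing S sum to k), and
one more equality fixes the total N; cells outside the constrained closure
absorb padding. Integer feasibility of this system is decided by a MILP
solve (HiGHS via `scipy.optimize.milp`) with a seeded random objective, so
any feasible instance yields a witness, the seed selects among feasible
vertices deterministically, and m ≤ 16 keeps the cell space tractable. The
cell formulation is essential: greedy top-down allocation fails on
instances where a constrained item must be painted onto existing carrier
transactions rather than added in fresh ones. Every returned transaction
set is verified against the brute-force support oracle *inside* the
operation before being returned.

**Feasibility diagnosis.** Before (or instead of) solving, the checker
runs: (i) subset monotonicity — S ⊆ T requires count(S) ≥ count(T);
(ii) the exact integer search above when m ≤ 16; (iii) inclusion–exclusion
union bounds — for any group of ≤ 3 items whose full nonempty-subset
lattice is constrained, the union cardinality is determined exactly and
must not exceed N. Check (iii) is how the packaged fixtures' documented
inconsistency is proved: adding the printed singleton citation counts
(AS 95, LiC 94, RG 78) to the ten combination counts forces
|AS ∪ LiC ∪ RG| = 95 + 94 + 78 − 92 − 75 − 73 + 73 = 100 > 99. At least one
printed family of numbers must carry rounding or transcription error; which
one is undecidable from the printed record, so the packaged constraint
fixture keeps the combination counts and omits the singletons.

## Numerical and design choices

- Percent rounding: nearest integer, ties away from zero; RFC rounding:
  2 decimals. These reproduce every printed percentage from the packaged
  catalog.
- Frequency tables serialize exact fractions with full `repr` precision and
  are read back with round-trip float parsing, so write-then-read is the
  identity.
- Mining runs over the full catalog universe, not a pre-filtered core; the
  core *emerges* from the thresholds.
- Property/flavor/effect profiles use the frequent subset as denominator;
  family/part composition uses the full catalog — matching how surveys
  report each.
- Empty transactions are permitted (the solver's padding cells produce
  them); an empty *transaction set* (N = 0) is an error wherever a
  denominator is needed.
- Determinism: the sampler and solver are pure functions of (input, seed);
  the CLI `report` is byte-stable across runs at fixed seed and config, and
  its manifest records config and versions but no timestamps.

## Problem sizes

The packaged analyses run at survey scale: 99 transactions over ≤ 77
materials, a 64-cell integer program, 10,000-draw dose recovery, and
1,000-instance randomized miner-vs-oracle equivalence (≤ 12 items × ≤ 50
transactions). The full suite completes in seconds.

## Known limitations

- The miner is quadratic in the candidate join step and scans transactions
  per candidate; fine at survey scale, unsuitable for retail-scale basket
  data by design.
- The solver handles at most 16 distinct constrained items and exact
  equality constraints only (no inequalities or ranges).
- The archetype sampler draws doses independently per material; real
  prescriptions correlate doses within a formula.
- Printed totals that depend on the full unreleased survey (the overall
  combination and rule counts, 77-material family/part proportions,
  per-material dose means) cannot be reproduced from packaged fixtures and
  are covered by internal-consistency and property-based tests instead.
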