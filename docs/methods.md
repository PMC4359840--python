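# Methods

## Decision tables

All stages operate on a decision table: a finite set of subjects (rows)
described by discrete condition attributes (scale-item scores) plus one
categorical decision attribute (Normal / MCI / AD, or arbitrary labels for
generic tables).  Values are categorical tokens compared only by equality —
the rough-set machinery never orders or averages them — so `"5"` and
`"5.0"` are distinct unless the integer-normalisation flag is set at load
time.  Missing cells are rejected at load with their coordinates; duplicate
subject rows are legal (rows are anonymous; internal identifiers are row
indices).  Tables may be *inconsistent* (identical condition rows with
different decisions): the dependency degree of the full condition set is
then simply below 1, and reducts preserve that value rather than reach 1.

## Rough-set kernel

For an attribute subset B, the indiscernibility partition groups subjects
agreeing on every attribute of B.  The positive region POS_B(D) is the
union of partition blocks that are pure in the decision; the dependency
degree is γ_B = |POS_B(D)|/|O|.  The core is computed by the single-removal
test (an attribute is in the core iff deleting it alone changes γ of the
full set), which coincides with the intersection of all reducts; the test
suite asserts this identity against the exhaustive enumerator on small
random tables.

`enumerate_reducts` is an exhaustive oracle, not a production reducer: it
visits subsets in order of increasing size, prunes supersets of found
reducts (so every hit is minimal by construction), and refuses tables with
more than 16 attributes by default since minimal attribute reduction is
NP-hard.

Numerics: partitions are computed by mixed-radix integer keys over
per-column factorized codes (with a lexicographic `np.unique` fallback if
the radix product would overflow 62 bits); block order follows first
occurrence, making all outputs deterministic.  γ comparisons inside the
core test use integer positive-region counts, never floats.

## GA reduct search

Chromosomes are bit vectors over the condition attributes; core positions
are pinned to 1 throughout.  Fitness is

F(x) = β·(1 − card(x)/card(C)) + |POS_x(D)|/|POS_C(D)|,

with the second term defined as 1 when the full set's positive region is
empty (degenerate table; a warning is emitted and parsimony alone drives
the search).  Defaults follow the published parameterisation where one
exists: population 1000, at most 500 generations, crossover probability
0.5, mutation probability 0.03, elite fraction 0.2, tournament selection.
Choices the source description leaves open, fixed here:

* **β = 0.5** — keeps the dependency term (range [0, 1], weight 1)
  dominant over parsimony (range [0, β]), so γ-preservation is only traded
  for roughly β/|C| of dependency per dropped attribute.  Configurable.
* **Crossover** — one-point (tails swapped at a uniform cut, core
  re-pinned); uniform crossover is available behind `crossover="uniform"`.
* **Mutation** — a chromosome is mutated with probability P_m, and then a
  single uniformly chosen non-core gene is flipped (not per-bit flipping).
* **Elitism** — the top `elite_fraction` of each generation is copied
  unaltered, which also guarantees a non-decreasing best-fitness history;
  setting the fraction near zero still preserves one individual.
* **Stagnation stop** — "no change for several generations" is fixed at a
  50-generation window, alongside the generation cap.
* **Selection** — tournament of size 2 with replacement, repeated until a
  full replacement population is drawn; ties broken by fewer selected
  attributes, then lower population index.
* **Initialisation** — non-core bits are Bernoulli(1/2).  An all-zero
  chromosome (possible only with an empty core) is repaired by flipping one
  rng-chosen bit; the public `fitness` function rejects all-zero input.
* **Early exit** — if the core alone already preserves γ the core is
  returned with zero generations run.

Runs are bit-reproducible from the seed.  `GARoughSetSelector` wraps the
search as a scikit-learn `SelectorMixin`, so it slots into pipelines and
model selection.

## Bayesian-network classifier

The classifier is a discrete Bayesian network over the selected items plus
one class node, with one CPT per node estimated by Laplace-smoothed
relative frequency (α = 1 by default; empty parent configurations therefore
get uniform columns).  Two structure strategies:

* **naive** (default): class → every item.  With ~500 training cases and
  ~10 selected items this is the robust choice; richer structures mostly
  add variance at this scale.
* **hillclimb**: greedy add/delete/reverse arc search maximising a
  BIC-penalised log-likelihood, starting from the naive structure, class
  node always present, in-degree capped (default 3), acyclicity enforced.

Screening cases observe every selected item, so inference needs no junction
tree: the posterior over the class node is the normalised product of CPT
entries evaluated once per class value (log-space).  Ties at the argmax go
to the first class in the declared label order.  A value unseen in training
is an error at α = 0; with α > 0 it receives the pseudocount floor
α/(N_config + α(k+1)) (treated as a novel (k+1)-th state), and an unseen
*parent* value yields an uninformative uniform likelihood.  Partially
observed cases are out of scope.  Models serialise to plain JSON (states,
parents, counts, CPTs) and reload bit-exactly.

## Evaluation protocol

* **Metrics** — per-class recall (row-wise) and precision (column-wise)
  and overall accuracy from a truth × prediction confusion matrix;
  zero-denominator entries are reported as undefined (`None`), never 0.
* **Cross-validation** — stratified k-fold (k = 10), shuffled with a
  per-repetition derived seed, repeated 10 times; the confusion matrix is
  pooled within a repetition and metrics are averaged across repetitions.
  An unstratified mode exists; stratification is the default because the
  smallest class holds ~29% of subjects and folds stay balanced.
* **0.632 bootstrap** — per repetition an n-out-of-n draw with replacement
  trains the model; the in-bag (resubstitution) and out-of-bag confusion
  matrices are normalised to proportions and combined with Efron's weights
  0.368/0.632, from which all metrics are read.  This makes the combined
  error an exact convex combination of the component errors (asserted in
  the tests).  Draws missing a class are redrawn (logged; at most 100
  attempts).  Repetitions default to 10.
* **Friedman test** — mid-ranks within blocks, tie-corrected chi-square
  with k − 1 degrees of freedom, asymptotic p-value; a fully tied matrix
  returns statistic 0, p = 1.  When the CLI compares classifiers, blocks
  are resampling repetitions.
* **Wilcoxon signed-rank** — zero differences dropped, mid-ranks for tied
  magnitudes; exact p by subset-sum dynamic programming for n ≤ 25 without
  ties, otherwise a normal approximation with tie-corrected variance and
  (by default) continuity correction.  Two-sided statistic is
  min(W⁺, W⁻); one-sided alternatives use W⁺.  Both tests are
  cross-checked against independent reference implementations to 1e−9.
* **Reduction ratio** — r = (m − n)/m × 100 for m items before and n
  after reduction; 34 → 10 gives 70.59%.
* **Cut-off baselines** — MMSE: ≥ 27 Normal, 19–26 MCI, ≤ 18 AD.  The
  published staging leaves 25–26 unassigned (normal ≥ 27, mild 19–24); the
  mild band is extended to 26 so the mapping is total, and the mild /
  moderate-severe split is mapped to MCI / AD.  MoCA publishes only the
  single cut-off at 26; below it a configurable secondary threshold
  (default 17: AD iff score ≤ 17) splits MCI from AD, and reports flag
  this as a package convention.  `TotalScoreCutoffClassifier` applies these
  stages to a 30-point rescaled item-total, as a weak comparator.

## Synthetic data

Real scale batteries with adjudicated diagnoses cannot be redistributed, so
two generators define the test conditions.

**Planted-reduct tables** (defaults: 300 objects, 5 relevant + 0 redundant
+ 10 irrelevant binary attributes, 3 classes).  Relevant attributes are
uniform; the decision is the sum of their codes modulo the class count (for
two binary attributes, exactly XOR), so it depends on every relevant
attribute, is surjective onto the classes, and gives the planted set
dependency degree 1 by construction.  Redundant attributes are
value-permuted copies of relevant columns (interchangeable in reducts,
hence shrinking the core); irrelevant attributes are independent uniform.
Binary value supports are deliberate: they keep the joint cardinality of
any small attribute subset far below the object count, so irrelevant
attributes cannot spuriously discern the sample and the planted set is
genuinely the minimal reduct — at higher cardinalities the table becomes
almost fully discernible by arbitrary subsets and "minimal reduct" loses
meaning in-sample.

**Cohorts** (defaults: 500 subjects; class mix Normal 28.8%, MCI 37.7%,
AD 33.5%; 34 grouped ordinal items named after 11 scale families, 10 of
them discriminative).  The 34-item granularity is the one reduction
operates on (the raw batteries hold 101 items; configurable).
Discriminative items score Binomial(max_i, p) with p = 0.85 − 0.25·stage
(stage 0/1/2 for Normal/MCI/AD, clipped to [0.05, 0.95]), so class means
decrease with disease stage on bounded ordinal supports; background items
are class-independent Binomial(max_i, 0.6) over mixed maxima (5/3/2/1).  A
5% contamination rate replaces scores with uniform draws.  A `separable`
mode draws discriminative scores from disjoint per-class bands — useful for
pipeline sanity checks (a classifier can be perfect) but not realistic.

What the cohorts do **not** emulate: inter-item correlation within a scale
(items are conditionally independent given the class, exactly the naive
network's assumption, so cohort results cannot expose naive-structure
misspecification), informant-based adjudication noise, demographic effects
on scores, and floor/ceiling artefacts of real instruments.  Passing tests
on these cohorts therefore demonstrate correctness of the algorithms under
their stated assumptions, not clinical performance.

## Problem sizes used in the automated checks

The verification suite and `scripts/acceptance.py` run the GA at population
200 and at most 100 generations on the planted tables (50 tables in the
suite, 20 in the script) and evaluate the cohort classifiers with 10-fold
CV and 10 bootstrap repetitions at n = 500 — the same object and attribute
scales as the study conditions, with the GA population scaled down from
1000 (the search space of 15–17 bits does not need a four-digit
population; recovery rates are reported by the script rather than
assumed).

## Known limitations

* The GA's fitness deliberately permits trading ~β/|C| of dependency per
  dropped item, so on noisy tables the selection may sit marginally below
  full γ; set β lower to force stricter preservation.
* Exact reduct enumeration is exponential and guarded at 16 attributes.
* The hill-climbing structure learner is a local search with a fixed
  operator set; it makes no optimality claim.
* Cut-off baselines assume 30-point instruments; other scales must be
  rescaled by the caller.
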