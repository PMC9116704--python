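# Methods

This note documents the model, the numerical choices, and what the test
suite does and does not demonstrate.

## Problem and model

The package imputes missing entries of a pairwise evolutionary distance
matrix δ over N OTUs so that a distance method (neighbor joining) can be
applied downstream. The approach is an iterative chained-regression
imputer in the missForest style — each incomplete column is regressed on
all other columns with a random forest, repeatedly, until an error
criterion stops improving — with three phylogeny-specific components:

- a symmetric initialization (column means, then pairwise averaging);
- an SSR tie-break for tree splits driven by the NJ Q-matrix of the
  initialized matrix, Q_ij = (N−2) δ_ij − S_i − S_j with S_x the full
  row sum (the diagonal zero is included in S_x; it cancels in
  comparisons);
- per-iteration symmetrization via the *split matrix* step: lower-mirror,
  upper-mirror and transpose-mean candidates compete under least squares
  (against each candidate's own NJ tree), minimum evolution, or the
  normalized set difference to the previous iteration.

The loop starts with old_error = ∞ so the first iteration is always
accepted, and returns the previous iteration's matrix the first time the
error fails to improve strictly. A safety cap (`max_iterations`, default
50) guards against floating-point oscillation; if it is hit the best
matrix so far is returned with `converged=False`.

Two stop criteria are supported. The set-difference criterion compares
consecutive matrices cell by cell, Σ(new−old)²/Σnew². The LS criterion
scores each iteration's matrix against its *own* NJ tree — a per-matrix
phylogenetic fit — and stops when that fit stops improving. The
cross-iteration form is deliberately left to the set-difference
criterion; making LS self-referential is what lets the rule judge each
matrix "from a phylogenetic perspective" rather than by proximity to its
predecessor.

## Assumptions and conventions

- **Missingness is pairwise.** Missing distances arise from pairs of
  sequences that cannot be compared, so masks are symmetric:
  `inject_missing` draws ⌊fraction · N(N−1)/2⌋ unordered pairs without
  replacement and masks both cells, redrawing any selection that would
  leave a column with no observed off-diagonal entry. The floor keeps the
  realized fraction at or below the requested one.
- **Column means exclude the diagonal.** The diagonal zero is structural,
  not data; including it would bias initial guesses downward.
- **Observed values are preserved exactly.** They are re-asserted after
  every forest write and in the final result. If a mask is asymmetric
  (possible only in hand-edited files), the missing partner of a
  one-sided observed cell mirrors the observed value so the output stays
  symmetric.
- **LS sums over ordered pairs** (each unordered pair twice). All
  candidates are scored under the same convention, so selection is
  unaffected; reported LS values are twice the unordered-pair sum.
- **NJ ties and negative branch lengths.** The joined pair is the
  lexicographically smallest (i, j) attaining the Q minimum, making the
  whole pipeline deterministic. Negative branch lengths are kept as
  computed — clamping would silently distort LS and patristic scores.
- **Tree containers are dendropy objects**; Newick serialization keeps a
  trifurcating root for unrooted trees. RF counts nontrivial bipartitions
  only, canonicalized by the side excluding the lexicographically
  smallest leaf label.

## Forest hyperparameters

Fractional hyperparameters are resolved as max(1, ⌈fraction · size⌉)
against the relevant dimension at fit time; `max_depth = −1` disables the
depth limit, and `max_depth = 1` resolves to the dataset size (depth
counted in edges — effectively near-unlimited at small N). Defaults are
the two tuned profiles:

| parameter       | non-bootstrap | bootstrap |
|-----------------|---------------|-----------|
| bootstrap       | off           | on (with replacement, full size) |
| trees           | 30            | 50        |
| max features    | 0.25          | 1.0       |
| max depth       | 1 (≈ unlimited) | 1 (≈ unlimited) |
| min leaf        | 0.01          | 0.13      |

Feature subsets are redrawn at every node (standard random-forest
practice). Split thresholds are midpoints of consecutive distinct sorted
values; when two adjacent floats are so close that their midpoint rounds
onto the upper value, the threshold falls back to the lower value, which
induces the identical partition under the `x ≤ t` rule. SSR ties are
detected at relative tolerance 1e−9 — exact float ties are rare, and the
Q-priority mechanism is meaningless without a tolerance. One seeded
generator, split into per-tree substreams, drives bootstrap draws,
feature subsets and random tie-breaks, so identical (data, config, seed)
gives bit-identical predictions. The Q-priority table is computed once
from the initial-guess matrix and not refreshed across iterations.

## Synthetic data

`make_instance` emulates the benchmark inputs: a uniform random unrooted
bifurcating topology (sequential attachment to a uniformly chosen edge),
i.i.d. branch lengths — uniform(0.1, 1.0) substitutions/site by default,
a realistic inter-species range; exponential available — and the tree's
patristic matrix, which is exactly additive. Optional multiplicative
lognormal noise (unit mean, chosen coefficient of variation) perturbs
each pair symmetrically; multiplicative noise keeps distances positive,
which additive Gaussian noise would not. Masks come from
`inject_missing`.

What this does *not* emulate: estimation noise with distance-dependent
variance, saturation at large distances, model misspecification, or
non-uniform missingness (real missing data cluster by taxon). Passing
tests therefore demonstrate correctness of the algorithmics and recovery
under idealized additive conditions, not field performance on real
alignments.

## Evaluation protocol

`run_benchmark` mirrors the standard protocol: ground truth is the NJ
tree of the complete source matrix; for each missing percentage a set of
masks is drawn (10 per percentage by default), each imputed several times
(5 by default) under each profile, and each run scored by NRF =
RF/(2N−6). Masks are generated once per (percentage, index) and shared
across profiles and runs, so comparisons are paired. `accumulate_nrf`
sums per-cell mean NRF percentages across a dataset × percentage grid.
Wall-clock time is recorded per run but never used in any assertion
(hardware-dependent).

Test-scale choices: the suite exercises N = 8–12 with fractions 5–40%,
20 seeds for the recovery/baseline comparisons, and a 6-percentage ×
10-mask grid (1 run per mask) for the degradation trend — sizes at which
the full pipeline remains interactive while the statistical checks are
stable. The trend check asserts a positive rank correlation between the
missing percentage and the per-percentage mean NRF plus a strictly higher
mean at the largest percentage than at the smallest, in at least 4 of 5
replicates; strict elementwise monotonicity is deliberately not asserted,
since adjacent-percentage means routinely cross by a few points under
this protocol even at realistic replication.

## Degenerate inputs and edge cases

- N < 4 is rejected for imputation and RF/NRF (2N−6 vanishes at N = 3);
  NJ itself accepts N = 3 and returns the closed-form star.
- A fully missing column is rejected with advice to drop the OTU.
- A fully observed matrix returns immediately (one iteration, NJ tree of
  the input).
- Pure nodes (constant targets) and unsplittable nodes become leaves;
  forest predictions are means of training targets and hence always lie
  within the observed range of the imputed column — this is what makes
  the output provably nonnegative.
- `set_difference_error` is undefined for an all-zero current matrix and
  raises.

## Known limitations

- The imputer is O(iterations × N × trees × N log N) per run with pure
  NumPy/Python trees; it is comfortable to a few hundred OTUs but not
  engineered for thousands.
- Only unrooted bifurcating NJ topologies are produced; rooted or
  multifurcating ground truths are out of scope.
- The LS selector rebuilds an NJ tree per candidate per iteration, which
  dominates runtime at larger N.
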