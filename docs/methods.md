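# Methods

## Model and procedure

`ordcascades` decides, for a labelled dataset (X, y) with label space 𝒴,
which total orders of 𝒴 are *reflected* in the feature representation. The
instrument is the ordinal classifier cascade: for an assumed order
y₍₁₎ ≺ … ≺ y₍ₘ₎, binary base classifiers c₍ₖ₎ trained only on the samples of
classes y₍ₖ₎ and y₍ₖ₊₁₎ are evaluated sequentially, and the first classifier
predicting its first class determines the output (the last label if none
does). A wrong order assumption lets an early classifier claim the feature
region of a later class, collapsing that class's sensitivity — the screen's
signal. An order is considered reflected when the cascade's minimal
class-wise sensitivity p* reaches a threshold t (default 0.5: every class
must be recovered at better than coin-flip sensitivity).

The pipeline has four stages, all sharing one fold assignment:

1. **Folds.** A repeated stratified partition (default 10 repeats × 10
   folds). Stratification deals each class round-robin onto folds so every
   test fold contains every class, making per-fold class-conditional rates
   well-defined. With optional sample groups (paired designs, per-subject
   profiles), whole label-pure groups are dealt instead of samples so a
   subject never appears in training and test simultaneously.
2. **Pairwise table.** All (m−1)·m ordered-pair classifiers are fitted per
   split on the training portions of their two classes and evaluated on the
   test portions of *all* classes, memorising first-class sensitivities
   FC(i,j) and pass-on rates SC(i,j,r). Rates are unweighted means of
   per-split rates over all repeat × fold test sets (macro pooling; folds
   are equal-sized under stratification, so micro pooling would coincide on
   balanced data).
3. **Screen.** Depth-first enumeration of orders. The first position is
   unconditional (no classifier exists yet); extending a partial order
   ending in yᵢ by yⱼ requires FC(i,j) ≥ t and SC(i,j,r) ≥ t for every
   remaining label r. A failing check prunes (remaining−1)! orders, counted
   analytically, so rejected-order statistics never require enumerating the
   full factorial space.
4. **Cross-check.** The per-position bounds
   min(FC(pair i), min_{k<i} SC(pair k, class i)) only upper-bound the
   cascade's sensitivities, so each surviving candidate is evaluated as a
   full cascade and passes only if the measured p* ≥ t.

### Exactness of the bound dominance

Cascade evaluation replays the *same cached per-split predictions* the rate
table was built from — no refitting per order. Per split, a cascade's
sensitivity for the class at position i is, sample for sample, dominated by
each of its bound terms; averaging a dominated quantity over splits keeps it
dominated. The empirical invariant p* ≤ overall bound (and class-wise
sensitivity ≤ class bound) therefore holds exactly, to floating-point
accuracy, on every dataset — the test suite asserts it on hundreds of random
orders. Model reuse is also what makes screening 10! orders tractable: the
complete linear-family benchmark (table + screen + cross-check) runs in a
few seconds.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| base learner | linear SVM, cost C = 1 | soft-margin linear SVM (libsvm backend), no feature scaling, no class weights; the standard transcriptomics baseline and the benchmark setting |
| repeats × folds | 10 × 10 | repeated CV smooths fold noise in the rates; requires every class (or group count) ≥ folds |
| threshold t | 0.5 | minimal class-wise sensitivity an order must be certified for; the CLI grid screens t ∈ {1.00, 0.95, …, 0.50} from the top down |
| inclusive_sc | true | the pass-on check at an extension also covers the label just placed; with it the screen's pass set is *exactly* {orders with overall bound ≥ t}, which the brute-force oracle test confirms. The exclusive variant (a strictly more permissive reading of the recursion's quantifier) is available as a switch |
| fold seed | — | single integer controlling the fold assignment; synthetic-data seeds are separate |

Threshold comparisons pass on ties (≥ t). Rates are kept at full float
precision; percent formatting with one decimal happens only in rendered
reports. A decision-function value of exactly zero resolves to the pair's
later class (the pass-on direction for the canonical orientation) — a
measure-zero event on continuous data, documented for completeness.

Both orientations (i,j) and (j,i) of a pair share one underlying fit per
split: training set and learner are identical and deterministic, only the
first/second-class roles differ. The table still stores all (m−1)·m ordered
entries; the sharing halves the fit count and makes the mirror identity
FC(i,j) = SC(j,i,i) exact.

## Synthetic data families

The three generator families reproduce the benchmark designs: 10 classes ×
100 samples in ℝ², isotropic Gaussian noise of common sd around class
centroids; sd = 0.2 is the headline setting and {0.2, 0.6, 1.0} the
condensed spread sweep used by the packaged tests.

* **linear** — centroid of class i at (i, i).
* **curved** — centroids follow a random monotone walk from (0, 0) with
  per-coordinate increments ~ U(0.5, 2); the walk is drawn from the seed
  before any sample noise, so centroids and noise are independently
  reproducible.
* **nonordinal** — centroids on a fixed scrambled assignment of 10 grid
  points spanning [1, 4]² (9 points of a 3 × 3 grid plus (1.75, 1.75)),
  ordered so that no permutation is monotone in both coordinates (longest
  dominance chain < 10, asserted by test). The layout is this package's own
  choice of a maximally order-free arrangement in that range and is
  overridable per spec.

What the generators do **not** emulate: high dimensionality, correlated
features, heteroscedastic or heavy-tailed noise, unbalanced classes — all
present in real expression data. Passing tests on these families shows the
machinery (rates, bounds, pruning, accounting) is correct and that clearly
ordinal vs. clearly non-ordinal geometries are separated; it does not
calibrate expected sensitivities for any real dataset. Real matrices enter
through `load_dataset` (TSV/CSV, either orientation, labels as column or
side file) and use the identical pipeline and report schema.

A known borderline of the linear family: class i+1 sits exactly on the
decision boundary of the classifier for classes (i, i+2), so pass-on rates
like SC(8,10,9) hover around 0.5 with substantial draw-to-draw variance (the
max-margin boundary is set by a handful of extreme samples). Orders that
swap the last two classes of either direction therefore enter or leave the
candidate set depending on the draw — the reason screens of ordinal
families return two to four candidates rather than always exactly two, and
why such extras are usually removed again by the cross-check.

## Numerical and design choices

* External pass-on rates SC(i,j,r), r ∉ {i,j}, are measured on the *test*
  portion of class r per split, keeping every rate on the same held-out
  sets as the cascade evaluations; this is what makes the dominance
  invariant exact (see above) where other choices would make it approximate.
* `max_certified_bound` brackets the maximum overall bound by threshold
  bisection over an early-exit variant of the pruned screen (tolerance
  1e-6), then takes the exact maximum over the few orders above the
  bracket. If no order reaches the tolerance the maximum is exactly zero
  (fold-averaged rates are multiples of 1/n_splits of per-fold counts).
* The worst-case lookup formula f(m) = Σₖ k·C(m, k+1) is provided as the
  closed form; the screen instruments its actual (short-circuited) lookup
  count, which on separable data at t = 0.5 is orders of magnitude below an
  exhaustive traversal.
* Degenerate inputs are rejected early with named offenders: missing or
  non-numeric cells, unlabeled or duplicated samples, classes smaller than
  the fold count, label-impure groups, folds = 1, thresholds outside
  [0, 1], orders with repeated or unknown labels.
* Serialised rate tables (JSON, bit-exact rates) support re-screening
  without refitting; cached per-split predictions and models live only in
  memory, so cross-checking needs the in-session table.

## Problem sizes in the packaged checks

The test suite and `scripts/acceptance.py` run the full benchmark scale for
the screening claims — 10 classes × 100 samples, 10 × 10 CV, all 3.6 million
orders per screen — because the pruned screen makes that cheap. Property
tests (brute-force equivalence, dominance, monotonicity) use 4-7-class
datasets or random rate tables, where exhaustive oracles are feasible. The
condensed sd sweep {0.2, 0.6, 1.0} stands in for a finer grid; behaviour is
monotone in sd (asserted separately), so the three points bracket the range.

## Limitations

* A cascade cannot distinguish an order from its reverse; candidate sets
  are symmetric by construction.
* The screen certifies *discriminability along an order*, not causality or
  temporal direction; near-threshold candidates (bounds within fold noise
  of t) should be judged with the cross-checked p*, and the last two
  positions of an order are the least constrained — swapped tail variants
  are the typical false positives.
* Exhaustiveness is over orders of the given label set (or an explicit
  subset); discovery of ordinal sub-structures beyond a named subset is out
  of scope, as are heuristic searches, probability calibration, reject
  options and alternative multi-class decompositions.
* Grouped folds require label-pure groups; group-spanning classes would
  break stratified rate estimation.
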