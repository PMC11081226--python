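# Methods

This note records the models and procedures `gafs` implements, the
parameters that matter, the numerical conventions, and the places where the
design was genuinely open and a choice had to be made.

## Problem setting

The package targets labelled sample-by-feature matrices of the kind produced
by expression profiling: thousands of features, tens to a few hundred
samples, 2–5 unordered classes, strong redundancy among features, class
imbalance, and occasional missing entries.  In that regime wrapper feature
selection (scoring subsets by a classifier) and filter selection (scoring
features by a statistic) are complementary, and both are implemented around
a single K-nearest-neighbour classifier.

## KNN classifier and distances

The classifier assigns a query the plurality label of its k nearest training
samples.  Two metrics are provided: Chebyshev, L∞(x, y) = max_l |x_l − y_l|,
and the weighted Minkowski family

    L_p(x, y) = ( Σ_l (w_l |x_l − y_l|)^p )^(1/p),  p ≥ 1, w_l ≥ 0,

with unit weights by default.  The weighted form is what couples the wrapper
to the classifier: a chromosome's per-feature weights are applied inside the
metric, so "empowering" a feature changes the geometry, not only membership.

Determinism conventions: equal distances keep the lower training index
(stable sort); vote ties go to the class whose nearest member is closest,
then to the lexicographically smallest label.  The default k is 7 —
recognition-rate scans over the odd grid 1, 3, …, 15 (odd k avoids binary
vote ties) typically peak there on this kind of data, and `scan_k` exposes
the scan so users can confirm on their own data.  Missing entries are not
accepted by the classifier; imputation is an explicit prior step, as is
standardization (never applied implicitly).

A note on the p → ∞ limit: L_p → L∞ as p grows, but at p = 64 the residual
is of order max·(r₂/r₁)^p where r₂/r₁ is the ratio of the second-largest to
the largest coordinate difference — only when that ratio is well below 1 is
the limit numerically attained.  The tests check the exact two-sided bound
L∞ ≤ L_p ≤ d^(1/p)·L∞ rather than a fixed absolute tolerance.

## Missing-value imputation

Rows are compared with a co-observation-masked taxicab distance on
standardized data,

    d(x*_i, x*_j) = Σ_n Z_in Z_jn |x*_in − x*_jn| / Σ_n Z_in Z_jn,

undefined when no coordinate is co-observed (undefined distances rank after
all defined ones).  Each incomplete row takes its k nearest rows (same
default k = 7, capped at the number of rows with defined distance) as the
donor set, and each missing standardized value is the weighted average of
the donors observing that feature, with inverse-distance weights

    β_j = (1/(d_j + ε)) / Σ_j' (1/(d_j' + ε)),  ε = 1e-8,

re-normalized over the eligible donors.  If no donor in the set observes the
feature, the nearest eligible row outside the set is used; failing even
that, the standardized feature mean (zero).  Values are mapped back through
x = x*·σ + μ.  Observed entries are returned bit-identical, and every
imputed standardized value is a convex combination of donor values.  The
weight function is this package's choice: any normalized, distance-decreasing
weighting fits the framework, and ε-stabilized inverse distance is the
common convention in KNN imputation.

Standardization uses the population SD (divide by N) with σ floored at 1e-8
for constant features; the affine inverse is exact to that floor.

## Chi-square relevance filter

Each feature is discretized (default: above/below its own median, giving a
presence/absence-style split; equal-frequency bins with r > 2 levels are
available), cross-tabulated against the classes, and scored with the
independence chi-square Σ (O − E)²/E, df = (r−1)(c−1), p-values from the
survival function.  For 2×2 tables this equals the closed form
n(ad−bc)²/[(a+c)(b+d)(a+b)(c+d)]; no continuity correction by default (a
Yates variant is exposed).  Ranking is descending by statistic with stable
ties; selection is top-m or p < α (α ≥ 1 selects everything, since null
features carry p = 1 exactly).  A feature constant after discretization
scores 0 with a warning.  No multiple-testing correction is applied by
default — the raw-α convention this kind of screening typically uses — but
Benjamini–Hochberg adjustment is available.

## Matrix-structured GA

The population is an R×C grid (default 5×5, 25 individuals).  One generation:

1. mark each row's best individual (first occurrence on ties);
2. copy it onto the row's main-diagonal slot (square grids only — a
   non-square grid disables diagonal dominance with a warning and uses the
   row best directly);
3. cross every off-diagonal cell with its row's diagonal individual at the
   crossover rate (default 0.9);
4. mutate each offspring gene at the mutation rate (default 1/dims);
5. re-evaluate changed cells;
6. elitism: if the new grid's best is worse than the incoming global best,
   the stored elite replaces the worst cell.

Continuous chromosomes blend arithmetically with a uniform α per offspring
and mutate by a Gaussian with σ = 10% of the bound width, clipped to the
box; binary chromosomes use uniform crossover and bit-flips.  The pairing
rule (off-diagonal × diagonal) is the package's reading of diagonal
dominance: the diagonal holds each row's champion, so every crossover pulls
toward a local best while elitism keeps the global one.  Convergence on the
2-D sphere benchmark comes mainly from blend contraction — offspring lie
between their parents, so the cloud shrinks geometrically around the elite —
which is why a fixed mutation σ still reaches 1e-6-scale minima within 200
generations.  Termination is a fixed generation budget with an optional
absolute fitness tolerance.  Everything is minimization; accuracy-maximizing
wrappers pass 1 − accuracy.

## GA-KNN wrapper selection

A chromosome is a length-D weight vector in [0, 1] under one of five
encodings; decoding keeps features with weight strictly above a threshold:

| scheme   | representation                | threshold |
|----------|-------------------------------|-----------|
| binary   | bits {0, 1}                   | 0.5       |
| decimal  | quantized to {0, 0.1, …, 1.0} | 0.5       |
| real     | free in [0, 1]                | 0.5       |
| gaussian | real, initialized N(0.5, 0.2) clipped | 0.5 |
| adaptive | real; threshold = mean weight of the current best, per generation | moving |

Only the scheme names are conventional; every decode/initialization rule is
this package's recorded interpretation and configurable.  Fitness is KNN
accuracy on a single seeded stratified 70/30 split of the input (one
accuracy per individual; cross-validation would be straightforward but is
not the default), with the weighted Minkowski metric restricted to the
decoded subset; an empty decode scores 0.  Results report the before/after
pair — the all-features accuracy and the best chromosome's accuracy — with
rates rounded to 4 decimals.

Two honesty caveats, both visible in the tests:

* the reported `acc_after` is the internal-validation accuracy of the best
  of ~R·C·(G+1) evaluated chromosomes and is therefore optimistically biased
  (winner's curse); on label-independent data it can sit far above the
  majority rate even though the selected subset carries no signal.  Held-out
  accuracy of the selected subset is the unbiased quantity, and that is what
  the experiment runner reports.
* when the classes are so separable that validation accuracy saturates at
  1.0 for almost any subset, accuracy-only fitness has no gradient: the
  evolution is neutral and the selected subset stays near its random
  initialization.  Strongly redundant planted signal produces exactly this
  regime; recovering specific "original" features is then non-identifiable,
  because redundant copies are interchangeable with their sources under any
  accuracy-based criterion.

## GP feature construction

Constructed features are binary arithmetic trees over a chosen terminal set:
operators {+, −, ×, ÷}, leaves feature indices or ephemeral constants
U(−1, 1) (10% of leaf draws).  Division is protected (x ÷ y = 1 when
|y| < 1e-9, the standard GP convention) and every node output is clamped to
±1e100, so evaluation is total and finite at any depth.  Initialization is
ramped half-and-half between depths 2 and min(6, max_depth); the depth cap
(default 19) is enforced by rejecting violating offspring and retaining the
parent.  Selection is size-7 tournament; each offspring is produced by
crossover, reproduction or subtree mutation with probabilities proportional
to the configured rates (defaults 1.0 / 0.2 / 0.2, i.e. 5/7, 1/7, 1/7 —
the three rates are used as a categorical weight vector since they do not
sum to 1), with elitism of one.  Default population 600 and 55 generations;
the test suite and acceptance script run a scaled 200/20 configuration,
which is already sufficient to recover a planted two-feature interaction.

Tree fitness is KNN validation accuracy with the tree's output appended as
one extra column, standardized by train-derived statistics (the same
statistics are applied to any later set — no leakage).  Constructed features
augment rather than replace the original matrix; replacement is left to the
caller by selecting columns afterwards.

## Synthetic data

The generator plants known structure so recovery can be asserted without any
external dataset:

* informative features — class-conditional Gaussians; class c has mean
  sign_j · c · effect_size · noise_sd, so adjacent classes are separated by
  `effect_size` within-class SDs (default 2.0);
* redundant features — a random informative source plus N(0, 0.3·noise_sd)
  noise, keeping source–copy correlation above 0.9;
* all remaining features — label-independent Gaussian noise;
* labels drawn from configurable class weights (imbalance honoured to
  binomial accuracy); MCAR missingness at a configurable rate, re-drawn so
  every row and feature keeps at least one observed entry.

Presets (`colon-like`, `srbct-like`, `ovarian-like`, …) reproduce the matrix
shapes of classic microarray benchmarks — features in the thousands, samples
in the tens — not their content.  Two special-purpose generators exist: a
rank-2 latent-structure matrix (U V + noise) for imputation benchmarking,
and an XOR-style interaction dataset whose label is the sign of f0·f1 (each
sign·(0.5 + U(0, 1)), plus N(0, 0.1) label noise) with 10 standard-normal
distractor features.  The distractor count was set by construction: with an
oracle product column appended, 10 distractors are what it takes for the
baseline KNN to degrade enough that the true interaction is worth ≥ 0.1
accuracy — fewer distractors leave the baseline too strong for any
constructed feature to matter.  What these generators do **not** model:
array/batch effects, heavy-tailed expression noise, correlated noise blocks,
informative missingness.  Passing recovery tests on them shows the machinery
works as specified, not that it will rank real genes correctly.

## Experiment protocol

`run_experiment` repeats (default 50): fresh stratified 70/30 split per
repeat, then the configured stages — imputation is performed once up front
(it is unsupervised and deterministic), chi-square filtering and wrapper
selection are fitted on the training side only, constructed features are
fitted on an internal split of the training side — and held-out KNN accuracy
is recorded.  Summaries report mean accuracy, max accuracy, mean feature
count and the completed-repeat count; a failed repeat is logged and
excluded.  Per-repeat seeds are derived from the master seed by a counter
and written to the JSON log together with package and library versions.

## Numerical conventions, degenerate inputs

* σ floor 1e-8 (standardization and constructed-column scaling).
* Split rounding: per-class floor(fraction·size), leftover slots by largest
  fractional part then label order; both sides of every class non-empty.
* Stratified splitting refuses singleton classes.
* An all-missing feature or an all-missing row is an error; a row
  co-observing nothing with any other row is an error.
* Chromosomes decoding to the empty set score 0 rather than raising.
* Labels are opaque strings throughout; no numeric coercion.

## Problem sizes in the test and acceptance runs

The suite runs everything at desk scale by choice: 60–200-sample matrices
with up to 1800 features, 5×5 GA grids for 40–200 generations, GP population
200 for 20 generations, 10-seed replication for stochastic claims (100 seeds
for the chi-square ranking claim), and 20 000 random trees for the totality
sweep.  These sizes make every claim recomputable in about a minute while
leaving the default (larger) library parameters untouched.
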