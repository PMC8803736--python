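# Methods

This note records the modelling assumptions, parameter choices, numerical
conventions and known limitations of the depstack pipeline, in the order
the stages run.

## Feature engineering

Every feature is a rate or proportion per user, never a raw count.  The
motivating invariant: duplicating a user's entire post stream k times must
leave their feature vector unchanged, so users with wildly different
posting volumes live on the same scale.  The property tests assert this
invariance directly.

* **POS proportions (20).**  The 20-tag inventory is a convention modelled
  on the categories a Chinese tagger distinguishes (including
  onomatopoeia, idioms and measure words); it is configurable, and any
  tagger satisfying the `Tagger` contract (deterministic, total) can be
  injected.  The shipped `LookupTagger` does whitespace splitting plus a
  token→tag map with a default tag for unknowns — sufficient for
  pre-segmented or synthetic text, not for raw Chinese, which needs a
  segmenter adapter.
* **Lexicon rates (7 emotion + 6 pronoun + 2 specific).**  Counts are
  normalized per 1000 tokens.  The denominator is the user's total token
  count; matches are exact surface-form membership tests against the
  lexicon categories.  Per-1000 rather than per-token keeps the numbers in
  a readable range; the scale cancels anyway once features are z-scored
  inside the selectors and learners.
* **Polarity proportions (3).**  Computed over polarity-annotated posts
  only; posts without an annotation are excluded from the denominator, not
  imputed.  A user with no annotated posts gets zeros and a warning.
* **Behavior (3 + 4 + 7).**  Hour bins are half-open [0,6), [6,12),
  [12,18), [18,24) local time, with no timezone conversion (posting hours
  are meaningful in the user's local clock); the week runs Monday-first.
* Degenerate users (no tokens) yield zero rows with a logged warning and
  are flagged as exclusion candidates rather than dropped, so row indices
  stay aligned with the input corpus.

Default schema: 20 + 7 + 6 + 2 + 3 textual + 3 + 11 behavior = 52
features.  The 6 pronoun classes include an "others" class alongside the
person/number classes.

## Hybrid feature selection

Three scorers, all seeing the same z-scored copy of the data:

* **RFE (wrapper):** recursive elimination with a 100-tree random forest,
  one feature per step down to a single survivor.  The elimination order
  maps linearly to weights, w_i ∝ n − rank_i + 1 (rank 1 = last
  survivor).  A linear map is the simplest monotone choice; only the
  ordering is meaningful.
* **Extra-trees (embedded):** mean impurity-decrease importances over 200
  extremely-randomized trees.
* **Mutual information (filter):** k=3 nearest-neighbor MI estimates,
  clamped at zero, each feature weighted by its share of the total.
  When every estimate is zero the weights fall back to uniform with a
  warning (no feature carries information, so no preference).

Each vector is normalized to sum 1 *before* fusion: raw RFE ranks,
impurity importances and MI values live on incommensurable scales, and
the sum W = W_r + W_e + W_m is only meaningful after normalization.  The
fused vector therefore sums to 3 (a conservation law the tests assert).

Selection drops the floor(0.2·n) lowest-weight features.  Ties are broken
by dropping the later-declared schema feature, so the retained set is
deterministic; retained features keep their original schema order.  With
the default 52-feature schema this yields 42 retained features; note that
42 retained is also consistent with a 53-feature schema under ceiling
rounding — the 52/floor combination is this package's convention.

MI estimates at noise level are sparse: on data independent of the label,
a single feature often carries all of the (tiny) MI mass in any one
sample, so near-uniformity of MI weights is a property of the seed
average, not of individual runs.

## Stacking ensemble

* **Base learners** (canonical order SVM, KNN, NB, LG1, LG2): RBF-kernel
  SVM with Platt probability outputs; distance-weighted KNN; *Gaussian*
  naive Bayes — the features after selection are continuous rates, which
  rules out the multinomial variant; L1- and L2-penalized logistic
  regression (liblinear).  Each base learner runs inside a pipeline that
  z-scores features using statistics of its own training fold only.
* **Out-of-fold construction:** K=5 stratified folds (configurable); for
  each learner and fold, the model fitted on the other four folds predicts
  the held-out fold's positive-class probability.  No meta-feature for
  sample i is ever produced by a model that saw i; the test suite certifies
  this with a memorizing 1-NN oracle whose resubstitution accuracy is 100%
  but whose out-of-fold column cannot be.
* **Meta-learner:** binary logistic regression with a fixed L2 penalty
  (C=1) on the N×5 probability matrix — deliberately low-capacity to avoid
  overfitting five-dimensional inputs.
* **Scoring new data:** each learner's meta-feature is the mean of its K
  fold models' probabilities; `refit_full=True` switches to a single model
  refitted on all training data.  Averaging is the default because it
  reuses exactly the models that defined the meta-feature distribution the
  meta-learner saw.
* **Decision rule:** label 1 (patient) iff meta probability ≥ threshold
  (default 0.5; the boundary case is positive by convention).
* **Determinism:** fold assignment can be keyed to sample ids, making the
  fit invariant to row permutations of the training set.
* Grid search maximizes mean stratified-CV accuracy over a deliberately
  small grid, scoring every point on the same folds; ties go to the first
  point in canonical grid order.  Fold counts auto-reduce (with a warning)
  when the smallest class cannot fill them.

## Class imbalance

SMOTE with k=5 minority neighbors (the method's canonical default) and a
1:1 target ratio: each synthetic sample is x_i + u·(x_z − x_i) with
u ~ Uniform(0,1) and x_z one of the k nearest minority neighbors of a
uniformly drawn minority point x_i, so synthetic points lie on minority
segments, inside the minority convex hull.  Balancing is applied strictly
after the train/test split, on training data only — oversampling before
the split would leak interpolated copies of test-set neighborhoods into
training.  Requesting k ≥ minority count is an error suggesting a
smaller k.

A measured caveat: on the default synthetic scenario, SMOTE reliably
raises minority recall for the regularized logistic learner, while for
the full stacking model the mean change over 20 seeds was −0.01 (within
seed noise) — fold-probability averaging already smooths the decision
boundary that balancing would otherwise shift.

## Evaluation protocol

* 75/25 stratified split (per-class test proportions within one sample of
  the target), then 10-fold stratified CV for model selection.
* Metrics from the confusion matrix with positive class = depressed (=1),
  configurable.  With no positive predictions, precision is reported as 0
  with a warning rather than NaN.  Report rounding is half-even at 4
  decimals; accuracy improvements are absolute percentage points,
  100·(after − before), rounded to 2 decimals.
* The CV score matrix uses the same folds for every method — the paired
  design Friedman and Wilcoxon require.  Friedman uses tie-corrected
  mid-ranks (two-method matrices are computed directly, since the scipy
  routine requires three); identical columns short-circuit to statistic 0.
  Wilcoxon drops zero differences, uses the exact null for ≤25 nonzero
  tie-free differences and the tie-corrected normal approximation
  otherwise; all-zero difference pairs report p = 1 with a warning.
  Fold-level pairing (rather than repetition-level) is the convention
  chosen here.

## Synthetic data

Two generation paths share one `ScenarioConfig`, both pure functions of
(config, seed):

* The **corpus path** emulates the raw data the featurizer consumes:
  tokens drawn from class-dependent mixtures over bundled synthetic
  lexicons (depressed users draw negation ×3, first-person-singular ×2,
  sadness ×2.5, happiness/liking ×0.5), timestamps from class-dependent
  hour-bin distributions (depressed users post 35% vs 10% in the 00–06
  bin), habit flags and polarity from class-dependent rates, post counts
  log-normal (median 30).  Users within a class are heterogeneous:
  per-user lognormal random effects (SD 0.5) on mixture weights and
  Dirichlet/Beta draws (concentration 8) around the class means for time,
  polarity and flag rates.  Without that overdispersion a user's ~450
  aggregated tokens would pin down their class almost exactly and every
  classifier would sit at 100%.
* The **table path** emits the 52-feature table directly — exchangeable
  Gaussian noise with a standardized mean shift (default effect size 1.5
  on 5 named features) for the depressed class — and is used wherever
  exact control of the signal is needed (selector recovery, null
  calibration, effect-size response).
* `ScenarioConfig().null()` removes all class differences; the pipeline's
  held-out accuracy then matches the majority prior (320/450 ≈ 0.711)
  within 0.05 — the type-I-error-style calibration check.

What passing tests on this generator do **not** show: real corpora have
segmentation/tagging errors, topic drift, label noise, missing metadata
and much lower class separability (the default synthetic scenario yields
held-out accuracies around 0.98–1.0, well above what real social-media
data supports).  The generator validates the machinery — leakage
freedom, calibration, monotone response to signal — not real-world
accuracy levels.

## Problem sizes used by the test suite

Stochastic suites run at the default study conditions (450 users, 52
features) with seed counts chosen for stable Monte-Carlo averages:
planted-feature recovery 25 seeds, null calibration and
stacking-advantage 20 seeds each, effect-size monotonicity 10 seeds per
level, MI null-uniformity 30 seeds.  The full suite completes in about
five minutes on one CPU; `scripts/acceptance.py` in about ten seconds.

## Known limitations

* No real Chinese segmentation or sentiment scoring is bundled; both are
  adapter points (`Tagger`, the polarity column).
* The 20-tag inventory, the per-1000 rate denominator, the 52-feature
  schema and the floor/tie-break conventions in selection are package
  conventions where the underlying study design left details unstated;
  each is configurable.
* Positive-class choice affects precision/recall asymmetrically under
  imbalance; the default (depressed = positive) is a flag away from its
  opposite.
* Wilcoxon p-values are reported uncorrected for multiple comparisons.
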