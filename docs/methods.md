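# Methods

## The procedure

The package implements wrapper-based backward feature elimination for a
three-class survivorship outcome (*alive*, *dead*, *alive but follow-up
< 24 months*) on an 18-parameter allo-HSCT cohort, orchestrated over five
tree-based classification meta-algorithms.

Given a starting pattern of `n` features, each round trains and scores one
model per leave-one-out candidate and removes the feature whose exclusion
leaves the **highest** selection statistic — the feature the models miss
least.  (The opposite rule, removing the feature whose exclusion hurts the
most, destroys the most informative feature first; it is available as
`elimination="literal"` purely for auditing.)  Run to a single remaining
feature, the sweep scores `n(n+1)/2` distinct patterns, versus
`2(2^n − 1)` for the doubled exhaustive subset enumeration it replaces.
The greedy path explores a strict subset of all patterns, so its optimum
can never exceed the exhaustive optimum; on noise-free data where a small
sufficient subset exists the two coincide (asserted in the tests for
`n = 4` against a brute-force oracle over all 15 subsets).

Pattern scoring uses repeated random splits: `n_splits` stratified 80/20
train/test partitions crossed with `n_seeds` model seeds, all derived as
consecutive integers from a master seed.  The train size is
`floor(0.8 N)` — 451/113 for `N = 564`.  Splits are stratified by outcome
by default because the third class is a minority and unstratified splits
can occasionally leave a class out of the training partition (which is a
hard error).  The **selection statistic** comparing patterns is the mean
test accuracy over the grid; the single best evaluation (`max`) is also
retained and can be selected instead, since a best-model readout is a
common alternative convention.  Accuracy, macro precision, macro recall
and macro F1 plus the full confusion matrix are recorded per evaluation;
macro averaging is used because the classes are imbalanced.

Optimal-pattern selection takes the argmax of the selection statistic over
the baseline and every step's outgoing pattern; ties break toward fewer
features, then earlier steps.  Feature ranking ("rank method: loo-drop"):
features inside the optimal pattern are ordered by the drop in the
statistic when each is excluded at the optimal step (these leave-one-out
scores already exist in the trajectory whenever the sweep continued past
the optimum); features outside it are appended in reverse elimination
order.  The ranking rule for the in-pattern features is an interpretation
— several conventions exist — and is therefore labelled in every output.

## Learners and hyperparameters

| id | implementation | frozen defaults |
|----|----------------|-----------------|
| `extra_trees` | `ExtraTreesClassifier` | 100 trees, sqrt features |
| `decision_tree` | `DecisionTreeClassifier` | gini, unbounded depth |
| `cat_boost` | `HistGradientBoostingClassifier` with native categorical splits | 100 iterations, lr 0.1 |
| `gradient_boosting` | `GradientBoostingClassifier` | 100 stages, lr 0.1, depth 3 |
| `ada_boost` | `AdaBoostClassifier` | 100 stumps, lr 1.0 |

Hyperparameters are frozen in `HYPER_DEFAULTS` (and overridable per run)
rather than left to library defaults, so results do not drift across
scikit-learn versions.  The `cat_boost` slot is the categorical-aware
histogram-gradient-boosting family: categorical columns are declared to
the learner and split natively rather than treated as ordinal.  Features
are otherwise passed through unscaled — ordinal integer codes for
categorical parameters, raw clinical units for continuous ones — because
all five learners are trees and scale-invariant.

## Synthetic cohorts

The generator emulates the marginal structure of a 564-patient adult
allo-HSCT cohort:

- **Categorical features** are drawn independently with the cohort's
  published frequencies (e.g. 60.1% male; 65.1% myeloid disease; 1.8%
  secondary malignancy).
- **Continuous features** (age, day-2 platelets/LDH/creatinine, CD34+
  dose) follow log-normals truncated to the observed ranges, with the
  location parameter solved numerically so the *truncated* median equals
  the published median exactly (the observed medians sit far below the
  range midpoints, implying right skew).  The log-scale dispersion defaults
  to one sixth of the log-range; age uses σ = 0.4 to give the wider spread
  typical of adult transplant cohorts (IQR roughly mid-30s to 60).
- **Outcome** is drawn from a multinomial logit on within-cohort
  standardised signal features, with *alive* as the reference class.  The
  default signal is planted on the seven clinically selected predictors
  (day-2 creatinine, age, aGvHD, disease phase, cGvHD, disease group,
  platelet engraftment) with strong monotone effects (|weights| 1.5–3 on
  the standardised scale) — directions are testing conventions, not
  clinical claims.  Intercepts target roughly 55/30/15 class shares;
  with the strong default coefficients the realised shares shift toward
  a more even mix, which keeps all three classes trainable.  Optional
  Gaussian logit noise (`noise_scale`) and a deterministic argmax mode
  (`deterministic=True`, the noise-free variant used by the recovery
  tests) are provided.
- **Cell floor.**  The real cohort has at least 17 patients in each of the
  12 outcome × gender × age (≤40 / >40) cells.  The generator enforces
  this by whole-table outcome redraws first; because the smallest
  gender × age stratum makes its minority-outcome cell improbable under
  the default marginals, pure rejection does not terminate, so after a
  bounded number of redraws the generator repairs deficits directly:
  within the deficient stratum it reassigns the records with the highest
  model probability for the deficient outcome, never drawing a donor cell
  below the floor.  This relabels a small number of records (~1–2% at
  N = 564) relative to the planted signal, and fails loudly if a stratum
  is smaller than three times the floor.

All randomness flows through one `numpy.random.default_rng(seed)` (PCG64);
identical arguments give byte-identical tables.  Continuous values are
canonicalised to six significant digits at generation and at load, which
makes CSV write/read round trips exact identities.

What the generator does **not** emulate: correlations between input
features (only marginals are known), survival times, or any patient-level
structure of the real database.  Passing the recovery tests therefore
shows that the elimination machinery finds a planted conditional
dependency at realistic marginals and sample size — not that the seven
predictors are recoverable from real transplant data.

## Problem sizes in the test suite

Simulation-backed checks are scaled to desk size: the planted-signal
recovery simulation runs Extra Trees with 25-tree forests under a
2-split × 2-seed grid on 564-record cohorts over 20 master seeds; the
trajectory-ledger checks use a single CART tree with a 2 × 2 grid on
300-record cohorts for 2–8 features; the greedy-vs-oracle check uses
4 features and all 15 subsets.  The full 25 × 101 grid is available
everywhere via `SplitProtocol` or the CLI's `--paper-protocol`.

## Numerical choices and degenerate inputs

- Candidate-score ties during elimination break by schema order of the
  excluded feature; optimal-pattern ties break toward fewer features.
  Both rules are deterministic, so a whole run is a pure function of
  (table, protocol, hyperparameters, algorithm).
- Pattern scores are memoised in memory keyed by (table, algorithm,
  pattern, protocol, hyperparameters); the greedy path never revisits a
  pattern, but ranking and ensemble sweeps do.
- Tables must have ≥ 2 records and ≥ 2 outcome classes before training;
  single-class training partitions raise instead of silently fitting.
- Rows with missing values, out-of-level codes or out-of-range continuous
  values are rejected at load with the row index; no imputation is
  attempted.
- The outcome is a flat 3-class label; survival is deliberately not
  modelled as a time-to-event process, and no censoring-aware metrics
  (C-index etc.) are computed.

## Known limitations

- Greedy elimination is myopic: on noisy data it can discard a feature
  whose value only shows in combination with features removed later.
- The ranking of in-pattern features depends on the leave-one-out drop at
  a single step and inherits that step's sampling noise.
- With few evaluations per pattern (small grids) the optimal pattern can
  carry one or two spurious features whose removal appeared harmful by
  chance; larger grids tighten this at linear cost.
- The doubled exhaustive pattern count `2(2^n − 1)` is implemented as the
  conventional accounting figure only; nothing in the package enumerates
  subsets at that scale (exhaustive search is guarded above 20 features).
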