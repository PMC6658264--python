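# Methods

This note documents the models, procedures, and design choices behind
`stresscast`: what is computed, under which assumptions, with which defaults,
and what the synthetic experiments do and do not demonstrate.

## Daily activity features from minute traces

A participant-day is 1440 per-minute intensity codes (0 non-wear, 1
sedentary, 2 light, 3 moderate, 4 vigorous). A day is analyzable only with at
least 10 hours of registered wear; "fewer than 10 hours" is excluded, so
exactly 600 wear minutes is valid — the boundary is tested exactly.

An exercise bout is any consecutive 30-minute window containing at least 24
minutes of moderate-to-vigorous activity (MVPA); the analogous 10-minute/8-
minute convention is computed alongside. Overlapping qualifying windows are
resolved greedily: scanning left to right, the earliest qualifying start
claims its window and scanning resumes after the window's end. This
convention is deterministic and is verified against an exhaustive oracle that
scores all 1411 (or 1431) windows independently. One consequence worth
knowing: an isolated mid-day block of 30 MVPA minutes is claimed by the
window that starts six minutes before the block (the earliest window holding
24 MVPA minutes), so `exercise_min_in_bouts_30` counts 24 minutes for it, not
30. Bouts never span midnight, because traces are per-day.

"Active hours" is the number of clock hours (0–23) containing at least 10
minutes at light intensity or higher. MVPA means moderate or vigorous; light
does not count toward bouts.

## Lagged samples, splits, thresholds

A prediction sample for day *t* uses weather at lags 0–3 (min/max/average
temperature, temperature range, daylight minutes, precipitation), stress
ratings at lags 1–3, daily activity features at lags 1–3, a one-hot day of
week, and — in nomothetic mode only — the static person covariates age, sex,
height, and weight. Same-day weather is included because weather on the
rating day is plainly observable at prediction time; same-day activity is
excluded to avoid ambiguity about end-of-day timing. Day *t* is eligible only
if its own rating and all three lagged ratings are observed and the three
lagged days pass the wear rule (a stress-only eligibility mode is available).
Missing ratings are never imputed; affected windows are excluded.

Splits are chronological per person: the first ⌈p·n⌉ eligible samples train,
the rest test, for p ∈ {0.30, …, 0.80}. Persons without at least one training
and one test sample are dropped from evaluation.

The continuous prediction is binarized against the person's *median
training-set rating*: class 1 iff strictly above the median, so a rating
equal to the median is class 0 (the tie rule is configurable). This makes
"high stress" person-relative and partially absorbs restricted range use.
Every fitted statistic — per-person medians, feature means and standard
deviations — is computed from training rows only and records the training
date range it was fitted on, so leakage is checkable structurally.

## Model families

All families share one contract: a continuous stress prediction per sample,
plus a family-specific attribution hook.

* **baseline** — predicts each person's training median for every day. Under
  the tie rule its binarized prediction is always class 0, so its accuracy
  equals the test frequency of that class and its AUC is 0.5; this anchors
  the comparisons.
* **elastic net, decision tree, random forest, gradient-boosted trees** —
  scikit-learn estimators behind the module surface. Reduction identities are
  tested: a 1-tree forest without bootstrap or feature subsampling equals the
  plain tree, and a 1-stage unit-shrinkage boosted model equals the plain
  tree.
* **MLP and RNN** — explicit-weight numpy networks (rectifier hidden units,
  identity output), because relevance propagation traverses the weight
  matrices directly and all biases can be locked to exactly zero. Training is
  mini-batch Adam on squared error, inverted dropout on hidden units
  (training only, default rate 0.2), early stopping on the chronological tail
  of the training rows (MAE, patience 25), gradient clipping for the RNN.
  Defaults: one hidden layer of 32 units (MLP), hidden size 16 (RNN). The RNN
  unrolls over the lag days oldest-to-newest — each step carries that lag's
  stress, weather, and activity variables — and concatenates the final hidden
  state with the static inputs (lag-0 weather, day of week, person
  covariates); this layout is recorded in model metadata. A zero-hidden-layer
  network reproduces least squares to 1e-3 on clean data (tested), and
  zero-bias rectifier networks are positively homogeneous: f(c·x) = c·f(x)
  for c > 0.

Hyperparameter search is an exhaustive grid with 3-fold cross-validation
minimizing mean absolute error. Folds are contiguous chronological blocks to
respect the time-series structure; ties go to the earliest grid point, and
grids are ordered simplest/most-regularized first. The training loss is
squared error; MAE is the selection criterion.

## Attribution

**LRP (epsilon rule).** Relevance flows backward from the output:
R_i = Σ_j z_ij/(z_j + ε·sign(z_j)) · R_j with z_ij = a_i·w_ij, ε = 1e-9 by
default. With all biases locked to zero the propagation is conservative —
|Σ relevances − output| stays below 1e-6 across 1000 random networks (tested)
— and for a linear network it equals w_i·x_i exactly, which is the Shapley
value at a zero baseline. Free-bias networks are propagated too, but biases
absorb relevance and conservation is not promised. For the RNN the same rule
runs through the unrolled graph (output → final hidden state and statics →
backward through time), preserving conservation.

**Shapley oracle.** An exact enumerator over all 2^d feature subsets (d ≤ 12)
with excluded features set to the baseline (default zero = the training mean
after standardization). On monotone rectifier networks with a live output,
LRP signs match Shapley signs exactly and the orderings agree in nearly every
case; occasional near-tie rank swaps are expected because LRP approximates
rather than equals Shapley. A fully dead network (all hidden units inactive,
output 0) has all-zero relevances while Shapley values need not be zero —
nothing flows backward through a zero output.

**Trees.** Feature importance is the normalized total impurity decrease. For
regression trees the impurity is variance, so the commonly used name "Gini
importance" is realized as variance-impurity decrease (Gini impurity is
undefined for continuous targets). Rankings aggregate per-person top-5 lists
(ties broken by canonical feature order; zero-importance features never make
the list), and the LRP analogue takes each person's median absolute relevance
per input. A per-person profile from a pooled model's relevances restricted
to the person's highest-stress days is available (`top_stress_fraction`,
default 0.25 — the fraction is a free design choice).

**Force reports** order one prediction's signed relevances into upward and
downward groups; the entries sum to the model output.

## Evaluation

AUC is the probability that a random positive is ranked above a random
negative, computed via mid-ranks so ties count one half; it is verified
against the O(n²) pairwise definition. Pooled AUC scores are person-centred
(prediction minus the person's threshold) so that ranking across persons with
different medians is meaningful. Precision, recall, F1, and accuracy follow
the standard confusion-matrix definitions with the positive class "above the
person's median". Undefined metrics (single-class test sets, zero predicted
positives) propagate as missing values — never coerced to 0 or 0.5.

The sweep reports pooled (sample-level) metrics — one row per model ×
training proportion × subgroup — mirroring a single results row per model;
subgroup rows recompute the same metrics restricted to persons with more than
50 or more than 100 valid days. Person-averaged diagnostics can be derived
from the same frames. Cells with no qualifying test samples are emitted
explicitly with missing metrics.

**Warm start.** For one person, both a pooled and a personal model are
monitored day by day. Each model is weighted by the inverse of its rolling
MAE over its last *w* scored days (default window 14; uniform weights until
both have *w* scores), the continuous predictions are blended, and the blend
is binarized. A hard-switch variant (all weight to the currently better
model) is available. The inverse-error weighting rule is this package's
concretization of the idea of continuously adjusting each model's
contribution as evidence accumulates.

## The synthetic cohort generator

The generator is the package's study population. Stress is latent Gaussian
AR(1) around a person baseline with additive weather and exercise terms,
rounded and clamped to 0..ceiling, where the ceiling (3–10) reproduces
restricted range use. Missingness is logistic in the *latent* (not observed)
stress — logit(miss_base) + slope·latent — so missing days genuinely hide
higher stress without circularity; with slope > 0 the marginal missing rate
exceeds `miss_base`, which the defaults anticipate. Weather is sinusoidal
(temperature peaking late July, daylight at the June solstice, in °F and
inches), with zero-inflated exponential precipitation. Exercise days follow a
two-state Markov chain with stationary rate `exercise_rate/7` and optional
persistence (multi-day streaks). Non-wear days truncate wear below 10 hours
(leaving over 14 hours of non-wear). Persons whose observed ratings have
fewer than 10 responses or variance below 0.05 are excluded and re-drawn,
mirroring the exclusion of near-constant responders. All randomness descends
from one root seed through named substreams; a (config, seed) pair yields
byte-identical CSVs.

Defaults: 77 persons over a 365-day window with participation 60–365 days,
baselines U(2,5), AR coefficients U(0.1,0.5), sign-varying temperature
effects up to 0.12 points/°F and daylight effects up to 0.006 points/minute,
exercise effects U(−0.8,0) points/bout, noise SD U(0.8,1.5), missingness base
rate U(0.05,0.2) with MNAR slope U(0,0.3), non-wear probability U(0,0.1).
These are desk-scale choices for a plausible cohort of intermittently
exercising urban adults, not a fit to any real sample (no such data are
available).

Two named regimes encode designed experimental conditions:

* **`high_heterogeneity`** (the crossover condition): 60 persons, mostly
  short records (30–80 days) with a fixed 15% of long records (180–240 days,
  matching the minority of long-record participants such cohorts actually
  have); temperature variation mostly day-to-day noise (SD 10°F, seasonal
  amplitude 5°F) so lagged stress cannot proxy the person-specific
  temperature response; strong sign-varying temperature effects
  (0.11–0.16 points/°F); a consistent, pooled-learnable exercise effect
  (−1.2 to −0.5 points/bout) and moderate AR (0.25–0.45). In this regime the
  pooled elastic net leads the per-person trees (leaf size 12, the
  constrained-complexity setting for N-of-1 trees) over all persons at
  training proportion 0.30, while the trees lead for the >100-valid-day
  subgroup at proportion 0.80 — the crossover holds in roughly nine of ten
  replicate cohorts (17 of the 20 fixed seeds in the test suite).
* **`dominant_driver`** (the recovery condition): long, low-missingness
  records where each person's stress variance is dominated by one driver —
  temperature, daylight, or exercise. Its weather is mostly non-seasonal
  because seasonal temperature and daylight are collinear and the drivers
  would not be identifiable from each other. Exercise-driver persons exercise
  in multi-day streaks (persistence 0.65–0.8) so the lagged activity features
  carry the same-day exercise signal that actually drives their stress; the
  occasional residual confusion attributes an exercise driver to the lag-1
  stress rating, which is causally downstream of it. Per-person tree
  importances recover the driver family for well over 80% of persons with
  ≥100 valid days.

What passing these synthetic experiments shows: the pipeline's machinery —
eligibility, splits, thresholds, training, attribution, aggregation — behaves
as specified, and the qualitative phenomena (crossover, MNAR direction,
driver recovery) emerge when the generative structure contains them. What it
does not show: that real stress dynamics follow an AR(1) with additive
effects, that real missingness is logistic in latent stress, or that the
specific accuracies reported on synthetic cohorts transfer to any real
population. Minute traces are schematic (sleep blocks, scattered light
activity, inserted bouts), with no physiological realism.

## Numerical choices and degenerate inputs

* LRP ε = 1e-9; ε = 0 with a zero pre-activation raises rather than divides
  by zero. sign(0) is taken as +1 in the denominator guard.
* Standardization uses training-row means/SDs; zero-SD columns pass through
  centred rather than dividing by zero.
* Median thresholds use the standard even-count midpoint convention.
* Constant-target trees are single leaves with all-zero importances.
* Elastic net with alpha = 0 falls back to ordinary least squares.
* Network training aborts with a clear error if the loss becomes non-finite;
  Adam plus gradient clipping (RNN) keeps the default settings stable.
* Grid-search ties resolve to the earliest (simplest) grid point,
  deterministically.
* Problem sizes in the test suite and acceptance script (cohorts of 25–60
  persons, 10–20 replicate seeds, 1000-network/1000-trace oracle checks) are
  chosen so the whole battery runs in a few minutes on one CPU while leaving
  the Monte-Carlo margins comfortable.

## Known limitations

* The generative model is intentionally minimal; it contains no within-day
  dynamics, no anticipatory ratings, and no feedback from stress to exercise
  behaviour.
* The RNN input layout (which variables are steps vs statics) is one
  reasonable choice among several; it is recorded in metadata rather than
  asserted as canonical.
* Pooled AUC across persons requires the person-centred score described
  above; raw pooled scores would conflate between-person level differences
  with discrimination.
* LRP on free-bias networks leaks relevance into the biases; conservation
  holds only in zero-bias mode.
* The warm-start rule weights by regression error (MAE) while the end metric
  is classification accuracy; when the two disagree about which model is
  better, the blend tracks the MAE judgement.
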