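# Methods

`plgarelease` implements a two-stage, stacked classification–regression
framework for predicting in vitro drug release from PLGA (poly(lactic-co-
glycolic acid)) microspheres, together with the validation and
interpretation machinery such a study needs and a synthetic-data generator
that stands in for the curated literature dataset the method is designed
for. This note records the model, its assumptions, the tunable parameters,
and the design choices made where the design was genuinely open.

## The two-stage model

**Stage 1 — early-release classification.** A formulation is a
*slow-release system* when its cumulative release at day 3 (72 h) is at
most 0.20 (fraction scale; the boundary is inclusive). When no observation
falls exactly on day 3 the release there is linearly interpolated between
the bracketing observations — the weakest-assumption estimator given no
guarantees about sampling grids. The classifier is an L2-regularized
logistic regression (lbfgs) on the 13 formulation descriptors (time
excluded), with predictors standardized using training-fold statistics
only. The regularization strength 0.5 is interpreted in the scikit-learn
`C` convention (smaller = stronger penalty); the alternative reading
(penalty weight λ, `C = 1/λ`) is available behind the
`regularization_convention` config key.

**Stacking.** Out-of-fold (OOF) probabilities from a seeded group 10-fold
pass — grouped by formulation index, so the model scoring a formulation
never saw any of its rows — become the `predicted_slow_release`
meta-feature. At deployment time the meta-feature comes instead from the
stage-1 model refit on all formulations: the standard stacking asymmetry
(train on OOF, predict with the full model).

**Stage 2 — full release regression.** One row per (formulation, time
point): 13 descriptors + meta-feature + time → cumulative release fraction.
Six algorithms are compared (LR, SVR, DT, RF, XGBoost, LightGBM) under
seeded group 5-fold cross-validation grouped by formulation; per fold we
report MAE and Pearson r, aggregate as mean (SD) across folds, and select
the lowest mean MAE (ties: higher mean r, then fixed name order).
Predictions are clipped to [0, 1]; no monotonicity across time is enforced,
so the two stages can disagree for out-of-distribution queries.

**Stacking hygiene.** Two modes are implemented. `global` (default): a
single global OOF pass feeds every outer regression fold. This lets a test
formulation's own label influence its meta-feature through the global
pass — a mild leak, but it is the construction the headline numbers of this
kind of study use. `nested` (strict): stage 1 is refit inside each outer
training fold and the test formulations are scored by that refit, making
the meta-feature leakage-free. The mode is a single switch on
`groupkfold_evaluate`.

## Validation schemes

* **Repeated group resampling** (uncertainty analysis): 30 independent
  `GroupShuffleSplit` draws at test fraction 0.2 (the fraction is not
  dictated by the protocol; 0.2 is the package default and configurable),
  grouped by formulation. Reported as mean (SD) over repeats.
* **Leave-one-drug-out (LODO):** every formulation of one drug held out in
  turn; deterministic apart from model seeds. Per-drug Pearson r is left
  undefined (NaN, logged) when a drug's observed releases are constant
  rather than coerced to a number.

## Metrics

Classification: accuracy, precision, recall and F1 from the confusion
matrix with slow-release as the positive class; zero-denominator metrics
are NaN with a warning, never silently 0. Regression: MAE on the fraction
scale and sample Pearson r; r per fold, then averaged.

## Feature attribution

All attributions satisfy local accuracy (base value + per-feature
attributions = model output per row) and are computed on the model's
natural output scale — log-odds for the classifier, raw regression output
for stage 2:

* logistic model: closed-form linear SHAP,
  `phi_j = w_j (z_j − mean z_j)` over the standardized background;
* XGBoost / LightGBM: the libraries' exact TreeSHAP
  (`pred_contribs` / `pred_contrib`);
* sklearn DT/RF: an in-package path-dependent TreeSHAP (validated against
  brute-force coalition enumeration in the tests);
* other families (SVR): seeded permutation-sampling Shapley against a
  background sample. Allocation is approximate, but additivity still holds
  exactly because each permutation's marginal contributions telescope; the
  explained-row count is capped (default 32) because each row costs
  `permutations × features × background` model calls.

Because SHAP values center on the background, their plain mean carries no
direction; the *effect direction* of a feature is therefore measured as the
covariance between feature value and attribution across rows
(`AttributionSet.effect_direction`).

Spearman screening uses average-rank tie handling; a constant column yields
NaN against every partner. The matrix is exported as CSV and heatmap.

## Synthetic data generator

The generator emulates the structure of a curated PLGA release dataset; it
is the test bed, not a physical model of PLGA hydrolysis.

Noiseless kinetics are biphasic — a first-order burst of the
surface-associated fraction followed by a Weibull degradation phase:

    F(t) = b (1 − e^(−t/τ_b)) + (1 − b)(1 − e^(−(t/τ_d)^k))

with burst fraction `b ~ U(0, 0.20)`, burst timescale
`τ_b ~ U(0.2, 1.0)` d, shape `k ~ U(0.8, 1.6)`, and a degradation
timescale carrying the planted effects on the log scale,

    τ_d = exp(β₀ + Σ_f β_f z_f + u_drug),  clipped to [2, 45] d,

where `z_f` are per-table standardized descriptors, the signed defaults are
drug MW +0.45, polymer MW +0.40, polymer concentration +0.35, acid end-cap
−0.30, agitation −0.25, drug TPSA −0.15 (signs chosen to match the known
physical directions: heavier drugs and polymers and denser matrices slow
release; acid-terminated chains and stronger agitation speed it up), and
`u_drug ~ N(0, 0.35)` is a per-drug random effect shared by a drug's
formulations but not predictable from the descriptors. The random effect is
what makes leave-one-drug-out genuinely harder than formulation-grouped CV,
as observed on real data. `β₀ = log(18.5 d)` sets the slow/fast label split
near the 132/182 balance of the reference study.

Structure of the feature table: 89 drugs, 1 + Poisson(2.6) formulations per
drug capped at 8 (~321 rows); drug-level descriptors (MW log-uniform on
200–4500 Da, TPSA positively coupled to MW, logP ~ N(2, 2)) shared within a
drug; formulation-level descriptors drawn from plausible ranges (polymer MW
5–100 kDa, D/M 0.05–0.5, EE skewed high on 0.3–0.99, polymer concentration
0.02–0.35, agitation from {50, 75, 100, 150, 200} rpm, acid end-cap
Bernoulli(½)). DLC follows the encapsulation mass balance
`DLC = EE·DM/(1 + EE·DM)` up to 2% relative noise, planting the strong
DLC↔D/M rank dependency (|ρ| ≈ 0.96 at n ≈ 320) that the screening stage
must flag.

Profiles: 10–15 roughly log-spaced points bracketing day 3, with the study
length coupled to the formulation's timescale (`T = τ_d·U(1.2, 2.0)`
clipped to 20–60 d) — emulating the curation reality that studies run until
release plateaus. Measurement noise is additive Gaussian on the fraction
scale (SD 0.02) followed by an isotonic clip (running maximum, bounded to
[0, 1]) so every stored curve remains a valid cumulative release. The
inclusion filters (span ≥ 72 h, final release > 60%) are applied inside
`generate_dataset`, as they would be during curation.

**What the generator does not emulate:** real marginal feature
distributions (the ranges are plausible defaults, not estimates), abrupt
mid-phase release accelerations, lag phases longer than the burst
timescale, assay-medium effects (pH, surfactants), or correlated
measurement error along a profile. Passing recovery tests therefore show
that the pipeline recovers planted structure of this smooth biphasic kind —
not that it attains any particular accuracy on the external curated
dataset, whose headline numbers require that dataset itself.

## Numerical choices and degenerate inputs

* Day-3 boundary inclusive; classification threshold 0.5 inclusive
  (probability 0.5 → slow).
* Group fold assignment: groups sorted, seeded shuffle, round-robin deal —
  reproducible from the seed and independent of row order.
* A training fold collapsing to one class falls back to predicting the
  training prior, with a warning (a crash would make grouped CV fragile on
  small strata).
* Zero-variance predictor columns are scaled to zero deviation and warned
  about rather than dropped, keeping the coefficient vector aligned with
  the schema.
* Release values up to 1.1 are tolerated on input (measurement overshoot)
  and clipped to [0, 1]; DLC inconsistent with the encapsulation mass
  balance beyond 10% relative is excluded with a reason code, as are rows
  missing any mandatory descriptor (no imputation).
* Ranges given as intervals in vendor specifications (e.g., polymer MW
  "24–38 kDa") are encoded as midpoints. The LA/GA ratio is encoded as the
  numeric LA:GA molar ratio (50:50 → 1.0, 75:25 → 3.0).
* DLC/EE are stored as fractions in [0, 1], release as fractions (so MAE
  is on the fraction scale).
* External queries with descriptors outside the training range predict
  with an `ExtrapolationWarning` rather than refusing.

## Problem sizes

The default study is the generator's default configuration (~320
formulations over 89 drugs, ~4000 release points). The test suite reuses
one shared instance of this study for the expensive analyses (6-algorithm
grouped CV, 30-repeat resampling, LODO over 89 drugs) and a 15-drug
configuration for unit-level checks.

## Known limitations

* The stage-2 hyperparameters are package defaults (500 trees, depth 6,
  learning rate 0.05 for the boosters; RBF SVR on standardized inputs),
  versioned in `defaults.yaml`; no tuning framework is included.
* `global`-mode stacking carries the mild OOF label leak described above;
  use `nested` mode when strict leakage-freedom matters more than
  comparability.
* Attribution for kernel models is sampling-based; only its additivity,
  not its allocation, is exact.
* The framework predicts release under the assay conditions encoded in the
  descriptors; it does not model dissolution-medium chemistry or in vivo
  kinetics.
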