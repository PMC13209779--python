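# plgarelease

Two-stage machine learning for predicting in vitro drug release from PLGA
(poly(lactic-co-glycolic acid)) microspheres — the workhorse of long-acting
injectable (LAI) depot formulations. The package is aimed at formulation
scientists and ML practitioners who want to estimate a release profile from
formulation descriptors instead of running weeks of dialysis assays, and at
anyone who needs the grouped-validation and attribution machinery such
tabular pharmaceutical studies require.

## The model

Early-stage behavior shapes the whole release curve, so prediction is
staged:

1. **Slow-release classification.** A formulation is *slow-release* when
   its cumulative release at day 3 satisfies F(3 d) ≤ 0.20 (linear
   interpolation between bracketing observations). An L2-regularized
   logistic regression (C = 0.5, lbfgs) on 13 descriptors — polymer MW,
   LA/GA ratio, initial D/M ratio, drug MW/TPSA/logP, particle size, DLC,
   EE, solubility-enhancer concentration, agitation rate, polymer
   concentration, acid end-cap — predicts P(slow).
2. **Stacked release regression.** Out-of-fold probabilities from a group
   10-fold pass (grouped by formulation, so no formulation is scored by a
   model that saw it) join the descriptors and time as features of a
   per-timepoint regression of cumulative release F(t) ∈ [0, 1]. Six
   algorithms (LR, SVR, DT, RF, XGBoost, LightGBM) are compared under
   group 5-fold CV by MAE = Σ|ŷᵢ − yᵢ|/n and Pearson r; the lowest mean
   MAE is selected.

Robustness is probed by 30-repeat group resampling and leave-one-drug-out
(LODO) cross-validation; interpretation by exact SHAP attributions (linear
closed form for the classifier, TreeSHAP for the tree ensembles) and
|Spearman ρ| collinearity screening. A synthetic-data generator with
planted, signed feature effects and known kinetic ground truth
(burst + Weibull: F(t) = b(1 − e^(−t/τ_b)) + (1 − b)(1 − e^(−(t/τ_d)^k)))
makes the whole pipeline testable without any external data. See
`docs/methods.md` for the full model account and `docs/dataset_schema.json`
for the CSV contracts.

## Worked example

```python
import plgarelease as pr

# a synthetic study with the structure the method assumes:
# ~320 formulations over 89 drugs, 10-15 timepoints each
ds = pr.generate_dataset(seed=1)

# stage 1: out-of-fold slow-release probabilities and their quality
oof = pr.oof_slow_release_probabilities(ds.features, k=10, seed=1)
report = pr.confusion_and_metrics(
    pr.classify(oof["predicted_slow_release"]), ds.features["slow_release"])
print(f"stage 1: accuracy {report.accuracy:.3f}, F1 {report.f1:.3f}")

# stage 2: compare regressors under group 5-fold CV and select
comp = pr.groupkfold_evaluate(ds.features, ds.profiles, k=5, seed=1)
print(comp.summary().round(3)[["mae_mean", "mae_sd", "r_mean"]])
print("selected:", comp.best())

# deploy and predict an unseen formulation's profile
model = pr.train_full(ds.features, ds.profiles, comp.best(), seed=1)
record = ds.features.iloc[[0]]
result = model.predict_full_profile(record, [0.5, 1, 4, 7, 14, 28])
print(f"P(slow) = {result.slow_release_probability:.3f}")
print(result.predicted_release.round(3))
```

Output (seed 1):

```
stage 1: accuracy 0.707, F1 0.623
           mae_mean  mae_sd  r_mean
algorithm
lr            0.120   0.005   0.834
svr           0.083   0.004   0.916
dt            0.081   0.007   0.914
rf            0.070   0.007   0.936
xgb           0.069   0.006   0.941
lgbm          0.068   0.007   0.942
selected: lgbm
P(slow) = 0.253
[0.123 0.153 0.348 0.484 0.689 0.902]
```

Stage 1 separates slow from fast formulations at roughly 0.7 accuracy —
early release is predictable but noisy, exactly the regime in which its
*probability* (not a hard label) is worth stacking. In stage 2 the tree
ensembles cut MAE by ~40% relative to the linear model, reflecting the
planted non-linear kinetics, and the selected booster's CV MAE of ≈0.07
release-fraction units is a ~70% improvement over the predict-the-mean
baseline (0.229). The deployed model gives the example formulation a 25%
slow-release probability and a curve rising from 12% at 12 h to 90% at
28 days.

A command-line layer mirrors the library
(`plga-release simulate|stage1|stage2|validate|predict|eval-external|run`);
`plga-release run --features f.csv --profiles p.csv --out dir/` executes
the entire analysis on any dataset in the documented CSV formats — use it
with the published curated release dataset to reproduce a full study on
real data.

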