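"""Stage 2: time-dependent cumulative release regression.

The regression matrix holds one row per (formulation, time point): the 13
descriptors, the stage-1 predicted slow-release probability (constant within
a formulation) and time, with the observed cumulative release fraction as
target. Six algorithms (LR, SVR, DT, RF, XGB, LGBM) are compared under
seeded group 5-fold cross-validation grouped by formulation, scored by MAE
and per-fold Pearson r, and the lowest mean MAE wins (ties: higher mean r,
then fixed name order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, validate_data
from xgboost import XGBRegressor

from . import metrics
from .config import default_hyperparams
from .data import (
    FEATURE_COLUMNS,
    PROB_COLUMN,
    RELEASE_COLUMN,
    TIME_COLUMN,
)
from .folds import grouped_kfold_indices
from .stage1 import oof_slow_release_probabilities

#: Predictor columns of the regression matrix, in canonical order.
REGRESSION_FEATURES = FEATURE_COLUMNS + [PROB_COLUMN, TIME_COLUMN]

#: The six compared algorithms, in the fixed tie-break order.
DEFAULT_ALGORITHMS = ["lr", "svr", "dt", "rf", "xgb", "lgbm"]


def _make_estimator(algorithm: str, hyperparams: dict, seed: int):
    hp = dict(hyperparams)
    if algorithm == "lr":
        return LinearRegression(**hp)
    if algorithm == "svr":
        return make_pipeline(StandardScaler(), SVR(**hp))
    if algorithm == "dt":
        return DecisionTreeRegressor(random_state=seed, **hp)
    if algorithm == "rf":
        return RandomForestRegressor(random_state=seed, **hp)
    if algorithm == "xgb":
        return XGBRegressor(random_state=seed, **hp)
    if algorithm == "lgbm":
        return LGBMRegressor(random_state=seed, **hp)
    if algorithm == "mean":
        # predict-the-training-mean baseline used in signal-recovery checks
        return DummyRegressor(strategy="mean")
    raise ValueError(
        f"unknown algorithm {algorithm!r}; valid names: "
        f"{DEFAULT_ALGORITHMS + ['mean']}"
    )


class ReleaseRegressor(RegressorMixin, BaseEstimator):
    """Cumulative-release regressor over a configurable algorithm family.

    Predictions are clipped to the physical range [0, 1] after the wrapped
    model's raw output; no monotonicity across time is enforced.

    Parameters
    ----------
    algorithm : str
        One of ``lr, svr, dt, rf, xgb, lgbm`` (or ``mean`` for the
        training-mean baseline).
    hyperparams : dict or None
        Overrides of the packaged defaults for that algorithm.
    random_state : int
        Seed forwarded to stochastic learners.
    """

    def __init__(self, algorithm: str = "xgb", hyperparams: dict | None = None,
                 random_state: int = 0):
        self.algorithm = algorithm
        self.hyperparams = hyperparams
        self.random_state = random_state

    def _resolved_hyperparams(self) -> dict:
        try:
            hp = default_hyperparams(self.algorithm)
        except KeyError:
            hp = {}
        hp.update(self.hyperparams or {})
        return hp

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X, y = validate_data(self, X, y)
        self.model_ = _make_estimator(
            self.algorithm, self._resolved_hyperparams(), self.random_state
        ).fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        with warnings.catch_warnings():
            # fit/predict both see plain arrays; lightgbm's auto-generated
            # column names trip sklearn's name check spuriously
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names")
            raw = self.model_.predict(X)
        return np.clip(raw, 0.0, 1.0)


@dataclass(frozen=True)
class FoldResult:
    fold_id: int
    mae: float
    pearson_r: float
    n_test_rows: int


@dataclass
class ModelComparison:
    """Per-algorithm grouped-CV results and the selection rule over them."""

    results: dict[str, list[FoldResult]]
    k: int
    seed: int
    stacking: str = "global"

    def summary(self) -> pd.DataFrame:
        rows = []
        for algo, folds in self.results.items():
            maes = np.array([f.mae for f in folds])
            rs = np.array([f.pearson_r for f in folds])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r_mean, r_sd = np.nanmean(rs), np.nanstd(rs, ddof=1)
                mae_sd = maes.std(ddof=1) if maes.size > 1 else 0.0
            rows.append({
                "algorithm": algo,
                "mae_mean": maes.mean(), "mae_sd": mae_sd,
                "r_mean": r_mean, "r_sd": r_sd,
                "n_folds": len(folds),
            })
        return pd.DataFrame(rows).set_index("algorithm")

    def best(self) -> str:
        return select_best_model(self)


def assemble_regression_matrix(table: pd.DataFrame,
                               probabilities: pd.DataFrame,
                               profiles: pd.DataFrame) -> pd.DataFrame:
    """Join descriptors, the stage-1 probability and the release observations
    into the per-timepoint regression matrix.

    The probability is broadcast across a formulation's time points; a
    formulation with a profile but no probability is an error.
    """
    with_profiles = set(profiles["formulation_id"])
    with_probs = set(probabilities["formulation_id"])
    missing = sorted(with_profiles - with_probs)
    if missing:
        raise ValueError(f"no stage-1 probability for formulation_id(s): {missing}")
    keys = [c for c in table.columns if c in ("formulation_id", "drug_id")]
    matrix = (
        profiles
        .merge(probabilities[["formulation_id", PROB_COLUMN]], on="formulation_id")
        .merge(table[keys + FEATURE_COLUMNS], on="formulation_id")
    )
    cols = keys + REGRESSION_FEATURES + [RELEASE_COLUMN]
    return matrix[cols].reset_index(drop=True)


# re-exported here because they score stage-2 predictions (Eq.-style metrics)
mae = metrics.mae
pearson_r = metrics.pearson_r


def fit_release_regressor(matrix: pd.DataFrame, algorithm: str = "xgb",
                          hyperparams: dict | None = None,
                          seed: int = 0) -> ReleaseRegressor:
    """Fit one algorithm on a full regression matrix."""
    if matrix.empty:
        raise ValueError("regression matrix is empty")
    reg = ReleaseRegressor(algorithm, hyperparams, random_state=seed)
    return reg.fit(matrix[REGRESSION_FEATURES], matrix[RELEASE_COLUMN].to_numpy())


def _nested_probabilities(table: pd.DataFrame, train_ids: set, test_ids: set,
                          stage1_folds: int, seed: int) -> pd.DataFrame:
    """Strict stacking: stage-1 OOF within the outer-train formulations, and
    a model fit on all outer-train rows scores the outer-test formulations."""
    from .stage1 import SlowReleaseClassifier  # local to avoid cycle noise

    train_tab = table[table["formulation_id"].isin(train_ids)]
    test_tab = table[table["formulation_id"].isin(test_ids)]
    k1 = min(stage1_folds, train_tab["formulation_id"].nunique())
    oof = oof_slow_release_probabilities(train_tab, k=k1, seed=seed)
    clf = SlowReleaseClassifier().fit(
        train_tab[FEATURE_COLUMNS], train_tab["slow_release"].to_numpy()
    )
    test_probs = pd.DataFrame({
        "formulation_id": test_tab["formulation_id"].to_numpy(),
        PROB_COLUMN: clf.slow_release_probability(test_tab[FEATURE_COLUMNS]),
    })
    return pd.concat(
        [oof[["formulation_id", PROB_COLUMN]], test_probs], ignore_index=True
    )


def groupkfold_evaluate(table: pd.DataFrame, profiles: pd.DataFrame,
                        algorithms=None, k: int = 5, seed: int = 0,
                        stacking: str = "global", stage1_folds: int = 10,
                        hyperparams: dict | None = None) -> ModelComparison:
    """Compare algorithms under group k-fold CV grouped by formulation.

    ``stacking="global"`` computes one global stage-1 out-of-fold pass and
    reuses it in every outer fold; ``stacking="nested"`` refits stage 1
    inside each outer training fold so the meta-feature of a test formulation
    never touches its own label.
    """
    algorithms = list(algorithms or DEFAULT_ALGORITHMS)
    if stacking not in ("global", "nested"):
        raise ValueError("stacking must be 'global' or 'nested'")
    n_groups = table["formulation_id"].nunique()
    if k > n_groups:
        raise ValueError(f"k={k} exceeds {n_groups} formulation groups")

    if stacking == "global":
        probs = oof_slow_release_probabilities(table, k=stage1_folds, seed=seed)
        matrix = assemble_regression_matrix(table, probs, profiles)

    results: dict[str, list[FoldResult]] = {a: [] for a in algorithms}
    ids = table["formulation_id"].to_numpy()
    for fold, train_g, test_g in grouped_kfold_indices(ids, k, seed):
        train_ids = set(ids[train_g])
        test_ids = set(ids[test_g])
        if stacking == "nested":
            probs = _nested_probabilities(table, train_ids, test_ids,
                                          stage1_folds, seed + fold)
            matrix = assemble_regression_matrix(table, probs, profiles)
        in_train = matrix["formulation_id"].isin(train_ids)
        in_test = matrix["formulation_id"].isin(test_ids)
        X_train = matrix.loc[in_train, REGRESSION_FEATURES]
        y_train = matrix.loc[in_train, RELEASE_COLUMN].to_numpy()
        X_test = matrix.loc[in_test, REGRESSION_FEATURES]
        y_test = matrix.loc[in_test, RELEASE_COLUMN].to_numpy()
        for algo in algorithms:
            hp = (hyperparams or {}).get(algo)
            reg = ReleaseRegressor(algo, hp, random_state=seed).fit(X_train, y_train)
            pred = reg.predict(X_test)
            with warnings.catch_warnings():
                # the mean baseline predicts a constant; its r is NaN by design
                warnings.simplefilter("ignore", RuntimeWarning)
                r = pearson_r(pred, y_test)
            results[algo].append(FoldResult(
                fold_id=fold,
                mae=mae(pred, y_test),
                pearson_r=r,
                n_test_rows=len(y_test),
            ))
    return ModelComparison(results, k=k, seed=seed, stacking=stacking)


def select_best_model(comparison: ModelComparison) -> str:
    """Lowest mean MAE; ties broken by higher mean r, then fixed name order."""
    if not comparison.results:
        raise ValueError("no algorithms evaluated")
    order = {name: i for i, name in enumerate(DEFAULT_ALGORITHMS + ["mean"])}
    summary = comparison.summary()

    def key(algo: str):
        row = summary.loc[algo]
        return (row["mae_mean"], -row["r_mean"], order.get(algo, len(order)))

    return min(summary.index, key=key)
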