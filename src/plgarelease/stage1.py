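"""Stage 1: slow-release classification.

An L2-regularized logistic regression (lbfgs, regularization strength 0.5 in
the sklearn ``C`` convention by default) on the 13 formulation descriptors —
time excluded — predicts the probability that a formulation releases at most
20% of its payload within the first three days. Out-of-fold probabilities
from a seeded group 10-fold pass become the stacked meta-feature of stage 2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

from .data import FEATURE_COLUMNS, LABEL_COLUMN, PROB_COLUMN
from .folds import grouped_kfold_indices


class SingleClassError(ValueError):
    """Training data contains only one slow-release class."""


class SlowReleaseClassifier(ClassifierMixin, BaseEstimator):
    """L2-logistic slow-release classifier with in-pipeline standardization.

    Parameters
    ----------
    regularization : float
        Regularization strength, 0.5 by default.
    regularization_convention : {"inverse", "penalty"}
        "inverse" treats the value as the sklearn ``C`` (smaller = stronger
        penalty); "penalty" treats it as the penalty weight, ``C = 1/value``.
    standardize : bool
        Standardize predictors with statistics from the training rows only.
    max_iter : int
        lbfgs iteration cap.
    """

    def __init__(self, regularization: float = 0.5,
                 regularization_convention: str = "inverse",
                 standardize: bool = True, max_iter: int = 1000):
        self.regularization = regularization
        self.regularization_convention = regularization_convention
        self.standardize = standardize
        self.max_iter = max_iter

    def _C(self) -> float:
        if self.regularization_convention == "inverse":
            return self.regularization
        if self.regularization_convention == "penalty":
            return 1.0 / self.regularization
        raise ValueError(
            "regularization_convention must be 'inverse' or 'penalty', got "
            f"{self.regularization_convention!r}"
        )

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise SingleClassError(
                f"training data contains a single class ({classes.tolist()}); "
                "both slow and fast formulations are required"
            )
        variances = X.var(axis=0)
        self.zero_variance_features_ = np.flatnonzero(variances == 0)
        if self.zero_variance_features_.size:
            warnings.warn(
                "constant predictor column(s) at index "
                f"{self.zero_variance_features_.tolist()}; they are scaled to "
                "zero and carry no coefficient weight", RuntimeWarning)
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        # L2 penalty is sklearn's default; C carries the strength
        self.model_ = LogisticRegression(
            C=self._C(), solver="lbfgs", max_iter=self.max_iter
        ).fit(Xs, y)
        self.classes_ = self.model_.classes_
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        return self

    def _transform(self, X):
        X = validate_data(self, X, reset=False)
        return self.scaler_.transform(X) if self.scaler_ is not None else X

    def decision_function(self, X):
        check_is_fitted(self)
        return self.model_.decision_function(self._transform(X))

    def predict_proba(self, X):
        check_is_fitted(self)
        return self.model_.predict_proba(self._transform(X))

    def predict(self, X):
        check_is_fitted(self)
        return self.model_.predict(self._transform(X))

    def slow_release_probability(self, X) -> np.ndarray:
        """P(slow-release), i.e. the probability of class 1."""
        check_is_fitted(self)
        proba = self.predict_proba(X)
        return proba[:, list(self.classes_).index(1)]


def fit_slow_release_classifier(table: pd.DataFrame,
                                **params) -> SlowReleaseClassifier:
    """Fit the stage-1 classifier on a labeled feature table."""
    clf = SlowReleaseClassifier(**params)
    return clf.fit(table[FEATURE_COLUMNS], table[LABEL_COLUMN].to_numpy())


def oof_slow_release_probabilities(table: pd.DataFrame, k: int = 10,
                                   seed: int = 0,
                                   **params) -> pd.DataFrame:
    """Out-of-fold slow-release probabilities under seeded group k-fold.

    Grouping key is ``formulation_id``: the model that scores a formulation
    never saw any row sharing its id. A training fold that degenerates to a
    single class falls back to predicting that class's prior (its rate in the
    fold) with a warning rather than crashing.

    Returns a frame with ``formulation_id``, ``predicted_slow_release`` and
    ``fold_id``.
    """
    X = table[FEATURE_COLUMNS]
    y = table[LABEL_COLUMN].to_numpy()
    ids = table["formulation_id"].to_numpy()
    out = np.full(len(table), np.nan)
    fold_ids = np.full(len(table), -1)
    for fold, train, test in grouped_kfold_indices(ids, k, seed):
        y_train = y[train]
        if np.unique(y_train).size < 2:
            prior = float(np.mean(y_train))
            warnings.warn(
                f"fold {fold}: training split is single-class; falling back "
                f"to the training prior {prior:.3f}", RuntimeWarning)
            out[test] = prior
        else:
            clf = SlowReleaseClassifier(**params).fit(X.iloc[train], y_train)
            out[test] = clf.slow_release_probability(X.iloc[test])
        fold_ids[test] = fold
    return pd.DataFrame({
        "formulation_id": ids,
        PROB_COLUMN: out,
        "fold_id": fold_ids,
    })


def classify(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Binarize probabilities; the threshold is inclusive (0.5 -> label 1)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(int)
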