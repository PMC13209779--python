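"""Deployment path: the two-stage model trained on the full dataset.

Training follows the standard stacking asymmetry: the stage-2 regressor is
fit on out-of-fold stage-1 probabilities (so its meta-feature matches what
it will see for unseen formulations), while at predict time the stage-1
model refit on all formulations supplies the probability.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import (
    FEATURE_COLUMNS,
    LABEL_COLUMN,
    PROB_COLUMN,
    RELEASE_COLUMN,
    TIME_COLUMN,
    FormulationRecord,
    ReleaseProfile,
    label_table,
)
from .metrics import mae, pearson_r
from .stage1 import SlowReleaseClassifier, oof_slow_release_probabilities
from .stage2 import (
    REGRESSION_FEATURES,
    ReleaseRegressor,
    assemble_regression_matrix,
)


class ExtrapolationWarning(UserWarning):
    """A descriptor of the query formulation lies outside the training range."""


@dataclass
class PredictionResult:
    formulation_id: str
    slow_release_probability: float
    time_days: np.ndarray
    predicted_release: np.ndarray

    def to_dict(self) -> dict:
        return {
            "formulation_id": self.formulation_id,
            "slow_release_probability": self.slow_release_probability,
            "time_days": np.asarray(self.time_days).tolist(),
            "predicted_release": np.asarray(self.predicted_release).tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class ExternalEvaluation:
    prediction: PredictionResult
    observed_release: np.ndarray
    mae: float
    pearson_r: float

    def to_dict(self) -> dict:
        return {
            "prediction": self.prediction.to_dict(),
            "observed_release": np.asarray(self.observed_release).tolist(),
            "mae": self.mae,
            "pearson_r": self.pearson_r,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ExternalEvaluation":
        p = d["prediction"]
        return cls(
            PredictionResult(
                p["formulation_id"], p["slow_release_probability"],
                np.asarray(p["time_days"]), np.asarray(p["predicted_release"]),
            ),
            np.asarray(d["observed_release"]), d["mae"], d["pearson_r"],
        )


class TwoStageReleaseModel(BaseEstimator):
    """Full two-stage release predictor (classification -> regression).

    Parameters
    ----------
    algorithm : str
        Stage-2 algorithm name (default the selected booster, ``xgb``).
    stage1_folds : int
        Folds of the group k-fold pass that builds the training
        meta-feature.
    random_state : int
        Seed for fold assignment and stochastic learners.
    hyperparams : dict or None
        Stage-2 hyperparameter overrides.
    check_ranges : bool
        Warn (:class:`ExtrapolationWarning`) when a query descriptor falls
        outside the training range.
    """

    def __init__(self, algorithm: str = "xgb", stage1_folds: int = 10,
                 random_state: int = 0, hyperparams: dict | None = None,
                 check_ranges: bool = True):
        self.algorithm = algorithm
        self.stage1_folds = stage1_folds
        self.random_state = random_state
        self.hyperparams = hyperparams
        self.check_ranges = check_ranges

    def fit(self, features: pd.DataFrame, profiles: pd.DataFrame,
            labels: pd.DataFrame | None = None):
        """Fit both stages on a (filtered) feature table and profile table.

        ``labels`` defaults to the day-3 slow-release rule applied to the
        profiles.
        """
        if labels is None:
            labels = label_table(profiles)
        table = features.merge(labels, on="formulation_id") \
            if LABEL_COLUMN not in features.columns else features
        k = min(self.stage1_folds, table["formulation_id"].nunique())
        self.oof_probabilities_ = oof_slow_release_probabilities(
            table, k=k, seed=self.random_state
        )
        self.classifier_ = SlowReleaseClassifier().fit(
            table[FEATURE_COLUMNS], table[LABEL_COLUMN].to_numpy()
        )
        self.matrix_ = assemble_regression_matrix(
            table, self.oof_probabilities_, profiles
        )
        self.regressor_ = ReleaseRegressor(
            self.algorithm, self.hyperparams, random_state=self.random_state
        ).fit(
            self.matrix_[REGRESSION_FEATURES],
            self.matrix_[RELEASE_COLUMN].to_numpy(),
        )
        self.feature_ranges_ = pd.DataFrame({
            "min": table[FEATURE_COLUMNS].min(),
            "max": table[FEATURE_COLUMNS].max(),
        })
        self.n_formulations_ = table["formulation_id"].nunique()
        return self

    def _record_frame(self, record: FormulationRecord | pd.DataFrame) -> pd.DataFrame:
        if isinstance(record, FormulationRecord):
            frame = record.to_frame()
        else:
            missing = [c for c in FEATURE_COLUMNS if c not in record.columns]
            if missing:
                raise ValueError(f"record is missing descriptor(s): {missing}")
            frame = record
        if self.check_ranges:
            for col in FEATURE_COLUMNS:
                lo = self.feature_ranges_.loc[col, "min"]
                hi = self.feature_ranges_.loc[col, "max"]
                vals = frame[col]
                if (vals < lo).any() or (vals > hi).any():
                    warnings.warn(
                        f"{col} outside the training range [{lo:.4g}, {hi:.4g}]; "
                        "prediction is an extrapolation", ExtrapolationWarning)
        return frame

    def predict_slow_release(self, record) -> float:
        """Slow-release probability from the full-data stage-1 model."""
        check_is_fitted(self, "classifier_")
        frame = self._record_frame(record)
        return float(self.classifier_.slow_release_probability(
            frame[FEATURE_COLUMNS])[0])

    def predict_full_profile(self, record, grid) -> PredictionResult:
        """Predict the cumulative release fraction on a time grid (days)."""
        check_is_fitted(self, "regressor_")
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("time grid is empty")
        if np.any(np.diff(grid) < 0):
            raise ValueError("time grid must be non-decreasing")
        frame = self._record_frame(record)
        prob = self.predict_slow_release(frame)
        X = frame[FEATURE_COLUMNS].iloc[[0] * grid.size].reset_index(drop=True)
        X[PROB_COLUMN] = prob
        X[TIME_COLUMN] = grid
        pred = self.regressor_.predict(X[REGRESSION_FEATURES])
        fid = (record.formulation_id if isinstance(record, FormulationRecord)
               else str(frame.get("formulation_id", pd.Series(["query"])).iloc[0]))
        return PredictionResult(fid, prob, grid, pred)

    def evaluate_external(self, record,
                          observed: ReleaseProfile | pd.DataFrame) -> ExternalEvaluation:
        """Predict on the observed time points and score MAE / Pearson r."""
        if isinstance(observed, pd.DataFrame):
            obs = observed.sort_values(TIME_COLUMN)
            t = obs[TIME_COLUMN].to_numpy(dtype=float)
            y = obs[RELEASE_COLUMN].to_numpy(dtype=float)
        else:
            t, y = observed.time_days, observed.cumulative_release
        if t.size == 0:
            raise ValueError("observed profile is empty")
        pred = self.predict_full_profile(record, t)
        if t.size < 2:
            warnings.warn("single observation; Pearson r undefined",
                          RuntimeWarning)
            r = float("nan")
        else:
            r = pearson_r(pred.predicted_release, y)
        return ExternalEvaluation(pred, y, mae(pred.predicted_release, y), r)

    def save(self, path) -> None:
        check_is_fitted(self, "regressor_")
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TwoStageReleaseModel":
        model = joblib.load(path)
        if not isinstance(model, TwoStageReleaseModel):
            raise TypeError(f"{path} does not hold a TwoStageReleaseModel")
        return model


def train_full(features: pd.DataFrame, profiles: pd.DataFrame,
               algorithm: str = "xgb", seed: int = 0,
               hyperparams: dict | None = None) -> TwoStageReleaseModel:
    """Train the deployable model pair on the full dataset."""
    return TwoStageReleaseModel(
        algorithm=algorithm, random_state=seed, hyperparams=hyperparams
    ).fit(features, profiles)
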